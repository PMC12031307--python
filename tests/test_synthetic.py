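"""Cohort generator: design counts, drift rules, noise, reproducibility."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from bisfruit import (
    CohortParameters,
    FitConfig,
    StudyDesign,
    apply_drift,
    draw_cohort,
    fit_spectrum,
    generate_cohort,
    measure_cohort,
)


class TestDrawCohort:
    def test_balanced_design(self, medium_cohort):
        design, records, _ = medium_cohort
        n = design.n_per_group
        assert len(records) == 4 * n
        assert sum(r.size == "small" for r in records) == 2 * n
        assert sum(r.size == "large" for r in records) == 2 * n
        assert sum(r.storage == "room" for r in records) == 2 * n
        # balance within each size group too
        for size in ("small", "large"):
            cell = [r for r in records if r.size == size and r.storage == "cold"]
            assert len(cell) == n

    def test_seeded_determinism(self):
        design = StudyDesign(n_per_group=3, seed=42)
        a = draw_cohort(design)
        b = draw_cohort(design)
        for ra, rb in zip(a, b):
            assert ra.sample_id == rb.sample_id
            assert ra.diameter_mm == rb.diameter_mm
            np.testing.assert_array_equal(
                ra.true_params[0].as_array(), rb.true_params[0].as_array()
            )

    def test_diameter_distributions_separated(self, medium_cohort):
        _, records, _ = medium_cohort
        small = [r.diameter_mm for r in records if r.size == "small"]
        large = [r.diameter_mm for r in records if r.size == "large"]
        assert max(small) < min(large) + 5  # distributions may touch slightly
        assert np.mean(large) - np.mean(small) > 10

    def test_size_coupling_on_membrane_q(self, medium_cohort):
        _, records, _ = medium_cohort
        qm_small = [r.true_params[0].cpe_m.q for r in records if r.size == "small"]
        qm_large = [r.true_params[0].cpe_m.q for r in records if r.size == "large"]
        assert np.median(qm_large) > np.median(qm_small)

    def test_invalid_diameter_config_rejected(self):
        bad = CohortParameters(diameter_mm={"small": (-5.0, 1.0), "large": (70.0, 3.0)})
        with pytest.raises(ValueError):
            draw_cohort(StudyDesign(n_per_group=2, seed=0), bad)


class TestApplyDrift:
    def test_zero_jitter_cold_group_is_identity(self):
        params = CohortParameters(cold_drift_jitter_sd=0.0)
        records = draw_cohort(StudyDesign(n_per_group=2, seed=1), params)
        rng = np.random.default_rng(0)
        cold = next(r for r in records if r.storage == "cold")
        r1 = apply_drift(cold, 1, params, rng)
        r2 = apply_drift(r1, 2, params, rng)
        np.testing.assert_array_equal(
            r2.true_params[2].as_array(), r2.true_params[0].as_array()
        )

    def test_room_group_resistances_grow(self):
        params = CohortParameters()
        records = draw_cohort(StudyDesign(n_per_group=12, seed=2), params)
        rng = np.random.default_rng(1)
        room = [r for r in records if r.storage == "room"]
        grown = 0
        day0, day2 = [], []
        for rec in room:
            rec = apply_drift(apply_drift(rec, 1, params, rng), 2, params, rng)
            grown += rec.true_params[2].r_ex > rec.true_params[0].r_ex
            day0.append(rec.true_params[0].r_ex)
            day2.append(rec.true_params[2].r_ex)
        assert grown >= 0.8 * len(room)  # jitter may flip rare individuals
        assert np.mean(day2) > 1.2 * np.mean(day0)

    def test_drift_compounds_across_days(self):
        params = CohortParameters(room_drift_jitter_sd=0.0, drift_size_exponent=0.0)
        records = draw_cohort(StudyDesign(n_per_group=1, seed=3), params)
        room = next(r for r in records if r.storage == "room")
        rng = np.random.default_rng(0)
        rec = apply_drift(apply_drift(room, 1, params, rng), 2, params, rng)
        factor = params.room_drift_per_day["r_ex"]
        assert rec.true_params[1].r_ex == pytest.approx(
            room.true_params[0].r_ex * factor, rel=1e-12
        )
        assert rec.true_params[2].r_ex == pytest.approx(
            room.true_params[0].r_ex * factor**2, rel=1e-12
        )

    def test_unknown_storage_label_rejected(self):
        records = draw_cohort(StudyDesign(n_per_group=1, seed=4))
        bad = dataclasses.replace(records[0], storage="freezer")
        with pytest.raises(ValueError):
            apply_drift(bad, 1, CohortParameters())

    def test_day_without_baseline_rejected(self):
        records = draw_cohort(StudyDesign(n_per_group=1, seed=5))
        with pytest.raises(ValueError):
            apply_drift(records[0], 2, CohortParameters())  # day-1 state missing


class TestMeasureCohort:
    def test_noiseless_measurement_equals_forward_model(self, grid):
        params = CohortParameters(noise_mag_rel_sd=0.0, noise_phase_sd_deg=0.0)
        records = draw_cohort(StudyDesign(n_per_group=1, seed=6), params)
        spectra = measure_cohort(records, params, grid, seed=0)
        from bisfruit import simulate_spectrum

        for rec, spec in zip(records, spectra):
            clean = simulate_spectrum(rec.true_params[0], grid)
            np.testing.assert_allclose(spec.values, clean.values, rtol=1e-12)

    def test_fit_recovers_truth_from_noiseless_measurement(self, grid):
        params = CohortParameters(noise_mag_rel_sd=0.0, noise_phase_sd_deg=0.0)
        records = draw_cohort(StudyDesign(n_per_group=1, seed=7), params)
        spectra = measure_cohort(records, params, grid, seed=0)
        res = fit_spectrum(spectra[0], FitConfig(seed=0))
        np.testing.assert_allclose(
            res.params.as_array(), records[0].true_params[0].as_array(), rtol=1e-2
        )


class TestGenerateCohort:
    def test_counts(self, medium_cohort):
        design, records, spectra = medium_cohort
        assert len(records) == design.n_samples
        assert len(spectra) == design.n_spectra
        days = {s.metadata.day for s in spectra}
        assert days == {0, 1, 2}

    def test_same_seed_identical_spectra(self):
        design = StudyDesign(n_per_group=2, seed=77)
        _, a = generate_cohort(design)
        _, b = generate_cohort(design)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.values, sb.values)

    def test_day0_distributions_exchangeable_across_storage(self, medium_cohort):
        # storage labels are assigned after drawing, so day-0 parameters of
        # room and cold groups come from one distribution
        _, records, _ = medium_cohort
        room = [r.true_params[0].r_ex for r in records if r.storage == "room"]
        cold = [r.true_params[0].r_ex for r in records if r.storage == "cold"]
        assert stats.mannwhitneyu(room, cold).pvalue > 0.01

    def test_size_phase_coupling_at_day0(self, grid):
        # larger fruit -> larger membrane Q -> smaller low-frequency |phase|
        design = StudyDesign(seed=13)
        _, spectra = generate_cohort(design)
        lowf = grid.frequencies <= 1000.0
        day0 = [s for s in spectra if s.metadata.day == 0]
        small = [np.mean(np.abs(s.phase_deg[lowf])) for s in day0 if s.metadata.size == "small"]
        large = [np.mean(np.abs(s.phase_deg[lowf])) for s in day0 if s.metadata.size == "large"]
        t = stats.ttest_ind(small, large)
        assert np.mean(large) < np.mean(small)
        assert t.pvalue < 0.01

    def test_room_impedance_rises_and_dominates_cold_changes(self, grid):
        design = StudyDesign(seed=19)
        records, spectra = generate_cohort(design)
        by = {(s.metadata.sample_id, s.metadata.day): s for s in spectra}
        deltas = {"room": [], "cold": []}
        day2_means = {"room": [], "cold": []}
        day0_means = {"room": [], "cold": []}
        for r in records:
            z0 = by[(r.sample_id, 0)].magnitude[0]
            z2 = by[(r.sample_id, 2)].magnitude[0]
            deltas[r.storage].append(abs(z2 - z0))
            day0_means[r.storage].append(z0)
            day2_means[r.storage].append(z2)
        # room group: impedance at 50 Hz rises over storage
        assert np.mean(day2_means["room"]) > np.mean(day0_means["room"])
        # room-group day-2 changes dwarf cold-group changes
        assert np.mean(deltas["room"]) > 3 * np.mean(deltas["cold"])
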