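"""Synthetic fruit cohorts with the storage-study design.

The generator emulates a two-temperature storage experiment on citrus
fruit: a balanced 2 x 2 cohort (size: small/large, storage: room 21 C /
cold 4 C), each fruit measured on days 0, 1 and 2, yielding
``n_per_group * 4`` fruit and three times as many spectra (the default
46 per cell gives 184 fruit and 552 spectra).

Each fruit carries a latent set of circuit parameters drawn log-normally
around group-level locations, with the membrane CPE magnitude coupled to
the fruit's diameter (a larger fruit has more membrane area, hence a
larger Q_m and a smaller low-frequency phase magnitude).  Storage drift
acts multiplicatively on the latent parameters, never on the spectra
directly, so every spectrum remains a physically consistent circuit
response:

* room group: extracellular and intracellular resistances grow and the
  membrane CPE magnitude shrinks each day (water loss concentrates the
  apoplast and shrinks membrane area), with per-fruit log-normal jitter
  and a surface-to-volume size effect (smaller fruit dry faster);
* cold group: all factors sit at 1 with small jitter, so changes stay
  near zero.

Measurement noise is applied in polar form: multiplicative relative
noise on |Z| and additive noise in degrees on the phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .ec_model import (
    ECParameters,
    FrequencyGrid,
    ImpedanceSpectrum,
    SpectrumMetadata,
    from_polar,
    simulate_spectrum,
)

__all__ = [
    "StudyDesign",
    "CohortParameters",
    "SampleRecord",
    "draw_cohort",
    "apply_drift",
    "measure_cohort",
    "generate_cohort",
]

SIZES = ("small", "large")
STORAGES = ("room", "cold")


@dataclass(frozen=True)
class StudyDesign:
    """Cohort layout: fruit per (size x storage) cell, days, grid, seed."""

    n_per_group: int = 46
    days: Tuple[int, ...] = (0, 1, 2)
    grid: FrequencyGrid = field(default_factory=FrequencyGrid.default)
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return 4 * self.n_per_group

    @property
    def n_spectra(self) -> int:
        return self.n_samples * len(self.days)


@dataclass(frozen=True)
class CohortParameters:
    """Distributional knobs of the synthetic cohort.

    diameter_mm          per size group: (mean, sd) in mm.  The defaults
                         (small 55 +/- 3, large 70 +/- 3) are nominal
                         market sizes, chosen to give two well-separated
                         (bimodal pooled) distributions.
    baseline_log_median  natural-log medians of the five positive
                         circuit parameters (r_e, q_e, r_ex, r_i, q_m).
    baseline_log_sd      log-normal scale of between-fruit variation.
    alpha_mean / alpha_sd  ideality factors drawn normally, clipped.
    qm_diameter_exponent   Q_m scales with (d / d_ref)^exponent; the
                         default positive sign means larger fruit ->
                         larger membrane Q_m -> smaller low-frequency
                         |phase|.
    room_drift_per_day   multiplicative per-day factors on (r_ex, r_i,
                         q_m) for room storage; resistances > 1, Q_m < 1.
    room_drift_jitter_sd / cold_drift_jitter_sd
                         log-normal sd of per-fruit-per-day jitter on
                         the factors; cold factors have median 1.
    drift_size_exponent  per-day log drift is scaled by
                         (d_ref / d)^exponent: smaller fruit (higher
                         surface-to-volume ratio) lose water faster.
    noise_mag_rel_sd     relative sd of multiplicative |Z| noise.
    noise_phase_sd_deg   sd of additive phase noise in degrees.
    batch_offset_log     optional two-batch purchase effect (log offset
                         applied to r_ex for the second batch); 0 = off.
    """

    diameter_mm: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {"small": (55.0, 3.0), "large": (70.0, 3.0)}
    )
    baseline_log_median: Dict[str, float] = field(
        default_factory=lambda: {
            "r_e": np.log(500.0),
            "q_e": np.log(2.0e-6),
            "r_ex": np.log(2.0e4),
            "r_i": np.log(6.0e3),
            "q_m": np.log(8.0e-7),
        }
    )
    baseline_log_sd: Dict[str, float] = field(
        default_factory=lambda: {
            "r_e": 0.30,
            "q_e": 0.30,
            "r_ex": 0.20,
            "r_i": 0.20,
            "q_m": 0.30,
        }
    )
    alpha_mean: Dict[str, float] = field(
        default_factory=lambda: {"alpha_e": 0.85, "alpha_m": 0.80}
    )
    alpha_sd: float = 0.03
    diameter_ref_mm: float = 62.5
    qm_diameter_exponent: float = 2.0
    room_drift_per_day: Dict[str, float] = field(
        default_factory=lambda: {"r_ex": 1.16, "r_i": 1.09, "q_m": 0.85}
    )
    room_drift_jitter_sd: float = 0.10
    cold_drift_jitter_sd: float = 0.05
    drift_size_exponent: float = 3.0
    noise_mag_rel_sd: float = 0.005
    noise_phase_sd_deg: float = 0.5
    batch_offset_log: float = 0.0


@dataclass
class SampleRecord:
    """One fruit: labels, diameter, and latent parameters per day."""

    sample_id: str
    size: str
    storage: str
    diameter_mm: float
    true_params: Dict[int, ECParameters]
    batch: int = 0


def _draw_baseline(
    rng: np.random.Generator, params: CohortParameters, diameter: float, batch: int
) -> ECParameters:
    loc = params.baseline_log_median
    sd = params.baseline_log_sd
    draw = {k: np.exp(rng.normal(loc[k], sd[k])) for k in loc}
    # membrane CPE scales with membrane area, hence with fruit size
    draw["q_m"] *= (diameter / params.diameter_ref_mm) ** params.qm_diameter_exponent
    if batch == 1 and params.batch_offset_log != 0.0:
        draw["r_ex"] *= np.exp(params.batch_offset_log)
    alphas = {
        k: float(np.clip(rng.normal(m, params.alpha_sd), 0.5, 0.99))
        for k, m in params.alpha_mean.items()
    }
    return ECParameters.from_array(
        [
            draw["r_e"],
            draw["q_e"],
            alphas["alpha_e"],
            draw["r_ex"],
            draw["r_i"],
            draw["q_m"],
            alphas["alpha_m"],
        ]
    )


def draw_cohort(
    design: StudyDesign, params: Optional[CohortParameters] = None
) -> List[SampleRecord]:
    """Draw the day-0 state of a balanced cohort.

    Fruit are drawn per size group first; storage labels are assigned by
    a seeded permutation afterwards, so day-0 parameter distributions
    are exchangeable between the room and cold groups.
    """
    if params is None:
        params = CohortParameters()
    if design.n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    for size in SIZES:
        if size not in params.diameter_mm:
            raise ValueError(f"missing diameter distribution for size {size!r}")
        mean, sd = params.diameter_mm[size]
        if sd < 0 or mean <= 0:
            raise ValueError("diameter distributions must have mean > 0, sd >= 0")

    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 0xC0]))
    records: List[SampleRecord] = []
    counter = 0
    for size in SIZES:
        n_size = 2 * design.n_per_group
        mean, sd = params.diameter_mm[size]
        diameters = rng.normal(mean, sd, size=n_size)
        diameters = np.clip(diameters, 1.0, None)
        # randomized storage assignment within each size group
        storages = np.array([STORAGES[0]] * design.n_per_group
                            + [STORAGES[1]] * design.n_per_group)
        rng.shuffle(storages)
        for i in range(n_size):
            counter += 1
            batch = 0 if i < n_size // 2 else 1
            baseline = _draw_baseline(rng, params, float(diameters[i]), batch)
            records.append(
                SampleRecord(
                    sample_id=f"M{counter:03d}",
                    size=size,
                    storage=str(storages[i]),
                    diameter_mm=float(diameters[i]),
                    true_params={0: baseline},
                    batch=batch,
                )
            )
    return records


def apply_drift(
    record: SampleRecord,
    day: int,
    params: CohortParameters,
    rng: Optional[np.random.Generator] = None,
) -> SampleRecord:
    """Advance a fruit's latent parameters to *day* (1 or 2).

    Drift compounds from the previous day's parameters.  Room factors
    are log-normal around the configured per-day medians, scaled by the
    surface-to-volume size effect; cold factors are log-normal around 1.
    With jitter sd set to 0 the cold group's parameters are exactly the
    day-0 parameters.
    """
    if day not in (1, 2):
        raise ValueError("drift days are 1 and 2")
    if day - 1 not in record.true_params:
        raise ValueError(f"day {day - 1} state missing for {record.sample_id}")
    if record.storage not in STORAGES:
        raise ValueError(f"unknown storage label {record.storage!r}")
    if rng is None:
        rng = np.random.default_rng(0)

    prev = record.true_params[day - 1]
    size_scale = (params.diameter_ref_mm / record.diameter_mm) ** params.drift_size_exponent
    factors: Dict[str, float] = {}
    if record.storage == "room":
        for name, median in params.room_drift_per_day.items():
            jitter = rng.normal(0.0, params.room_drift_jitter_sd)
            factors[name] = float(np.exp(np.log(median) * size_scale + jitter))
    else:
        for name in params.room_drift_per_day:
            jitter = rng.normal(0.0, params.cold_drift_jitter_sd)
            factors[name] = float(np.exp(jitter)) if params.cold_drift_jitter_sd > 0 else 1.0
    new_params = prev.scaled(**factors)
    updated = dict(record.true_params)
    updated[day] = new_params
    return replace_record(record, true_params=updated)


def replace_record(record: SampleRecord, **changes) -> SampleRecord:
    return replace(record, **changes)


def measure_cohort(
    records: Sequence[SampleRecord],
    params: Optional[CohortParameters] = None,
    grid: Optional[FrequencyGrid] = None,
    seed: int = 0,
) -> List[ImpedanceSpectrum]:
    """Noisy polar measurements of every fruit x day.

    Evaluates the forward model on each fruit's latent parameters, then
    perturbs |Z| multiplicatively and the phase additively.  With both
    noise scales at 0 the spectra equal the forward model exactly.
    Output order: fruit in input order, days ascending within fruit.
    """
    if params is None:
        params = CohortParameters()
    if grid is None:
        grid = FrequencyGrid.default()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5E]))
    spectra: List[ImpedanceSpectrum] = []
    for rec in records:
        for day in sorted(rec.true_params):
            clean = simulate_spectrum(
                rec.true_params[day],
                grid,
                metadata=SpectrumMetadata(
                    sample_id=rec.sample_id,
                    day=day,
                    size=rec.size,
                    storage=rec.storage,
                    diameter_mm=rec.diameter_mm,
                ),
            )
            mag, phase = np.abs(clean.values), np.degrees(np.angle(clean.values))
            if params.noise_mag_rel_sd > 0:
                mag = mag * (1.0 + rng.normal(0.0, params.noise_mag_rel_sd, mag.shape))
            if params.noise_phase_sd_deg > 0:
                phase = phase + rng.normal(0.0, params.noise_phase_sd_deg, phase.shape)
            spectra.append(clean.with_values(from_polar(np.abs(mag), phase)))
    return spectra


def generate_cohort(
    design: StudyDesign, params: Optional[CohortParameters] = None
) -> Tuple[List[SampleRecord], List[ImpedanceSpectrum]]:
    """Full pipeline: draw day 0, drift days 1 and 2, measure everything.

    All randomness derives from ``design.seed`` through separate child
    streams for drawing, drift and measurement noise, so the cohort is
    reproducible from the design alone.
    """
    if params is None:
        params = CohortParameters()
    records = draw_cohort(design, params)
    drift_rng = np.random.default_rng(np.random.SeedSequence([design.seed, 0xD1]))
    drifted: List[SampleRecord] = []
    for rec in records:
        for day in sorted(d for d in design.days if d > 0):
            rec = apply_drift(rec, day, params, drift_rng)
        drifted.append(rec)
    spectra = measure_cohort(drifted, params, design.grid, seed=design.seed)
    return drifted, spectra
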