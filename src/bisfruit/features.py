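"""Feature-table assembly: the six dataset variants and the 8:2 split.

From a cohort of spectra (and optionally their circuit fits and
diameters) this module builds the six datasets used to benchmark the
storage-temperature classifiers:

===================  ================================  ========
kind                 features                          width
===================  ================================  ========
``bio-raw``          |Z| then phase at each frequency  2 * n_f
``bio-delta``        day-t minus day-0 differences     2 * n_f
``bio-delta-diam``   deltas plus diameter              2 * n_f + 1
``ec-raw``           the seven circuit parameters      7
``ec-delta``         circuit-parameter differences     7
``ec-delta-diam``    deltas plus diameter              8
===================  ================================  ========

Instances are fruit x day for days >= 1 only; day-0 rows are consumed as
baselines and never emitted.  Feature order is fixed: magnitudes in
ascending frequency, then phases; circuit parameters in the canonical
order r_e, q_e, alpha_e, r_ex, r_i, q_m, alpha_m; diameter last.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.model_selection import train_test_split

from .ec_fit import FitResult
from .ec_model import EC_PARAMETER_NAMES, ImpedanceSpectrum

__all__ = [
    "FeatureTable",
    "SplitSpec",
    "NormalizationStats",
    "DATASET_KINDS",
    "delta_features",
    "zscore_normalize",
    "assemble_dataset",
    "split",
]

DATASET_KINDS = (
    "bio-raw",
    "bio-delta",
    "bio-delta-diam",
    "ec-raw",
    "ec-delta",
    "ec-delta-diam",
)


@dataclass(frozen=True)
class FeatureTable:
    """Instances x features matrix with storage labels."""

    kind: str
    instance_ids: Tuple[str, ...]
    feature_names: Tuple[str, ...]
    X: np.ndarray
    y: np.ndarray  # storage labels, "room"/"cold"

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        if X.shape != (len(self.instance_ids), len(self.feature_names)):
            raise ValueError("matrix shape does not match ids/feature names")
        if np.any(~np.isfinite(X)):
            raise ValueError("feature matrix contains non-finite values")
        if len(self.y) != len(self.instance_ids):
            raise ValueError("label vector length mismatch")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", np.asarray(self.y))

    @property
    def n_instances(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class SplitSpec:
    """Train/test split: stratified 8:2 by default, train size rounded half-up."""

    train_fraction: float = 0.8
    stratify: bool = True
    seed: int = 0


@dataclass(frozen=True)
class NormalizationStats:
    feature_names: Tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray
    constant_features: Tuple[str, ...] = ()


def delta_features(day_t: np.ndarray, day_0: np.ndarray,
                   ids_t: Optional[Sequence[str]] = None,
                   ids_0: Optional[Sequence[str]] = None) -> np.ndarray:
    """Elementwise change from baseline: delta X_t = X_t - X_0.

    When id sequences are given they must match pairwise (the rows must
    come from the same fruit).
    """
    a = np.asarray(day_t, dtype=float)
    b = np.asarray(day_0, dtype=float)
    if a.shape != b.shape:
        raise ValueError("day-t and day-0 feature blocks differ in shape")
    if ids_t is not None or ids_0 is not None:
        if list(ids_t) != list(ids_0):
            raise ValueError("sample ids of day-t and day-0 rows do not align")
    return a - b


def zscore_normalize(
    table: FeatureTable,
    stats: Optional[NormalizationStats] = None,
    ddof: int = 0,
) -> Tuple[FeatureTable, NormalizationStats]:
    """Per-feature standardization (x - mean) / sd.

    With ``stats=None`` the statistics are fit on the table itself
    (population sd by default, ``ddof=0``) and returned for reuse on
    held-out data.  A zero-variance feature is centered only and listed
    in ``constant_features``.
    """
    if stats is None:
        mean = table.X.mean(axis=0)
        sd = table.X.std(axis=0, ddof=ddof)
        constant = tuple(
            name for name, s in zip(table.feature_names, sd) if s == 0.0
        )
        stats = NormalizationStats(
            feature_names=table.feature_names,
            mean=mean,
            sd=np.where(sd == 0.0, 1.0, sd),
            constant_features=constant,
        )
        if constant:
            import warnings

            warnings.warn(
                f"zero-variance features centered only: {constant}", stacklevel=2
            )
    if stats.feature_names != table.feature_names:
        raise ValueError("normalization statistics were fit on different features")
    Xn = (table.X - stats.mean) / stats.sd
    return replace(table, X=Xn), stats


def _polar_matrix(spectra: Sequence[ImpedanceSpectrum]) -> np.ndarray:
    return np.stack([np.concatenate([s.magnitude, s.phase_deg]) for s in spectra])


def _bio_feature_names(n_f: int) -> List[str]:
    return [f"zmod_{i + 1:03d}" for i in range(n_f)] + [
        f"phase_{i + 1:03d}" for i in range(n_f)
    ]


def _group_by_sample(
    spectra: Sequence[ImpedanceSpectrum],
) -> Dict[str, Dict[int, ImpedanceSpectrum]]:
    out: Dict[str, Dict[int, ImpedanceSpectrum]] = {}
    for s in spectra:
        out.setdefault(s.metadata.sample_id, {})[s.metadata.day] = s
    return out


def assemble_dataset(
    kind: str,
    spectra: Optional[Sequence[ImpedanceSpectrum]] = None,
    fits: Optional[Sequence[FitResult]] = None,
    diameters: Optional[Dict[str, float]] = None,
) -> FeatureTable:
    """Build one of the six dataset variants.

    ``bio-*`` kinds require ``spectra``; ``ec-*`` kinds require ``fits``
    (whose ``metadata`` must carry sample id, day and labels);
    ``*-diam`` kinds additionally require a ``diameters`` map or
    metadata diameters.  Changes datasets need a day-0 baseline for
    every fruit.  Assembly is deterministic: instances are ordered by
    day then sample id.
    """
    if kind not in DATASET_KINDS:
        raise ValueError(f"unknown dataset kind {kind!r}; choose from {DATASET_KINDS}")
    family = "bio" if kind.startswith("bio") else "ec"
    wants_delta = "delta" in kind
    wants_diam = kind.endswith("diam")

    if family == "bio":
        if spectra is None:
            raise ValueError("bio datasets require spectra")
        per_sample = _group_by_sample(spectra)
        n_f = len(spectra[0].grid)
        feature_names = _bio_feature_names(n_f)

        def vec(item: ImpedanceSpectrum) -> np.ndarray:
            return np.concatenate([item.magnitude, item.phase_deg])

        def meta(item: ImpedanceSpectrum):
            return item.metadata
    else:
        if fits is None:
            raise ValueError("ec datasets require fit results")
        per_sample = {}
        for r in fits:
            m = r.metadata
            if m is None or not getattr(m, "sample_id", ""):
                raise ValueError("fit results must carry spectrum metadata")
            per_sample.setdefault(m.sample_id, {})[m.day] = r
        feature_names = list(EC_PARAMETER_NAMES)

        def vec(item: FitResult) -> np.ndarray:
            return item.params.as_array()

        def meta(item: FitResult):
            return item.metadata

    days = sorted({d for v in per_sample.values() for d in v if d > 0})
    sample_ids = sorted(per_sample)
    rows, ids, labels, diam_col = [], [], [], []
    for day in days:
        for sid in sample_ids:
            if day not in per_sample[sid]:
                raise ValueError(f"missing day-{day} record for sample {sid}")
            item = per_sample[sid][day]
            x = vec(item)
            if wants_delta:
                if 0 not in per_sample[sid]:
                    raise ValueError(f"missing day-0 baseline for sample {sid}")
                x = delta_features(x, vec(per_sample[sid][0]))
            m = meta(item)
            if wants_diam:
                if diameters is not None:
                    d = diameters[sid]
                else:
                    d = m.diameter_mm
                if not np.isfinite(d):
                    raise ValueError(f"missing diameter for sample {sid}")
                diam_col.append(d)
            rows.append(x)
            ids.append(f"{sid}_d{day}")
            labels.append(m.storage)
    X = np.stack(rows)
    names = list(feature_names)
    if wants_diam:
        X = np.column_stack([X, np.asarray(diam_col)])
        names.append("diameter_mm")
    return FeatureTable(
        kind=kind,
        instance_ids=tuple(ids),
        feature_names=tuple(names),
        X=X,
        y=np.asarray(labels),
    )


def split(table: FeatureTable, spec: Optional[SplitSpec] = None
          ) -> Tuple[FeatureTable, FeatureTable]:
    """Stratified, seeded train/test split.

    The train size is ``round(train_fraction * n)`` with ties rounded
    half-up (368 instances at 0.8 give 294 train / 74 test).
    """
    if spec is None:
        spec = SplitSpec()
    n = table.n_instances
    n_train = int(np.floor(spec.train_fraction * n + 0.5))
    if n_train < 1 or n_train >= n:
        raise ValueError("split leaves an empty train or test set")
    strat = table.y if spec.stratify else None
    idx_train, idx_test = train_test_split(
        np.arange(n),
        train_size=n_train,
        stratify=strat,
        random_state=spec.seed,
    )
    idx_train = np.sort(idx_train)
    idx_test = np.sort(idx_test)

    def take(idx: np.ndarray) -> FeatureTable:
        return FeatureTable(
            kind=table.kind,
            instance_ids=tuple(table.instance_ids[i] for i in idx),
            feature_names=table.feature_names,
            X=table.X[idx],
            y=table.y[idx],
        )

    return take(idx_train), take(idx_test)
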