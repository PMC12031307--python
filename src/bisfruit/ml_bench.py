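"""Eight-classifier benchmark with paired Wilcoxon comparison.

Each model family (SVM, LR, MLP, kNN, RF, LDA, NB, DT) is tuned by grid
search under 5x-repeated stratified 10-fold cross-validation on the
training split only; the winning grid point's 50 fold accuracies are
kept as a vector.  Because the fold assignment is seeded and shared
across every grid point, model and dataset, accuracy vectors from two
datasets are paired fold-by-fold, which is the precondition of the
Wilcoxon signed-rank comparison used to assign significance letters
within each dataset family (bioimpedance-based and circuit-parameter
based).  Held-out evaluation refits the winning configuration on the
full training split and reports confusion-matrix metrics.

The exact signed-rank tail (used when at most 25 nonzero differences
remain) is computed by dynamic programming over doubled midranks, which
stays exact in the presence of ties; larger samples fall back to the
normal approximation with continuity correction.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.base import clone
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import ParameterGrid, RepeatedStratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.ensemble import RandomForestClassifier

from .features import FeatureTable

__all__ = [
    "MODEL_FAMILIES",
    "CVSettings",
    "ModelSpec",
    "CVResult",
    "ConfusionMatrix",
    "HoldoutResult",
    "BenchmarkResult",
    "make_cv",
    "fold_assignment_hash",
    "grid_search_cv",
    "wilcoxon_compare",
    "exact_signed_rank_p",
    "assign_letters",
    "confusion_metrics",
    "confusion_from_predictions",
    "evaluate_holdout",
    "pca_embed",
    "run_benchmark",
]

POSITIVE_CLASS = "room"

#: Default hyperparameter grids per family (parameter names are the
#: estimator's own; an empty grid means the family has no tunables here).
MODEL_FAMILIES: Dict[str, Tuple[type, object]] = {
    "SVM": (
        SVC,
        [
            {"kernel": ["linear"], "C": [0.1, 1, 10, 100]},
            {"kernel": ["rbf"], "C": [0.1, 1, 10, 100], "gamma": ["scale", 0.01, 0.001]},
        ],
    ),
    "LR": (LogisticRegression, {"C": [0.01, 0.1, 1, 10]}),
    "MLP": (
        MLPClassifier,
        {"hidden_layer_sizes": [(16,), (32,), (64,)], "alpha": [1e-4, 1e-3]},
    ),
    "kNN": (KNeighborsClassifier, {"n_neighbors": [3, 5, 7, 9, 11]}),
    "RF": (
        RandomForestClassifier,
        {"n_estimators": [100, 300], "max_depth": [None, 5, 10]},
    ),
    "LDA": (LinearDiscriminantAnalysis, {}),
    "NB": (GaussianNB, {}),
    "DT": (DecisionTreeClassifier, {"max_depth": [None, 3, 5, 10]}),
}


@dataclass(frozen=True)
class CVSettings:
    """Repeated stratified k-fold settings (5 x 10 = 50 estimates)."""

    n_repeats: int = 5
    n_folds: int = 10
    seed: int = 0

    @property
    def n_estimates(self) -> int:
        return self.n_repeats * self.n_folds


@dataclass(frozen=True)
class ModelSpec:
    """A model family plus an (optional) custom hyperparameter grid."""

    family: str
    grid: object = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        grid = self.grid if self.grid is not None else MODEL_FAMILIES[self.family][1]
        if isinstance(grid, dict):
            grid = [grid]
        if any(len(ParameterGrid(g)) == 0 for g in grid) and grid != [{}]:
            raise ValueError("hyperparameter grid must be nonempty")
        object.__setattr__(self, "grid", grid)


@dataclass(frozen=True)
class CVResult:
    family: str
    dataset_kind: str
    accuracies: np.ndarray  # one per repeat x fold
    best_params: dict
    fold_hash: str

    def __post_init__(self) -> None:
        acc = np.asarray(self.accuracies, dtype=float)
        if np.any((acc < 0) | (acc > 1)):
            raise ValueError("accuracies must lie in [0, 1]")
        object.__setattr__(self, "accuracies", acc)

    @property
    def mean(self) -> float:
        return float(self.accuracies.mean())

    @property
    def sd(self) -> float:
        return float(self.accuracies.std(ddof=1))


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary counts with the room-storage group as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def swapped(self) -> "ConfusionMatrix":
        """The same matrix with the positive class exchanged."""
        return ConfusionMatrix(tp=self.tn, fp=self.fn, fn=self.fp, tn=self.tp)


@dataclass(frozen=True)
class HoldoutResult:
    family: str
    dataset_kind: str
    best_params: dict
    train_matrix: ConfusionMatrix
    test_matrix: ConfusionMatrix
    train_metrics: dict
    test_metrics: dict


def make_estimator(family: str, params: dict, seed: int = 0):
    """Instantiate a family member with given hyperparameters."""
    cls = MODEL_FAMILIES[family][0]
    kwargs = dict(params)
    if family == "LR":
        kwargs.setdefault("max_iter", 5000)
    if family == "MLP":
        kwargs.setdefault("max_iter", 600)
        kwargs.setdefault("random_state", seed)
    if family in ("RF", "DT"):
        kwargs.setdefault("random_state", seed)
    if family == "SVM":
        kwargs.setdefault("random_state", seed)
        # deterministic iteration budget; large-C linear fits on
        # overlapping classes otherwise dominate the grid's runtime
        kwargs.setdefault("max_iter", 20000)
    return cls(**kwargs)


def _pipeline(family: str, params: dict, seed: int, scale: bool) -> Pipeline:
    steps = []
    if scale:
        steps.append(("scale", StandardScaler()))
    steps.append(("clf", make_estimator(family, params, seed)))
    return Pipeline(steps)


def make_cv(settings: CVSettings) -> RepeatedStratifiedKFold:
    return RepeatedStratifiedKFold(
        n_splits=settings.n_folds,
        n_repeats=settings.n_repeats,
        random_state=settings.seed,
    )


def fold_assignment_hash(y: np.ndarray, settings: CVSettings) -> str:
    """SHA-256 digest of the test-index sequence of every split.

    Depends only on the label vector and the CV seed, so two datasets
    with identical instance ordering share a hash — the pairing
    precondition of the signed-rank comparison.
    """
    cv = make_cv(settings)
    X_dummy = np.zeros((len(y), 1))
    h = hashlib.sha256()
    for _, test_idx in cv.split(X_dummy, y):
        h.update(np.asarray(test_idx, dtype=np.int64).tobytes())
        h.update(b"|")
    return h.hexdigest()


def grid_search_cv(
    train_table: FeatureTable,
    spec: ModelSpec,
    settings: Optional[CVSettings] = None,
    scale: bool = True,
) -> CVResult:
    """Tune one family on the training table; return its best 50-vector.

    Every grid point is evaluated on the identical seeded fold
    assignment; the point with the highest mean accuracy wins (ties
    broken by grid order).  Only the training table is ever seen here.
    """
    if settings is None:
        settings = CVSettings()
    cv = make_cv(settings)
    X, y = train_table.X, train_table.y
    splits = list(cv.split(X, y))
    if any(len(np.unique(y[tr])) < 2 for tr, _ in splits):
        raise ValueError("a CV fold contains a single class; reduce folds")

    best_params: Optional[dict] = None
    best_scores: Optional[np.ndarray] = None
    for params in ParameterGrid(spec.grid):
        model = _pipeline(spec.family, params, spec.seed, scale)
        scores = np.empty(len(splits))
        for k, (tr, te) in enumerate(splits):
            est = clone(model)
            est.fit(X[tr], y[tr])
            scores[k] = float(np.mean(est.predict(X[te]) == y[te]))
        if best_scores is None or scores.mean() > best_scores.mean():
            best_scores, best_params = scores, params
    assert best_scores is not None and best_params is not None
    return CVResult(
        family=spec.family,
        dataset_kind=train_table.kind,
        accuracies=best_scores,
        best_params=best_params,
        fold_hash=fold_assignment_hash(y, settings),
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank comparison


def exact_signed_rank_p(diffs: np.ndarray) -> float:
    """Exact two-sided signed-rank p-value for nonzero differences.

    Ranks |d| with midranks, doubles them to integers, and builds the
    null distribution of W+ (sum of positive-difference ranks) by
    dynamic programming over all 2^n equally likely sign assignments.
    p = min(1, 2 * min(P(W+ <= w), P(W+ >= w))).
    """
    d = np.asarray(diffs, dtype=float)
    if d.size == 0:
        return 1.0
    if np.any(d == 0):
        raise ValueError("zero differences must be removed first")
    ranks = stats.rankdata(np.abs(d))
    doubled = np.round(2 * ranks).astype(int)
    w_plus2 = int(np.sum(doubled[d > 0]))
    total = int(doubled.sum())
    # counts[s] = number of sign assignments with doubled W+ == s
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r > 0 else counts
        counts = counts + shifted
    counts /= counts.sum()
    p_le = counts[: w_plus2 + 1].sum()
    p_ge = counts[w_plus2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


@dataclass(frozen=True)
class WilcoxonComparison:
    p_value: float
    direction: int  # sign of mean(a - b); 0 when identical
    n_nonzero: int
    method: str


def wilcoxon_compare(
    result_a: CVResult | np.ndarray,
    result_b: CVResult | np.ndarray,
    exact_max_n: int = 25,
) -> WilcoxonComparison:
    """Paired two-sided signed-rank test on fold-wise accuracy differences.

    The two results must share the fold structure (same hash) so the 50
    differences are genuinely paired.  Zero differences are discarded
    (Wilcoxon's original convention); all-zero input gives p = 1.  The
    exact tail is used for at most *exact_max_n* nonzero differences,
    otherwise the normal approximation with continuity correction.
    """
    if isinstance(result_a, CVResult) and isinstance(result_b, CVResult):
        if result_a.fold_hash != result_b.fold_hash:
            raise ValueError("results are not paired: fold assignments differ")
        a, b = result_a.accuracies, result_b.accuracies
    else:
        a = np.asarray(result_a, dtype=float)
        b = np.asarray(result_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    direction = int(np.sign(d.mean()))
    d = d[d != 0]
    if d.size == 0:
        return WilcoxonComparison(1.0, 0, 0, "degenerate")
    if d.size <= exact_max_n:
        p = exact_signed_rank_p(d)
        method = "exact"
    else:
        p = float(
            stats.wilcoxon(d, alternative="two-sided", correction=True,
                           method="approx").pvalue
        )
        method = "approx"
    return WilcoxonComparison(p, direction, int(d.size), method)


def assign_letters(p_matrix: np.ndarray, alpha: float = 0.05) -> List[str]:
    """Compact letter display for k conditions from pairwise p-values.

    Conditions sharing a letter are not significantly different at
    *alpha*.  Letters follow the row order (a for the first condition's
    group).  Intransitive patterns yield overlapping letters such as
    "ab".
    """
    p = np.asarray(p_matrix, dtype=float)
    k = p.shape[0]
    if p.shape != (k, k):
        raise ValueError("p_matrix must be square")
    ns = p >= alpha  # non-significant adjacency
    groups: List[set] = []
    for i in range(k):
        placed = False
        for g in groups:
            if all(ns[i, j] for j in g):
                g.add(i)
                placed = True
        if not placed:
            # new group seeded by i, absorbing earlier compatible members so
            # every non-significant pair ends up sharing a letter
            g = {i}
            for j in range(i):
                if ns[i, j] and all(ns[j, m] for m in g):
                    g.add(j)
            groups.append(g)
    # drop groups that became subsets of another
    groups = [g for g in groups if not any(g < h for h in groups)]
    groups.sort(key=min)
    letters = [""] * k
    for idx, g in enumerate(groups):
        letter = chr(ord("a") + idx)
        for i in g:
            letters[i] += letter
    return letters


# ---------------------------------------------------------------------------
# Confusion-matrix metrics


def confusion_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray, positive: str = POSITIVE_CLASS
) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    return ConfusionMatrix(
        tp=int(np.sum((y_true == positive) & (y_pred == positive))),
        fp=int(np.sum((y_true != positive) & (y_pred == positive))),
        fn=int(np.sum((y_true == positive) & (y_pred != positive))),
        tn=int(np.sum((y_true != positive) & (y_pred != positive))),
    )


def confusion_metrics(cm: ConfusionMatrix) -> dict:
    """Accuracy, precision, recall and F1 for the positive class.

    Undefined ratios (empty denominators) are returned as NaN rather
    than raising, so callers can flag them.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    acc = (cm.tp + cm.tn) / cm.total
    prec = cm.tp / (cm.tp + cm.fp) if (cm.tp + cm.fp) > 0 else float("nan")
    rec = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) > 0 else float("nan")
    if np.isnan(prec) or np.isnan(rec) or (prec + rec) == 0:
        f1 = float("nan")
    else:
        f1 = 2 * prec * rec / (prec + rec)
    return {"accuracy": acc, "precision": prec, "recall": rec, "f1": f1}


def confusion_metrics_per_class(cm: ConfusionMatrix) -> dict:
    """Metrics with each class in turn treated as positive."""
    return {"room": confusion_metrics(cm), "cold": confusion_metrics(cm.swapped())}


def evaluate_holdout(
    train_table: FeatureTable,
    test_table: FeatureTable,
    family: str,
    best_params: dict,
    seed: int = 0,
    scale: bool = True,
) -> HoldoutResult:
    """Refit the winning configuration on the full training split.

    Predicts the held-out split exactly once and reports confusion
    matrices and metrics for both splits.
    """
    if train_table.feature_names != test_table.feature_names:
        raise ValueError("train and test tables disagree on features")
    model = _pipeline(family, best_params, seed, scale)
    model.fit(train_table.X, train_table.y)
    cm_train = confusion_from_predictions(train_table.y, model.predict(train_table.X))
    cm_test = confusion_from_predictions(test_table.y, model.predict(test_table.X))
    return HoldoutResult(
        family=family,
        dataset_kind=train_table.kind,
        best_params=dict(best_params),
        train_matrix=cm_train,
        test_matrix=cm_test,
        train_metrics=confusion_metrics(cm_train),
        test_metrics=confusion_metrics(cm_test),
    )


def pca_embed(table: FeatureTable, n_components: int = 3):
    """Principal-component projection for visualization.

    Returns (coordinates, explained-variance fractions).  The table
    should already be normalized; components may not exceed features.
    """
    if n_components > table.n_features:
        raise ValueError("more components than features")
    pca = PCA(n_components=n_components)
    coords = pca.fit_transform(table.X)
    return coords, pca.explained_variance_ratio_


# ---------------------------------------------------------------------------
# Orchestration


@dataclass
class BenchmarkResult:
    """Everything the benchmark produces, keyed by (dataset kind, family)."""

    cv_results: Dict[Tuple[str, str], CVResult]
    pairwise_p: Dict[Tuple[str, str, str, str], float]
    letters: Dict[str, Dict[str, str]]  # letters[model][kind]
    holdout: Dict[Tuple[str, str], HoldoutResult] = field(default_factory=dict)
    fold_hash: str = ""

    def summary_rows(self) -> List[dict]:
        rows = []
        for (kind, family), res in sorted(self.cv_results.items()):
            rows.append(
                {
                    "dataset": kind,
                    "model": family,
                    "mean_accuracy": res.mean,
                    "sd": res.sd,
                    "letter": self.letters.get(family, {}).get(kind, ""),
                    "best_params": res.best_params,
                }
            )
        return rows


DATASET_GROUPS = {
    "bio": ("bio-raw", "bio-delta", "bio-delta-diam"),
    "ec": ("ec-raw", "ec-delta", "ec-delta-diam"),
}


def run_benchmark(
    train_tables: Dict[str, FeatureTable],
    test_tables: Optional[Dict[str, FeatureTable]] = None,
    families: Sequence[str] = tuple(MODEL_FAMILIES),
    settings: Optional[CVSettings] = None,
    holdout_families: Sequence[str] = ("SVM",),
    scale: bool = True,
    alpha: float = 0.05,
    model_seed: int = 0,
) -> BenchmarkResult:
    """Grid-search every family on every training table and compare.

    Letters are assigned per model within each dataset group
    (bioimpedance and circuit-parameter), comparing the group's dataset
    variants pairwise by signed-rank test at *alpha*.  Held-out
    confusion matrices are computed for *holdout_families* when test
    tables are given.
    """
    if settings is None:
        settings = CVSettings()
    cv_results: Dict[Tuple[str, str], CVResult] = {}
    fold_hashes = set()
    for kind, table in train_tables.items():
        for family in families:
            spec = ModelSpec(family=family, seed=model_seed)
            res = grid_search_cv(table, spec, settings, scale=scale)
            cv_results[(kind, family)] = res
            fold_hashes.add(res.fold_hash)
    if len(fold_hashes) != 1:
        raise AssertionError("fold assignment differs across datasets; pairing broken")

    pairwise_p: Dict[Tuple[str, str, str, str], float] = {}
    letters: Dict[str, Dict[str, str]] = {}
    for family in families:
        letters[family] = {}
        for group, kinds in DATASET_GROUPS.items():
            present = [k for k in kinds if (k, family) in cv_results]
            if len(present) < 2:
                continue
            k = len(present)
            p = np.ones((k, k))
            for i in range(k):
                for j in range(i + 1, k):
                    cmp_ = wilcoxon_compare(
                        cv_results[(present[i], family)],
                        cv_results[(present[j], family)],
                    )
                    p[i, j] = p[j, i] = cmp_.p_value
                    pairwise_p[(family, group, present[i], present[j])] = cmp_.p_value
            for kind, letter in zip(present, assign_letters(p, alpha)):
                letters[family][kind] = letter

    holdout: Dict[Tuple[str, str], HoldoutResult] = {}
    if test_tables:
        for kind, train in train_tables.items():
            if kind not in test_tables:
                continue
            for family in holdout_families:
                if (kind, family) not in cv_results:
                    continue
                res = cv_results[(kind, family)]
                holdout[(kind, family)] = evaluate_holdout(
                    train, test_tables[kind], family, res.best_params,
                    seed=model_seed, scale=scale,
                )
    return BenchmarkResult(
        cv_results=cv_results,
        pairwise_p=pairwise_p,
        letters=letters,
        holdout=holdout,
        fold_hash=next(iter(fold_hashes)),
    )
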