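"""Model training: range filter, scaling, RBF-SVM fitting and feature-chain selection.

The classifier is a radial-basis-function SVM.  Before classification a
candidate must pass a *range filter*: a per-parameter window taken at the
0.1/99.9 empirical percentiles of the positive training values, with a hard
override that the ppri-miRNA free energy be below -20 kcal/mol (unstable
precursors are never positives).  Features are min-max scaled to [-1, 1] on
the training data; undefined (component-absent) values map to -1; values out
of range at prediction time are clipped.

A trained :class:`ModelBundle` is self-contained: it stores the selected
parameter names, scaler bounds, range filter, support vectors and dual
coefficients, and evaluates its own decision function, so prediction needs
neither the training data nor scikit-learn internals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Optional, Sequence as Seq

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .features import CATALOG_VERSION, FeatureVector, UNDEFINED, default_catalog, range_filter_names
from .structure import InputError

# LIBSVM-recommended coarse grid
DEFAULT_C_GRID = tuple(2.0 ** k for k in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(2.0 ** k for k in range(-15, 4, 2))
DEFAULT_RANGE_LIMITS = (0.1, 99.9)
DEFAULT_OVERRIDES = {"ppri_mfe": ("lt", -20.0)}


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Metrics:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def sensitivity(self) -> Optional[float]:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def specificity(self) -> Optional[float]:
        d = self.tn + self.fp
        return self.tn / d if d else None


def compute_metrics(tp: int, tn: int, fp: int, fn: int) -> Metrics:
    if min(tp, tn, fp, fn) < 0:
        raise InputError("negative count")
    if tp + tn + fp + fn == 0:
        raise InputError("all counts zero")
    return Metrics(tp=tp, tn=tn, fp=fp, fn=fn)


# ---------------------------------------------------------------------------
# Range filter
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RangeFilter:
    """Closed per-parameter windows plus hard overrides.

    Overrides replace the window with a one-sided bound, e.g.
    ``{"ppri_mfe": ("lt", -20.0)}`` requires ppri_mfe < -20.
    """

    bounds: dict  # name -> (lo, hi)
    overrides: dict  # name -> (op, value); op in {lt, le, gt, ge}
    limits: tuple[float, float] = DEFAULT_RANGE_LIMITS
    percentile_method: str = "linear"

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise InputError(f"{name}: lo {lo} > hi {hi}")


_OPS = {
    "lt": lambda v, b: v < b,
    "le": lambda v, b: v <= b,
    "gt": lambda v, b: v > b,
    "ge": lambda v, b: v >= b,
}


def fit_range_filter(
    vectors: Seq[FeatureVector] | pd.DataFrame,
    params: Seq[str],
    limits: tuple[float, float] = DEFAULT_RANGE_LIMITS,
    overrides: Optional[dict] = None,
) -> RangeFilter:
    """Empirical percentile windows on positive training values.

    Percentiles use linear interpolation between order statistics (the
    method is recorded in the filter so bundles are reproducible).
    Constant parameters give a degenerate window [v, v].  Undefined values
    are ignored when estimating the window.
    """
    if overrides is None:
        overrides = dict(DEFAULT_OVERRIDES)
    df = vectors if isinstance(vectors, pd.DataFrame) else vectors_to_frame(vectors, params)
    bounds = {}
    for name in params:
        if name in overrides:
            continue
        col = pd.to_numeric(df[name], errors="coerce").to_numpy(dtype=float)
        col = col[~np.isnan(col)]
        if col.size == 0:
            continue  # parameter never defined on positives: no window
        lo, hi = np.percentile(col, limits, method="linear")
        bounds[name] = (float(lo), float(hi))
    return RangeFilter(bounds=bounds, overrides=dict(overrides), limits=limits)


def apply_range_filter(rf: RangeFilter, fv: FeatureVector | dict) -> tuple[bool, list[str]]:
    """Candidate passes iff every parameter is inside its closed window and
    every override holds.  Undefined values always pass (absence is legal)."""
    values = fv.values if isinstance(fv, FeatureVector) else fv
    violated = []
    for name, (lo, hi) in rf.bounds.items():
        v = values.get(name, UNDEFINED)
        if v is UNDEFINED or (isinstance(v, float) and np.isnan(v)):
            continue
        if not (lo <= v <= hi):
            violated.append(name)
    for name, (op, bound) in rf.overrides.items():
        v = values.get(name, UNDEFINED)
        if v is UNDEFINED or (isinstance(v, float) and np.isnan(v)):
            continue
        if not _OPS[op](v, bound):
            violated.append(name)
    return (not violated), violated


# ---------------------------------------------------------------------------
# Scaling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureScaler:
    """Min-max scaling to [-1, 1] per parameter.

    Undefined values map to the component-absent code -1; at transform time
    out-of-range values are clipped to [-1, 1].  Constant training columns
    map to 0.
    """

    names: tuple[str, ...]
    mins: tuple[float, ...]
    maxs: tuple[float, ...]

    @classmethod
    def fit(cls, X: pd.DataFrame, names: Seq[str]) -> "FeatureScaler":
        mins, maxs = [], []
        for n in names:
            col = pd.to_numeric(X[n], errors="coerce").to_numpy(dtype=float)
            col = col[~np.isnan(col)]
            if col.size == 0:
                mins.append(0.0)
                maxs.append(0.0)
            else:
                mins.append(float(col.min()))
                maxs.append(float(col.max()))
        return cls(names=tuple(names), mins=tuple(mins), maxs=tuple(maxs))

    def transform(self, X: pd.DataFrame, clip: bool = True) -> np.ndarray:
        out = np.empty((len(X), len(self.names)))
        for k, n in enumerate(self.names):
            col = pd.to_numeric(X[n], errors="coerce").to_numpy(dtype=float)
            lo, hi = self.mins[k], self.maxs[k]
            if hi > lo:
                scaled = 2.0 * (col - lo) / (hi - lo) - 1.0
            else:
                scaled = np.zeros_like(col)
            if clip:
                scaled = np.clip(scaled, -1.0, 1.0)
            scaled[np.isnan(col)] = -1.0
            out[:, k] = scaled
        return out

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        out = np.empty_like(Z, dtype=float)
        for k in range(len(self.names)):
            lo, hi = self.mins[k], self.maxs[k]
            out[:, k] = (Z[:, k] + 1.0) / 2.0 * (hi - lo) + lo if hi > lo else lo
        return out


def vectors_to_frame(vectors: Seq[FeatureVector], names: Seq[str]) -> pd.DataFrame:
    rows = [[np.nan if v is UNDEFINED else v for v in fv.as_numeric(names)] for fv in vectors]
    return pd.DataFrame(rows, columns=list(names))


def dataset_to_xy(dataset, names: Seq[str]) -> tuple[pd.DataFrame, np.ndarray]:
    examples = dataset.examples
    X = vectors_to_frame([ex.features for ex in examples], names)
    y = np.array([ex.label for ex in examples])
    return X, y


# ---------------------------------------------------------------------------
# Model bundle
# ---------------------------------------------------------------------------

@dataclass
class ModelBundle:
    """Everything needed to classify a candidate, in one artifact."""

    group: str
    level: int
    params: tuple[str, ...]
    scaler: FeatureScaler
    range_filter: RangeFilter
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    gamma: float
    C: float
    backend_id: str
    catalog_version: str = CATALOG_VERSION
    cv_accuracy: Optional[float] = None

    def decision_function(self, Z: np.ndarray) -> np.ndarray:
        """Signed RBF decision values for scaled features (positive -> miRNA)."""
        d2 = (
            np.sum(Z**2, axis=1)[:, None]
            + np.sum(self.support_vectors**2, axis=1)[None, :]
            - 2.0 * Z @ self.support_vectors.T
        )
        K = np.exp(-self.gamma * np.maximum(d2, 0.0))
        return K @ self.dual_coef + self.intercept

    def score_vectors(self, vectors: Seq[FeatureVector]) -> np.ndarray:
        X = vectors_to_frame(vectors, self.params)
        return self.decision_function(self.scaler.transform(X))

    def save(self, path) -> None:
        doc = {
            "format": "mirsweep-model-1",
            "group": self.group,
            "level": self.level,
            "params": list(self.params),
            "scaler": {"names": list(self.scaler.names),
                       "mins": list(self.scaler.mins),
                       "maxs": list(self.scaler.maxs)},
            "range_filter": {"bounds": self.range_filter.bounds,
                             "overrides": self.range_filter.overrides,
                             "limits": list(self.range_filter.limits),
                             "percentile_method": self.range_filter.percentile_method},
            "svm": {"support_vectors": self.support_vectors.tolist(),
                    "dual_coef": self.dual_coef.tolist(),
                    "intercept": self.intercept,
                    "gamma": self.gamma,
                    "C": self.C},
            "backend_id": self.backend_id,
            "catalog_version": self.catalog_version,
            "cv_accuracy": self.cv_accuracy,
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def load(cls, path) -> "ModelBundle":
        doc = json.loads(Path(path).read_text())
        rf = doc["range_filter"]
        return cls(
            group=doc["group"],
            level=doc["level"],
            params=tuple(doc["params"]),
            scaler=FeatureScaler(names=tuple(doc["scaler"]["names"]),
                                 mins=tuple(doc["scaler"]["mins"]),
                                 maxs=tuple(doc["scaler"]["maxs"])),
            range_filter=RangeFilter(
                bounds={k: tuple(v) for k, v in rf["bounds"].items()},
                overrides={k: tuple(v) for k, v in rf["overrides"].items()},
                limits=tuple(rf["limits"]),
                percentile_method=rf["percentile_method"],
            ),
            support_vectors=np.array(doc["svm"]["support_vectors"], dtype=float),
            dual_coef=np.array(doc["svm"]["dual_coef"], dtype=float),
            intercept=float(doc["svm"]["intercept"]),
            gamma=float(doc["svm"]["gamma"]),
            C=float(doc["svm"]["C"]),
            backend_id=doc["backend_id"],
            catalog_version=doc["catalog_version"],
            cv_accuracy=doc.get("cv_accuracy"),
        )


# ---------------------------------------------------------------------------
# SVM training
# ---------------------------------------------------------------------------

def _cv_accuracy(Z: np.ndarray, y: np.ndarray, C: float, gamma, k: int,
                 seed: Optional[int]) -> float:
    skf = StratifiedKFold(n_splits=k, shuffle=seed is not None, random_state=seed)
    accs = []
    for train_idx, test_idx in skf.split(Z, y):
        clf = SVC(C=C, gamma=gamma, kernel="rbf")
        clf.fit(Z[train_idx], y[train_idx])
        accs.append(float(np.mean(clf.predict(Z[test_idx]) == y[test_idx])))
    return float(np.mean(accs))


def grid_search(
    Z: np.ndarray,
    y: np.ndarray,
    c_grid: Seq[float] = DEFAULT_C_GRID,
    gamma_grid: Seq[float] = DEFAULT_GAMMA_GRID,
    cv_folds: int = 5,
    seed: Optional[int] = 0,
) -> tuple[float, float, float]:
    """Exhaustive (C, gamma) grid search by cross-validated accuracy.

    Ties break toward smaller C, then smaller gamma.  Returns
    (best_C, best_gamma, best_cv_accuracy).
    """
    best = None
    for C in sorted(c_grid):
        for gamma in sorted(gamma_grid):
            acc = _cv_accuracy(Z, y, C, gamma, cv_folds, seed)
            if best is None or acc > best[2] + 1e-12:
                best = (C, gamma, acc)
    return best


def train_svm(
    X: pd.DataFrame,
    y: np.ndarray,
    params: Seq[str],
    group: str = "other",
    level: int = 1,
    c_grid: Seq[float] = DEFAULT_C_GRID,
    gamma_grid: Seq[float] = DEFAULT_GAMMA_GRID,
    cv_folds: int = 5,
    seed: Optional[int] = 0,
    range_filter: Optional[RangeFilter] = None,
    backend_id: str = "unspecified",
) -> ModelBundle:
    """Scale, grid-search (C, gamma) by CV accuracy, refit on all data.

    ``X`` holds raw (unscaled) features, one column per parameter; ``y`` is
    +1/-1.  ``range_filter`` defaults to one fitted on the positive rows.
    """
    if len(np.unique(y)) < 2:
        raise InputError("training data must contain both classes")
    params = tuple(params)
    scaler = FeatureScaler.fit(X, params)
    Z = scaler.transform(X[list(params)])
    C, gamma, cv_acc = grid_search(Z, y, c_grid, gamma_grid, cv_folds, seed)
    clf = SVC(C=C, gamma=gamma, kernel="rbf")
    clf.fit(Z, y)
    if range_filter is None:
        window_names = [n for n in range_filter_names(default_catalog()) if n in params]
        range_filter = fit_range_filter(X.iloc[np.flatnonzero(y == 1)], window_names)
    # sklearn orders classes [-1, +1]; decision > 0 predicts +1
    return ModelBundle(
        group=group,
        level=level,
        params=params,
        scaler=scaler,
        range_filter=range_filter,
        support_vectors=clf.support_vectors_.copy(),
        dual_coef=clf.dual_coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        gamma=float(clf._gamma),
        C=C,
        backend_id=backend_id,
        cv_accuracy=cv_acc,
    )


def cross_validate(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    k: int,
    C: float = 1.0,
    gamma="scale",
    seed: Optional[int] = 0,
    params: Optional[Seq[str]] = None,
) -> tuple[list[Metrics], Metrics]:
    """Stratified k-fold cross-validation; per-fold metrics and pooled counts.

    Scaling is refit inside every fold so no test information leaks.
    """
    if k < 2:
        raise InputError("k must be >= 2")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise InputError("both classes required")
    if k > counts.min():
        raise InputError(f"k={k} exceeds smallest class size {counts.min()}")
    if isinstance(X, pd.DataFrame):
        names = list(params) if params is not None else list(X.columns)
    else:
        X = pd.DataFrame(np.asarray(X, dtype=float))
        names = list(X.columns)
    skf = StratifiedKFold(n_splits=k, shuffle=seed is not None, random_state=seed)
    folds = []
    pooled = np.zeros(4, dtype=int)  # tp tn fp fn
    for train_idx, test_idx in skf.split(X, y):
        scaler = FeatureScaler.fit(X.iloc[train_idx], names)
        Ztr = scaler.transform(X.iloc[train_idx][names])
        Zte = scaler.transform(X.iloc[test_idx][names])
        clf = SVC(C=C, gamma=gamma, kernel="rbf")
        clf.fit(Ztr, y[train_idx])
        pred = clf.predict(Zte)
        truth = y[test_idx]
        tp = int(np.sum((pred == 1) & (truth == 1)))
        tn = int(np.sum((pred == -1) & (truth == -1)))
        fp = int(np.sum((pred == 1) & (truth == -1)))
        fn = int(np.sum((pred == -1) & (truth == 1)))
        folds.append(compute_metrics(tp, tn, fp, fn))
        pooled += np.array([tp, tn, fp, fn])
    return folds, compute_metrics(*pooled.tolist())


# ---------------------------------------------------------------------------
# Greedy parameter-chain selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SelectionResult:
    curve: tuple[tuple[int, float], ...]  # (chain length, best mean accuracy)
    best_chain: tuple[str, ...]
    best_score: float
    chains_by_length: dict  # length -> beam of (score, chain)


def greedy_parameter_selection(
    pos_sets: Seq[pd.DataFrame],
    neg_sets: Seq[pd.DataFrame],
    pool: Optional[Seq[str]] = None,
    beam: int = 10,
    max_len: Optional[int] = None,
    cv_folds: int = 5,
    C: float = 1.0,
    gamma="scale",
) -> SelectionResult:
    """Beam-searched forward selection of feature chains.

    Stage 1 scores every single parameter by SVM accuracy averaged over the
    paired (positive, negative) subsets and keeps the ``beam`` best as seeds.
    Each later stage extends every kept chain by every unused parameter and
    keeps the ``beam`` best chains of the new length, until the pool is
    exhausted (or ``max_len``).  Scoring is deterministic (no shuffling);
    ties at the beam boundary keep the lexicographically smallest chain.
    Returns the accuracy-vs-length curve and the argmax-length chain.
    """
    if len(pos_sets) != len(neg_sets) or not pos_sets:
        raise InputError("need equally many positive and negative subsets")
    if pool is None:
        pool = list(pos_sets[0].columns)
    pool = sorted(pool)
    if len(pool) < 2:
        raise InputError("pool must contain at least 2 parameters")

    # per-column [-1,1] scaling is chain-independent, so each paired dataset
    # is scaled once up front and chains just slice columns
    col_idx = {p: k for k, p in enumerate(pool)}
    datasets = []
    for P, N in zip(pos_sets, neg_sets):
        X = pd.concat([P[pool], N[pool]], ignore_index=True)
        y = np.concatenate([np.ones(len(P)), -np.ones(len(N))])
        Z = FeatureScaler.fit(X, pool).transform(X)
        datasets.append((Z, y))

    # CV accuracy depends on the feature *set*, not the chain order, so the
    # cache is keyed by set and permuted chains are exact ties
    cache: dict[frozenset, float] = {}

    def score(chain: tuple[str, ...]) -> float:
        key = frozenset(chain)
        if key in cache:
            return cache[key]
        idx = sorted(col_idx[p] for p in chain)
        accs = [
            _cv_accuracy(Z[:, idx], y, C, gamma, cv_folds, seed=None)
            for Z, y in datasets
        ]
        cache[key] = float(np.mean(accs))
        return cache[key]

    limit = len(pool) if max_len is None else min(max_len, len(pool))
    scored = sorted(((score((p,)), (p,)) for p in pool), key=lambda t: (-t[0], t[1]))
    beams = {1: scored[:beam]}
    curve = [(1, scored[0][0])]

    length = 1
    while length < limit:
        candidates: dict[frozenset, tuple[float, tuple[str, ...]]] = {}
        for _, chain in beams[length]:
            used = set(chain)
            for p in pool:
                if p in used:
                    continue
                new = chain + (p,)
                key = frozenset(new)
                sc = score(new)
                # permutations of one set are ties: keep the smallest chain
                if key not in candidates or new < candidates[key][1]:
                    candidates[key] = (sc, new)
        scored = sorted(candidates.values(), key=lambda t: (-t[0], t[1]))
        length += 1
        beams[length] = scored[:beam]
        curve.append((length, scored[0][0]))

    best_len, best_score = max(curve, key=lambda t: (t[1], -t[0]))
    best_chain = beams[best_len][0][1]
    return SelectionResult(
        curve=tuple(curve),
        best_chain=best_chain,
        best_score=best_score,
        chains_by_length=beams,
    )
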