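"""The classification protocol: information-gain selection, SVM grid search,
stratified hold-out, LOOCV, repeated hold-out, and the sample-size bound.

The protocol is fixed across biomarkers so their predictive value can be
compared: features are ranked by information gain on the *training rows
only* and the top k (default 5) kept; an RBF-kernel SVM is tuned by grid
search over log10 C = −3…8 and log10 γ = −3…3 (unit steps) using stratified
5-fold CV accuracy on the training set alone; the selected model is refit on
the full training set and produces per-class membership scores on the test
set via pairwise coupling.  Feature selection and model selection happen
inside every resampling loop, so no information from held-out subjects can
leak into training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.model_selection import LeaveOneOut, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "FeatureTable",
    "SplitPlan",
    "ModelSelectionGrid",
    "TrainedModel",
    "information_gain",
    "select_top_k",
    "stratified_split",
    "grid_search_train",
    "predict_scores",
    "loocv",
    "repeated_holdout",
    "sample_size_bound",
    "CLASSIFIERS",
]


@dataclass
class FeatureTable:
    """Named numeric features per subject, aligned with group labels."""

    features: pd.DataFrame  # index: subject_id, columns: feature names
    labels: pd.Series  # index: subject_id
    name: str = "features"

    def __post_init__(self) -> None:
        if not self.features.index.equals(self.labels.index):
            self.labels = self.labels.reindex(self.features.index)
        if self.labels.isna().any():
            raise ValueError("missing label for some subjects")
        if self.features.isna().any().any():
            raise ValueError("feature table contains missing values")

    def subset(self, idx: np.ndarray) -> "FeatureTable":
        return FeatureTable(self.features.iloc[idx], self.labels.iloc[idx], self.name)


@dataclass(frozen=True)
class SplitPlan:
    """Stratified train/test split: per class, floor(train_fraction * n) train."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int
    train_fraction: float = 0.75


@dataclass(frozen=True)
class ModelSelectionGrid:
    """Integer log10 exponent grids for the SVM penalty C and RBF width γ."""

    log10_C: tuple[int, ...] = tuple(range(-3, 9))
    log10_gamma: tuple[int, ...] = tuple(range(-3, 4))

    def __post_init__(self) -> None:
        if not self.log10_C or not self.log10_gamma:
            raise ValueError("grid ranges must be nonempty")

    @property
    def n_points(self) -> int:
        return len(self.log10_C) * len(self.log10_gamma)


#: reduced grid useful for simulation studies where the full 84-point grid
#: would dominate runtime
REDUCED_GRID = ModelSelectionGrid(log10_C=(-1, 1, 3), log10_gamma=(-2, 0))


@dataclass
class TrainedModel:
    """Outcome of selection + grid search, refit on the full training set."""

    selected_features: list[str]
    params: dict
    cv_score: float
    estimator: Pipeline
    classes: np.ndarray


def _entropy(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _equal_frequency_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Discretize by quantile bin edges, lowering the bin count until every
    nonempty bin holds at least 2 samples."""
    for b in range(n_bins, 1, -1):
        edges = np.unique(np.quantile(x, np.linspace(0, 1, b + 1)[1:-1]))
        binned = np.searchsorted(edges, x, side="right")
        counts = np.bincount(binned)
        if counts[counts > 0].min() >= 2:
            return binned
    return np.zeros(len(x), dtype=np.int64)


def information_gain(values: np.ndarray, labels: np.ndarray, n_bins: int = 10) -> float:
    """Information gain (bits) of a feature about the class labels.

    Continuous values are discretized by equal-frequency binning (default
    10 bins, reduced until each bin has >= 2 samples).  Gain is
    H(labels) − Σ_b p(b) H(labels | bin b), bounded by [0, H(labels)].
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if len(values) != len(labels) or len(values) < 2:
        raise ValueError("need >= 2 aligned samples")
    base = _entropy(labels)
    if base == 0.0:
        warnings.warn("single class: information gain is 0", stacklevel=2)
        return 0.0
    binned = _equal_frequency_bins(values, n_bins)
    cond = 0.0
    for b in np.unique(binned):
        in_bin = binned == b
        cond += in_bin.mean() * _entropy(labels[in_bin])
    return float(max(0.0, min(base, base - cond)))


def select_top_k(table: FeatureTable, k: int = 5, n_bins: int = 10) -> FeatureTable:
    """Keep the k features with highest information gain (ties: original order)."""
    n_feat = table.features.shape[1]
    if k > n_feat:
        raise ValueError(f"k={k} exceeds feature count {n_feat}")
    gains = np.array(
        [information_gain(table.features[c].to_numpy(), table.labels.to_numpy(), n_bins)
         for c in table.features.columns]
    )
    order = np.argsort(-gains, kind="stable")[:k]
    keep = table.features.columns[order]
    return FeatureTable(table.features[keep], table.labels, table.name)


def stratified_split(
    labels: np.ndarray | pd.Series, train_fraction: float = 0.75, seed: int = 0
) -> SplitPlan:
    """Per class, floor(train_fraction * n_c) randomly chosen training subjects."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 members")
        n_train = int(np.floor(train_fraction * len(idx)))
        if n_train >= len(idx):
            raise ValueError("empty test set for class " + str(cls))
        if n_train == 0:
            raise ValueError("empty training set for class " + str(cls))
        perm = rng.permutation(idx)
        train.extend(perm[:n_train])
        test.extend(perm[n_train:])
    return SplitPlan(
        train_idx=np.sort(np.array(train)),
        test_idx=np.sort(np.array(test)),
        seed=seed,
        train_fraction=train_fraction,
    )


def _fit_quietly(est: Pipeline, X: np.ndarray, y: np.ndarray) -> Pipeline:
    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=ConvergenceWarning)
        est.fit(X, y)
    return est


def _make_estimator(spec: str, params: dict, seed: int) -> Pipeline:
    # libsvm can spin effectively forever at the grid's largest C values on
    # overlapping classes; a generous iteration cap keeps every fit bounded
    # without affecting converged solutions
    if spec == "rbf_svm":
        clf = SVC(kernel="rbf", C=params["C"], gamma=params["gamma"],
                  decision_function_shape="ovo", random_state=seed,
                  max_iter=100_000)
    elif spec == "linear_svm":
        clf = SVC(kernel="linear", C=params["C"],
                  decision_function_shape="ovo", random_state=seed,
                  max_iter=100_000)
    elif spec == "nbayes":
        clf = GaussianNB()
    else:
        raise ValueError(f"unknown classifier spec {spec!r}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def _couple_pairwise(decisions: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """Class membership scores from one-vs-one SVM decision values.

    Each pairwise decision is mapped through a unit-slope sigmoid to a
    pairwise probability r_ij = P(class i | i or j), then the per-class
    scores p solve the pairwise-coupling least-squares problem
    min ½ Σ_i Σ_{j≠i} (r_ji p_i − r_ij p_j)² subject to Σ p = 1
    (Wu–Lin–Weng second method), which has a closed-form KKT solution.
    Deterministic, and consistent with pairwise voting on separable data.
    """
    n_samples = decisions.shape[0] if decisions.ndim == 2 else len(decisions)
    K = len(classes)
    if K == 2:
        d = decisions.reshape(n_samples)
        # sklearn binary convention: positive decision favors classes_[1]
        p1 = expit(d)
        return np.column_stack([1.0 - p1, p1])
    pairs = [(i, j) for i in range(K) for j in range(i + 1, K)]
    out = np.zeros((n_samples, K))
    for s in range(n_samples):
        R = np.full((K, K), 0.5)
        for col, (i, j) in enumerate(pairs):
            # ovo convention: positive decision favors class i of pair (i, j)
            r_ij = expit(decisions[s, col])
            R[i, j] = r_ij
            R[j, i] = 1.0 - r_ij
        Q = np.zeros((K, K))
        for i in range(K):
            Q[i, i] = sum(R[j, i] ** 2 for j in range(K) if j != i)
            for j in range(K):
                if j != i:
                    Q[i, j] = -R[j, i] * R[i, j]
        kkt = np.zeros((K + 1, K + 1))
        kkt[:K, :K] = Q
        kkt[:K, K] = 1.0
        kkt[K, :K] = 1.0
        rhs = np.zeros(K + 1)
        rhs[K] = 1.0
        sol = np.linalg.solve(kkt, rhs)
        out[s] = np.clip(sol[:K], 0.0, None)
        out[s] /= out[s].sum()
    return out


def _grid_points(spec: str, grid: ModelSelectionGrid):
    """Candidate parameter dicts in tie-break order (smaller C, then smaller γ)."""
    if spec == "rbf_svm":
        return [
            {"C": 10.0**c, "gamma": 10.0**g}
            for c in sorted(grid.log10_C)
            for g in sorted(grid.log10_gamma)
        ]
    if spec == "linear_svm":
        return [{"C": 10.0**c} for c in sorted(grid.log10_C)]
    if spec == "nbayes":
        return [{}]
    raise ValueError(f"unknown classifier spec {spec!r}")


def _cv_splitter(labels: np.ndarray, seed: int):
    """Stratified 5-fold, falling back to 3-fold then leave-one-out when the
    smallest training class cannot fill the folds."""
    min_class = np.bincount(pd.factorize(labels)[0]).min()
    if min_class >= 5:
        return StratifiedKFold(5, shuffle=True, random_state=seed)
    if min_class >= 3:
        warnings.warn("small class: falling back to 3-fold CV", stacklevel=3)
        return StratifiedKFold(3, shuffle=True, random_state=seed)
    warnings.warn("very small class: falling back to leave-one-out CV", stacklevel=3)
    return LeaveOneOut()


#: classifier specs accepted by the protocol (mirrors the classifier comparison)
CLASSIFIERS = ("rbf_svm", "linear_svm", "nbayes")


def grid_search_train(
    table: FeatureTable,
    grid: ModelSelectionGrid | None = None,
    classifier: str = "rbf_svm",
    k_features: int = 5,
    seed: int = 0,
    n_bins: int = 10,
) -> TrainedModel:
    """Feature selection + grid search on the training table alone.

    Information-gain selection runs first (training rows only), then every
    grid point is scored by stratified 5-fold CV accuracy; the best point
    (ties toward smaller C, then smaller γ) is refit on all training rows
    ; test-time scores come from pairwise coupling of its decision values.
    """
    grid = grid or ModelSelectionGrid()
    k = min(k_features, table.features.shape[1])
    selected = select_top_k(table, k=k, n_bins=n_bins)
    X = selected.features.to_numpy()
    y = selected.labels.to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain >= 2 classes")

    best_score, best_params = -np.inf, None
    splitter = _cv_splitter(y, seed)
    folds = list(splitter.split(X, y))
    for params in _grid_points(classifier, grid):
        correct = 0
        for tr, va in folds:
            est = _make_estimator(classifier, params, seed)
            _fit_quietly(est, X[tr], y[tr])
            correct += int((est.predict(X[va]) == y[va]).sum())
        score = correct / len(y)
        if score > best_score:
            best_score, best_params = score, params

    final = _make_estimator(classifier, best_params, seed)
    _fit_quietly(final, X, y)
    return TrainedModel(
        selected_features=list(selected.features.columns),
        params=best_params,
        cv_score=float(best_score),
        estimator=final,
        classes=final.classes_,
    )


def predict_scores(model: TrainedModel, features: pd.DataFrame) -> pd.DataFrame:
    """Per-class membership scores (rows sum to 1) from pairwise coupling."""
    missing = [c for c in model.selected_features if c not in features.columns]
    if missing:
        raise ValueError(f"missing selected feature columns: {missing}")
    X = features[model.selected_features].to_numpy()
    clf = model.estimator.named_steps["clf"]
    if hasattr(clf, "predict_proba"):  # naive Bayes baseline
        proba = model.estimator.predict_proba(X)
    else:
        decisions = model.estimator.decision_function(X)
        proba = _couple_pairwise(np.atleast_1d(decisions), model.classes)
    return pd.DataFrame(proba, index=features.index, columns=model.classes)


def loocv(
    table: FeatureTable,
    grid: ModelSelectionGrid | None = None,
    classifier: str = "rbf_svm",
    k_features: int = 5,
    seed: int = 0,
) -> tuple[pd.Series, pd.DataFrame]:
    """Leave-one-out CV with selection and grid search repeated in every fold."""
    n = len(table.features)
    if n < 3:
        raise ValueError("need >= 3 subjects for LOOCV")
    preds, scores = [], []
    for i in range(n):
        keep = np.setdiff1d(np.arange(n), [i])
        model = grid_search_train(
            table.subset(keep), grid=grid, classifier=classifier,
            k_features=k_features, seed=seed,
        )
        s = predict_scores(model, table.features.iloc[[i]])
        scores.append(s)
        preds.append(s.columns[int(np.argmax(s.to_numpy()))])
    scores = pd.concat(scores)
    return pd.Series(preds, index=table.features.index, name="predicted"), scores


def repeated_holdout(
    table: FeatureTable,
    grid: ModelSelectionGrid | None = None,
    classifier: str = "rbf_svm",
    k_features: int = 5,
    n_reps: int = 10,
    train_fraction: float = 0.75,
    seed: int = 0,
) -> dict:
    """``n_reps`` independent split → train → test runs.

    Returns the per-repetition evaluation reports and the mean/SD of the
    weighted multi-class AUC across repetitions.
    """
    from . import evaluation  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_reps)
    reports = []
    for rs in rep_seeds:
        plan = stratified_split(table.labels.to_numpy(), train_fraction, int(rs))
        model = grid_search_train(
            table.subset(plan.train_idx), grid=grid, classifier=classifier,
            k_features=k_features, seed=int(rs),
        )
        test = table.subset(plan.test_idx)
        scores = predict_scores(model, test.features)
        reports.append(evaluation.evaluate_multiclass(scores, test.labels))
    aucs = np.array([r.weighted_auc for r in reports])
    return {
        "reports": reports,
        "weighted_auc_mean": float(aucs.mean()),
        "weighted_auc_sd": float(aucs.std(ddof=1)) if n_reps > 1 else 0.0,
        "seeds": [int(s) for s in rep_seeds],
    }


def sample_size_bound(d: int, p_e: float) -> float:
    """Minimum total sample size N_min = d / (2 p_e) for d features at error p_e."""
    if d < 1:
        raise ValueError("d must be >= 1")
    if not 0 < p_e < 1:
        raise ValueError("p_e must lie strictly between 0 and 1")
    return d / (2.0 * p_e)
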