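"""Within-subject paired-contrast classification.

Speaker baselines are removed by classifying signed feature differences:
condition A vs B within a subject becomes (A - B) vs (B - A), so each
subject contributes one antisymmetric pair of samples and chance accuracy
is exactly 50%.  Discriminability is estimated by nested
leave-one-participant-out cross-validation: the outer loop holds out both
samples of one subject; an inner grouped cross-validation over the training
subjects selects the feature count (t-test ranking) and the classifier
(linear SVM without intercept, nearest neighbors, random forest) together
with its hyperparameters.  Significance of the pooled held-out accuracy is
assessed with a one-sided exact binomial test against 0.5.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

warnings.filterwarnings("ignore",
                        message="X does not have valid feature names")
import pandas as pd
from scipy import stats
from sklearn import config_context
from sklearn.svm import LinearSVC

log = logging.getLogger(__name__)

#: Feature-count grid searched by the inner loop (clipped to dimensionality).
DEFAULT_FEATURE_GRID = (1, 2, 5, 13, 34, 89, 126)
DEFAULT_SVM_C = (0.01, 0.1, 1.0, 10.0)
DEFAULT_KNN_K = (1, 3, 5)
DEFAULT_RF_TREES = 100
DEFAULT_INNER_SPLITS = 3


class _NearestNeighbors:
    """Minimal k-nearest-neighbor classifier (Euclidean, majority vote).

    Functionally equivalent to the standard implementation at these sample
    sizes but without per-call estimator overhead, which dominates inside
    the nested CV loop.
    """

    def __init__(self, n_neighbors: int):
        self.k = n_neighbors

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_NearestNeighbors":
        self.X_, self.y_ = np.asarray(X, float), np.asarray(y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        d = ((np.asarray(X, float)[:, None, :] - self.X_[None]) ** 2).sum(-1)
        k = min(self.k, len(self.y_))
        nn = np.argpartition(d, k - 1, axis=1)[:, :k]
        votes = self.y_[nn].sum(axis=1)
        # even-split ties go to the overall nearest neighbor
        nearest = self.y_[d.argmin(axis=1)]
        return np.where(votes == 0, nearest, np.sign(votes)).astype(int)


def _make_random_forest(n_trees: int, n_features: int, seed: int):
    """Random forest (bagged trees with sqrt-feature subsampling)."""
    import lightgbm as lgb

    frac = max(np.sqrt(n_features) / n_features, 1.0 / n_features)
    return lgb.LGBMClassifier(
        boosting_type="rf", n_estimators=n_trees,
        bagging_freq=1, bagging_fraction=0.8,
        feature_fraction=min(max(frac, 0.05), 1.0),
        num_leaves=15, min_child_samples=2, n_jobs=1,
        random_state=seed, verbose=-1)


@dataclass
class ContrastData:
    """Signed difference samples for one condition pair and task."""

    X: np.ndarray                 # (2 * n_subjects, n_features)
    y: np.ndarray                 # +1 for (A-B), -1 for (B-A)
    subjects: np.ndarray          # subject id per sample
    feature_names: list[str]
    contrast: tuple[str, str]
    task: str

    @property
    def n_subjects(self) -> int:
        return len(np.unique(self.subjects))


@dataclass
class FoldResult:
    subject: str
    n_features: int
    classifier: str
    params: dict
    inner_accuracy: float
    predictions: list[int]
    truths: list[int]

    @property
    def n_correct(self) -> int:
        return int(np.sum(np.asarray(self.predictions)
                          == np.asarray(self.truths)))


@dataclass
class CVResult:
    folds: list[FoldResult]
    accuracy: float
    n_correct: int
    n_total: int
    p_value: float
    contrast: tuple[str, str] = ("A", "B")
    task: str = ""

    def to_dict(self) -> dict:
        return {
            "contrast": list(self.contrast), "task": self.task,
            "accuracy": self.accuracy, "n_correct": self.n_correct,
            "n_total": self.n_total, "p_value": self.p_value,
            "folds": [asdict(f) for f in self.folds],
        }


class Standardizer:
    """Column z-transform with training-set parameters (sd uses n-1).

    Zero-variance columns are dropped for the fold (their indices are kept
    so test rows can be subset identically).
    """

    def fit(self, X: np.ndarray) -> "Standardizer":
        self.mean_ = X.mean(axis=0)
        self.sd_ = X.std(axis=0, ddof=1) if len(X) > 1 else np.ones(X.shape[1])
        self.keep_ = self.sd_ > 0
        if not self.keep_.all():
            log.debug("dropping %d zero-variance columns",
                      int((~self.keep_).sum()))
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        Z = (X[:, self.keep_] - self.mean_[self.keep_]) / self.sd_[self.keep_]
        return Z


def standardize(X_train: np.ndarray, X_test: np.ndarray | None = None):
    """Convenience wrapper: fit on training rows, apply to both."""
    sc = Standardizer().fit(X_train)
    if X_test is None:
        return sc.transform(X_train), sc
    return sc.transform(X_train), sc.transform(X_test), sc


def make_contrasts(table: pd.DataFrame, condition_a: str, condition_b: str,
                   task: str, feature_columns: list[str] | None = None
                   ) -> ContrastData:
    """Build the antisymmetric (A-B)/(B-A) samples from a feature table.

    ``table`` has one row per (subject_id, condition, task) and feature
    columns.  Subjects missing either condition for the task are excluded
    (logged), mirroring the all-recordings-usable rule.
    """
    cols = feature_columns or [c for c in table.columns
                               if c.split("-")[0] in ("A", "S", "P")]
    sub = table[table["task"] == task]
    rows_a = sub[sub["condition"] == condition_a].set_index("subject_id")
    rows_b = sub[sub["condition"] == condition_b].set_index("subject_id")
    subjects = sorted(set(rows_a.index) & set(rows_b.index))
    dropped = sorted(set(rows_a.index) ^ set(rows_b.index))
    if dropped:
        log.warning("excluding subjects missing a condition row: %s", dropped)
    if not subjects:
        raise ValueError(f"no subject has both {condition_a} and "
                         f"{condition_b} rows for task {task!r}")
    X, y, sids = [], [], []
    for sid in subjects:
        d = (rows_a.loc[sid, cols].to_numpy(dtype=float)
             - rows_b.loc[sid, cols].to_numpy(dtype=float))
        X.extend([d, -d])
        y.extend([1, -1])
        sids.extend([sid, sid])
    return ContrastData(X=np.asarray(X), y=np.asarray(y),
                        subjects=np.asarray(sids), feature_names=list(cols),
                        contrast=(condition_a, condition_b), task=task)


def rank_features(X: np.ndarray, y: np.ndarray,
                  feature_names: list[str] | None = None) -> np.ndarray:
    """Feature order by ascending two-sample t-test p-value (+1 vs -1 class).

    Ties are broken by lexicographic feature name.
    """
    a, b = X[y == 1], X[y == -1]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both classes must be present for ranking")
    na, nb = len(a), len(b)
    va = a.var(axis=0, ddof=1) if na > 1 else np.zeros(X.shape[1])
    vb = b.var(axis=0, ddof=1) if nb > 1 else np.zeros(X.shape[1])
    pooled = ((na - 1) * va + (nb - 1) * vb) / max(na + nb - 2, 1)
    se = np.sqrt(pooled * (1 / na + 1 / nb))
    t = np.where(se > 0, (a.mean(axis=0) - b.mean(axis=0)) / np.maximum(se, 1e-300), 0.0)
    p = 2 * stats.t.sf(np.abs(t), df=na + nb - 2)
    names = feature_names or [f"f{i:04d}" for i in range(X.shape[1])]
    order = sorted(range(X.shape[1]), key=lambda i: (p[i], names[i]))
    return np.asarray(order)


def _classifier_grid(seed: int, svm_c=DEFAULT_SVM_C, knn_k=DEFAULT_KNN_K,
                     rf_trees=DEFAULT_RF_TREES):
    """Ordered (id, params, factory) triples; order is the tie-break order.

    Factories take the number of selected features (the forest's feature
    subsampling fraction depends on it).
    """
    grid = []
    for c in svm_c:
        grid.append(("svm", {"C": c},
                     lambda nf, c=c: LinearSVC(C=c, fit_intercept=False,
                                               max_iter=20000)))
    for k in knn_k:
        grid.append(("knn", {"n_neighbors": k},
                     lambda nf, k=k: _NearestNeighbors(n_neighbors=k)))
    grid.append(("rf", {"n_estimators": rf_trees},
                 lambda nf: _make_random_forest(rf_trees, nf, seed)))
    return grid


def _inner_folds(subjects: np.ndarray, scheme: str,
                 rng: np.random.Generator) -> list[np.ndarray]:
    """Partition of unique subjects into validation groups."""
    uniq = np.unique(subjects)
    if scheme == "lopo":
        return [np.array([s]) for s in uniq]
    if scheme.startswith("kfold:"):
        k = int(scheme.split(":")[1])
        k = min(k, len(uniq))
        perm = rng.permutation(uniq)
        return [perm[i::k] for i in range(k)]
    raise ValueError(f"unknown inner CV scheme {scheme!r}")


def _select_model(X: np.ndarray, y: np.ndarray, subjects: np.ndarray,
                  feature_names: list[str], feature_grid, grid, scheme: str,
                  rng: np.random.Generator):
    """Inner loop: mean validation accuracy per (config, feature count)."""
    ks = sorted({min(k, X.shape[1]) for k in feature_grid})
    scores = np.zeros((len(grid), len(ks)))
    counts = np.zeros((len(grid), len(ks)))
    with config_context(assume_finite=True):
        for val_subjects in _inner_folds(subjects, scheme, rng):
            val = np.isin(subjects, val_subjects)
            tr = ~val
            if len(np.unique(y[tr])) < 2:
                continue
            sc = Standardizer().fit(X[tr])
            Xtr, Xval = sc.transform(X[tr]), sc.transform(X[val])
            kept_names = [n for n, k in zip(feature_names, sc.keep_) if k]
            order = rank_features(Xtr, y[tr], kept_names)
            for ki, k in enumerate(ks):
                sel = order[:min(k, Xtr.shape[1])]
                Xtr_k, Xval_k = Xtr[:, sel], Xval[:, sel]
                for gi, (_, _, factory) in enumerate(grid):
                    clf = factory(len(sel)).fit(Xtr_k, y[tr])
                    acc = float(np.mean(clf.predict(Xval_k) == y[val]))
                    scores[gi, ki] += acc * val.sum()
                    counts[gi, ki] += val.sum()
    mean_acc = np.divide(scores, counts, out=np.zeros_like(scores),
                         where=counts > 0)
    # best accuracy; ties -> smallest feature count, then classifier order
    best = None
    for ki, k in enumerate(ks):
        for gi in range(len(grid)):
            cand = (mean_acc[gi, ki], -ki, -gi)
            if best is None or cand > best[0]:
                best = ((mean_acc[gi, ki], -ki, -gi), gi, ki)
    _, gi, ki = best
    return gi, ks[ki], float(mean_acc[gi, ki])


def nested_lopo_cv(data: ContrastData,
                   feature_grid=DEFAULT_FEATURE_GRID,
                   svm_c=DEFAULT_SVM_C, knn_k=DEFAULT_KNN_K,
                   rf_trees=DEFAULT_RF_TREES,
                   inner_cv: str = f"kfold:{DEFAULT_INNER_SPLITS}",
                   seed: int = 0) -> CVResult:
    """Nested leave-one-participant-out cross-validation.

    The outer loop holds out both antisymmetric samples of one subject (they
    always co-travel, which is asserted); the inner loop selects feature
    count and classifier on the training subjects only.  Accuracy is the
    fraction of held-out samples predicted correctly over all folds.
    """
    X, y, subjects = data.X, data.y, data.subjects
    uniq = np.unique(subjects)
    if len(uniq) < 3:
        raise ValueError("nested CV requires at least 3 subjects")
    rng = np.random.default_rng(seed)
    grid = _classifier_grid(seed, svm_c, knn_k, rf_trees)

    folds: list[FoldResult] = []
    for sid in uniq:
        test = subjects == sid
        train = ~test
        assert test.sum() == 2 and len(np.unique(y[test])) == 2, \
            "both antisymmetric samples of a subject must co-travel"
        gi, k, inner_acc = _select_model(
            X[train], y[train], subjects[train], data.feature_names,
            feature_grid, grid, inner_cv, rng)
        sc = Standardizer().fit(X[train])
        Xtr, Xte = sc.transform(X[train]), sc.transform(X[test])
        kept_names = [n for n, kp in zip(data.feature_names, sc.keep_) if kp]
        order = rank_features(Xtr, y[train], kept_names)
        sel = order[:min(k, Xtr.shape[1])]
        cid, params, factory = grid[gi]
        clf = factory(len(sel)).fit(Xtr[:, sel], y[train])
        preds = clf.predict(Xte[:, sel])
        folds.append(FoldResult(subject=str(sid), n_features=int(k),
                                classifier=cid, params=dict(params),
                                inner_accuracy=inner_acc,
                                predictions=[int(p) for p in preds],
                                truths=[int(t) for t in y[test]]))
    n_correct = sum(f.n_correct for f in folds)
    n_total = sum(len(f.truths) for f in folds)
    accuracy = n_correct / n_total
    return CVResult(folds=folds, accuracy=accuracy, n_correct=n_correct,
                    n_total=n_total,
                    p_value=binomial_significance(n_correct, n_total),
                    contrast=data.contrast, task=data.task)


def binomial_significance(n_correct: int, n_total: int) -> float:
    """One-sided exact binomial tail P(X >= n_correct | n_total, 1/2)."""
    if not 0 <= n_correct <= n_total:
        raise ValueError("n_correct must lie in [0, n_total]")
    return float(stats.binomtest(n_correct, n_total, p=0.5,
                                 alternative="greater").pvalue)


def weight_profile(weights: np.ndarray,
                   feature_names: list[str] | None = None,
                   display_threshold: float = 0.10) -> pd.Series:
    """Relative feature contributions: |w| normalized to sum to 1.

    The 10% display threshold is applied only by report writers, never here.
    """
    w = np.abs(np.asarray(weights, dtype=float))
    total = w.sum()
    if total == 0:
        raise ValueError("all weights are zero: no contribution profile")
    names = feature_names or [f"f{i:04d}" for i in range(len(w))]
    return pd.Series(w / total, index=names)


# ---------------------------------------------------------------------------
# transfer to an external cohort
# ---------------------------------------------------------------------------

@dataclass
class FrozenModel:
    """A trained contrast classifier with frozen standardization."""

    classifier: object
    classifier_id: str
    params: dict
    scaler: Standardizer
    selected: np.ndarray              # indices into kept (post-scaler) columns
    feature_names: list[str]          # full training column list
    contrast: tuple[str, str]
    task: str
    inner_accuracy: float = np.nan

    @property
    def selected_features(self) -> list[str]:
        kept = [n for n, k in zip(self.feature_names, self.scaler.keep_) if k]
        return [kept[i] for i in self.selected]


def train_contrast_model(data: ContrastData,
                         feature_mask: list[str] | None = None,
                         feature_grid=DEFAULT_FEATURE_GRID,
                         svm_c=DEFAULT_SVM_C, knn_k=DEFAULT_KNN_K,
                         rf_trees=DEFAULT_RF_TREES,
                         inner_cv: str = f"kfold:{DEFAULT_INNER_SPLITS}",
                         seed: int = 0) -> FrozenModel:
    """Select and fit one final model on the whole cohort.

    ``feature_mask`` names features to *remove* before training (e.g. all
    acoustic features when the external cohort has no audio).
    """
    keep_cols = [i for i, n in enumerate(data.feature_names)
                 if not feature_mask or n not in set(feature_mask)]
    if not keep_cols:
        raise ValueError("feature mask removes every feature")
    X = data.X[:, keep_cols]
    names = [data.feature_names[i] for i in keep_cols]
    rng = np.random.default_rng(seed)
    grid = _classifier_grid(seed, svm_c, knn_k, rf_trees)
    gi, k, inner_acc = _select_model(X, data.y, data.subjects, names,
                                     feature_grid, grid, inner_cv, rng)
    sc = Standardizer().fit(X)
    Xz = sc.transform(X)
    kept_names = [n for n, kp in zip(names, sc.keep_) if kp]
    order = rank_features(Xz, data.y, kept_names)
    sel = order[:min(k, Xz.shape[1])]
    cid, params, factory = grid[gi]
    clf = factory(len(sel)).fit(Xz[:, sel], data.y)
    return FrozenModel(classifier=clf, classifier_id=cid, params=dict(params),
                       scaler=sc, selected=sel, feature_names=names,
                       contrast=data.contrast, task=data.task,
                       inner_accuracy=inner_acc)


def transfer_evaluate(model: FrozenModel, external: ContrastData
                      ) -> tuple[float, float]:
    """Score a frozen model on an external cohort's contrast samples.

    The external table must provide every unmasked training feature; the
    frozen standardization (training parameters) is applied, never refit.
    """
    missing = [n for n in model.feature_names
               if n not in external.feature_names]
    if missing:
        raise ValueError("external table lacks model features: "
                         + ", ".join(missing))
    idx = [external.feature_names.index(n) for n in model.feature_names]
    Xz = model.scaler.transform(external.X[:, idx])
    preds = model.classifier.predict(Xz[:, model.selected])
    accuracy = float(np.mean(preds == external.y))
    p = binomial_significance(int(np.sum(preds == external.y)), len(external.y))
    return accuracy, p
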