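"""Feature selection, SVM-RBF classification, cross-validation and fusion.

Per-feature discriminative power is scored with the Fisher score

    F_j = Σ_c n_c (μ_cj − μ_j)² / max(Σ_c n_c σ_cj², ε)

(between-class over within-class scatter; σ² is the population class
variance, ε = 1e-12).  Classification uses an SVM with RBF kernel (libsvm
backend, one-vs-one for multiclass); evaluation is stratified k-fold
cross-validation with the *entire* pipeline — vocabulary construction,
signature quantization, Fisher selection, standardization and the SVM —
refit on each training fold only, so no test-fold information leaks into
any training artifact.

Decision-level fusion combines the per-map (MD, FA, RD) predicted labels by
majority vote; when all three disagree, the RD map's vote arbitrates.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import confusion_matrix, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .bow import Codebook, build_codebook, quantize
from .descriptors import LocalFeature, descriptor_matrix

logger = logging.getLogger(__name__)

#: Clinical severity ordering; the positive class of a binary problem is the
#: more-impaired one (AD in AD-vs-*, MCI in MCI-vs-NC).
SEVERITY = {"NC": 0, "MCI": 1, "AD": 2}

_EPS = 1e-12


def class_order(labels) -> tuple[str, ...]:
    """Unique labels sorted from least to most impaired."""
    present = sorted(set(labels), key=lambda c: (SEVERITY.get(c, 99), c))
    return tuple(present)


def positive_class(labels) -> str:
    """The more-impaired class of a binary label set."""
    order = class_order(labels)
    if len(order) != 2:
        raise ValueError(f"positive class defined for binary problems, got {order}")
    return order[-1]


# ---------------------------------------------------------------------------
# Datasets


@dataclass
class LabeledSignatureSet:
    """Fixed signature matrix (subjects × features) with class labels."""

    X: np.ndarray
    y: np.ndarray
    subject_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X must be (n_subjects, p) matching y")
        if not np.isfinite(self.X).all():
            raise ValueError("signature features must be finite")
        if self.subject_ids is None:
            self.subject_ids = [f"s{i}" for i in range(self.X.shape[0])]

    @property
    def n(self) -> int:
        return self.X.shape[0]


@dataclass
class FeatureDataset:
    """Per-subject descriptor sets with class labels.

    ``features[subject]`` is either a single pooled feature list (one
    vocabulary) or a ``{map_kind: feature list}`` dict (one vocabulary per
    map, histograms concatenated — the ``histogram_concat`` fusion variant).
    """

    features: dict[str, list[LocalFeature] | dict[str, list[LocalFeature]]]
    labels: dict[str, str]
    detector: str = "SIFT"
    source_maps: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if set(self.features) != set(self.labels):
            raise ValueError("features and labels must cover the same subjects")

    @property
    def subject_ids(self) -> list[str]:
        return sorted(self.features)

    @property
    def y(self) -> np.ndarray:
        return np.array([self.labels[s] for s in self.subject_ids])

    @property
    def per_map(self) -> bool:
        first = self.features[self.subject_ids[0]]
        return isinstance(first, dict)


@dataclass
class CVConfig:
    """Tunable knobs of the per-fold pipeline."""

    K: int = 100
    m_selected: int = 50
    C: float | None = None  # fixed hyperparameters bypass the grid search
    gamma: float | None = None
    C_grid: tuple[float, ...] = tuple(2.0 ** np.arange(-2, 9, 2))
    gamma_grid: tuple[float, ...] = tuple(2.0 ** np.arange(-10, 3, 2))
    inner_folds: int = 3
    codebook_scope: str = "fold"  # "fold" (unleaked, default) or "global"
    store_artifacts: bool = False


# ---------------------------------------------------------------------------
# Fisher score


@dataclass
class FisherRanking:
    """Per-feature Fisher scores and the descending-score feature order."""

    scores: np.ndarray
    order: np.ndarray
    m_selected: int

    @property
    def selected(self) -> np.ndarray:
        return self.order[: self.m_selected]


def fisher_scores(X: np.ndarray, y: np.ndarray, m_selected: int | None = None) -> FisherRanking:
    """Fisher score of every feature column of X given class labels y.

    Requires at least two classes with at least two samples each.  Ties in
    the ranking break toward the lower feature index.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("fisher_scores needs at least 2 classes")
    if (counts < 2).any():
        raise ValueError("every class needs at least 2 samples")
    mu = X.mean(axis=0)
    between = np.zeros(X.shape[1])
    within = np.zeros(X.shape[1])
    for c, n_c in zip(classes, counts):
        Xc = X[y == c]
        mu_c = Xc.mean(axis=0)
        between += n_c * (mu_c - mu) ** 2
        within += n_c * Xc.var(axis=0)  # population variance
    scores = between / np.maximum(within, _EPS)
    order = np.argsort(-scores, kind="stable")
    if m_selected is None:
        m_selected = min(X.shape[1], 50)
    return FisherRanking(scores=scores, order=order, m_selected=int(m_selected))


# ---------------------------------------------------------------------------
# SVM


def grid_search_svm_rbf(
    X: np.ndarray,
    y: np.ndarray,
    C_grid,
    gamma_grid,
    inner_folds: int = 3,
    seed: int = 0,
) -> tuple[float, float]:
    """Pick (C, γ) by inner stratified CV accuracy; ties keep the first
    (smallest C, then smallest γ) candidate."""
    _, counts = np.unique(y, return_counts=True)
    n_splits = int(min(inner_folds, counts.min()))
    if n_splits < 2:
        return float(C_grid[len(C_grid) // 2]), float(gamma_grid[len(gamma_grid) // 2])
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    best = (-1.0, None, None)
    for C in C_grid:
        for g in gamma_grid:
            acc = 0.0
            for tr, te in splits:
                clf = SVC(kernel="rbf", C=C, gamma=g, random_state=0)
                clf.fit(X[tr], y[tr])
                acc += (clf.predict(X[te]) == y[te]).mean()
            acc /= len(splits)
            if acc > best[0] + 1e-12:
                best = (acc, float(C), float(g))
    return best[1], best[2]


def fit_predict_svm_rbf(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    C: float,
    gamma: float,
) -> tuple[np.ndarray, np.ndarray, SVC]:
    """Fit an RBF SVM on (already standardized) training features and predict.

    Returns (predicted labels, decision scores, fitted model).  For binary
    problems the decision scores are signed so that positive values favour
    the more-impaired class; for multiclass they are the one-vs-one vote
    matrix columns (the libsvm convention).
    """
    if not (np.isfinite(train_X).all() and np.isfinite(test_X).all()):
        raise ValueError("non-finite features")
    clf = SVC(
        kernel="rbf", C=C, gamma=gamma, decision_function_shape="ovo", random_state=0
    )
    clf.fit(train_X, train_y)
    pred = clf.predict(test_X)
    scores = clf.decision_function(test_X)
    if len(clf.classes_) == 2:
        pos = positive_class(clf.classes_)
        if clf.classes_[1] != pos:
            scores = -scores
    return pred, scores, clf


# ---------------------------------------------------------------------------
# Metrics


def binary_metrics(
    confusion: np.ndarray, positive_index: int = 1
) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) in percent from a 2×2 confusion
    matrix (rows true, cols predicted).

    Sensitivity = TP/(TP+FN) for the positive (more-impaired) class;
    a metric with an empty margin is undefined and reported as NaN.
    """
    conf = np.asarray(confusion, dtype=float)
    if conf.shape != (2, 2) or (conf < 0).any():
        raise ValueError("confusion must be a nonnegative 2x2 matrix")
    total = conf.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    p, n = positive_index, 1 - positive_index
    tp, fn = conf[p, p], conf[p, n]
    tn, fp = conf[n, n], conf[n, p]
    acc = 100.0 * (tp + tn) / total
    sens = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else np.nan
    spec = 100.0 * tn / (tn + fp) if (tn + fp) > 0 else np.nan
    return acc, sens, spec


def roc_auc(
    scores: np.ndarray, labels: np.ndarray, positive: str | None = None
) -> tuple[np.ndarray, float]:
    """ROC points (FPR, TPR) by threshold sweep and trapezoidal AUC.

    The AUC equals the Mann–Whitney probability that a random positive
    outranks a random negative.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if positive is None:
        positive = positive_class(labels)
    y = labels == positive
    if y.all() or (~y).all():
        raise ValueError("both classes must be present for a ROC curve")
    fpr, tpr, _ = roc_curve(y, scores, drop_intermediate=False)
    return np.column_stack([fpr, tpr]), float(_sk_auc(fpr, tpr))


def decision_fusion(md_vote, fa_vote, rd_vote):
    """Fuse the per-map predicted labels by majority vote.

    The modal label wins; when all three maps disagree (possible only with
    three or more classes) the RD map's vote arbitrates — the generalization
    of the stated two-map-disagree/RD-decides rule.  A missing vote is an
    error.
    """
    votes = (md_vote, fa_vote, rd_vote)
    if any(v is None for v in votes):
        raise ValueError("decision fusion requires a vote from each map")
    label, n = Counter(votes).most_common(1)[0]
    return rd_vote if n == 1 else label


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass
class EvalReport:
    """Cross-validated performance of one experiment.

    Accuracy/sensitivity/specificity are per-fold percentages; the ROC is
    pooled from test-fold decision values (binary experiments only).
    """

    name: str
    classes: tuple[str, ...]
    fold_confusions: list[np.ndarray]
    fold_accuracy: np.ndarray
    fold_sensitivity: np.ndarray | None = None
    fold_specificity: np.ndarray | None = None
    roc_points: np.ndarray | None = None
    auc: float | None = None
    positive: str | None = None
    artifacts: list[dict] | None = None
    flags: list[str] = field(default_factory=list)

    @staticmethod
    def _ms(vals) -> tuple[float, float]:
        vals = np.asarray(vals, dtype=float)
        ok = vals[~np.isnan(vals)]
        if ok.size == 0:
            return np.nan, np.nan
        return float(ok.mean()), float(ok.std(ddof=1)) if ok.size > 1 else 0.0

    @property
    def accuracy(self) -> tuple[float, float]:
        return self._ms(self.fold_accuracy)

    @property
    def sensitivity(self) -> tuple[float, float]:
        if self.fold_sensitivity is None:
            return np.nan, np.nan
        return self._ms(self.fold_sensitivity)

    @property
    def specificity(self) -> tuple[float, float]:
        if self.fold_specificity is None:
            return np.nan, np.nan
        return self._ms(self.fold_specificity)

    def summary(self) -> pd.DataFrame:
        acc, acc_sd = self.accuracy
        sen, sen_sd = self.sensitivity
        spe, spe_sd = self.specificity
        return pd.DataFrame(
            [
                {
                    "experiment": self.name,
                    "classes": "/".join(self.classes),
                    "accuracy": acc,
                    "accuracy_sd": acc_sd,
                    "sensitivity": sen,
                    "sensitivity_sd": sen_sd,
                    "specificity": spe,
                    "specificity_sd": spe_sd,
                    "auc": self.auc if self.auc is not None else np.nan,
                    "flags": ";".join(self.flags),
                }
            ]
        )


def _effective_folds(y: np.ndarray, k: int) -> int:
    if k < 2:
        raise ValueError("k must be >= 2")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        warnings.warn(
            f"smallest class has {counts.min()} members < k={k}; reducing folds",
            stacklevel=3,
        )
        k = int(counts.min())
    if k < 2:
        raise ValueError("need at least 2 members per class for cross-validation")
    return k


def _subject_signatures(
    ds: FeatureDataset, train_ids: list[str], all_ids: list[str], seed: int, cfg: CVConfig
) -> tuple[np.ndarray, dict]:
    """Build codebook(s) from the training subjects and quantize everyone."""

    def pool(ids, kind=None):
        out = []
        for s in ids:
            f = ds.features[s]
            out.append(descriptor_matrix(f[kind] if kind is not None else f))
        mats = [m for m in out if m.size]
        return np.vstack(mats) if mats else np.empty((0, 0))

    if ds.per_map:
        kinds = sorted({k for s in all_ids for k in ds.features[s]})
        books = {
            kind: build_codebook(
                pool(train_ids, kind), cfg.K, seed, (kind,), ds.detector
            )
            for kind in kinds
        }
        rows = []
        for s in all_ids:
            hists = [
                quantize(descriptor_matrix(ds.features[s][kind]), books[kind], s).histogram
                for kind in kinds
            ]
            rows.append(np.concatenate(hists))
        X = np.stack(rows)
        art = {"codebook": np.vstack([books[k].centroids for k in kinds])}
    else:
        book = build_codebook(pool(train_ids), cfg.K, seed, ds.source_maps, ds.detector)
        X = np.stack(
            [
                quantize(descriptor_matrix(ds.features[s]), book, s).histogram
                for s in all_ids
            ]
        )
        art = {"codebook": book.centroids}
    return X, art


def _fit_fold(
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    X_te: np.ndarray,
    seed: int,
    cfg: CVConfig,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Fisher selection → standardization → SVM on one training fold."""
    ranking = fisher_scores(X_tr, y_tr, m_selected=min(cfg.m_selected, X_tr.shape[1]))
    sel = ranking.selected
    scaler = StandardScaler().fit(X_tr[:, sel])
    Xs_tr = scaler.transform(X_tr[:, sel])
    Xs_te = scaler.transform(X_te[:, sel])
    if cfg.C is not None and cfg.gamma is not None:
        C, gamma = float(cfg.C), float(cfg.gamma)
    else:
        C, gamma = grid_search_svm_rbf(
            Xs_tr, y_tr, cfg.C_grid, cfg.gamma_grid, cfg.inner_folds, seed
        )
    pred, scores, clf = fit_predict_svm_rbf(Xs_tr, y_tr, Xs_te, C, gamma)
    artifacts = {
        "fisher_scores": ranking.scores,
        "selected": sel,
        "scaler_mean": scaler.mean_.copy(),
        "scaler_scale": scaler.scale_.copy(),
        "C": C,
        "gamma": gamma,
        "svm_support": clf.support_.copy(),
        "svm_dual_coef": clf.dual_coef_.copy(),
        "svm_intercept": clf.intercept_.copy(),
    }
    return pred, scores, artifacts


def _aggregate(
    name: str,
    classes: tuple[str, ...],
    fold_true: list[np.ndarray],
    fold_pred: list[np.ndarray],
    fold_scores: list[np.ndarray] | None,
    artifacts: list[dict] | None,
    flags: list[str],
) -> EvalReport:
    confs, accs, sens, spes = [], [], [], []
    binary = len(classes) == 2
    for yt, yp in zip(fold_true, fold_pred):
        conf = confusion_matrix(yt, yp, labels=list(classes))
        confs.append(conf)
        accs.append(100.0 * np.trace(conf) / conf.sum())
        if binary:
            a, se, sp = binary_metrics(conf, positive_index=1)
            sens.append(se)
            spes.append(sp)
    roc_pts, auc_val, pos = None, None, None
    if binary:
        pos = classes[1]
        if fold_scores is not None:
            all_scores = np.concatenate(fold_scores)
            all_true = np.concatenate(fold_true)
            roc_pts, auc_val = roc_auc(all_scores, all_true, pos)
    return EvalReport(
        name=name,
        classes=classes,
        fold_confusions=confs,
        fold_accuracy=np.array(accs),
        fold_sensitivity=np.array(sens) if binary else None,
        fold_specificity=np.array(spes) if binary else None,
        roc_points=roc_pts,
        auc=auc_val,
        positive=pos,
        artifacts=artifacts,
        flags=flags,
    )


def cross_validate(
    ds: FeatureDataset | LabeledSignatureSet,
    k: int = 10,
    seed: int = 0,
    config: CVConfig | None = None,
    name: str = "experiment",
) -> EvalReport:
    """Stratified k-fold cross-validation of the full pipeline.

    With a :class:`FeatureDataset`, each fold rebuilds the vocabulary from
    its training subjects only (unless ``config.codebook_scope == "global"``,
    the deliberately leaked variant), then quantizes, selects, standardizes
    and fits the SVM on the training portion.  With a
    :class:`LabeledSignatureSet` the signatures are taken as given and only
    selection/standardization/SVM are refit per fold.
    """
    cfg = config or CVConfig()
    from_features = isinstance(ds, FeatureDataset)
    if from_features:
        ids = ds.subject_ids
        y = ds.y
    else:
        ids = list(ds.subject_ids)
        y = ds.y
    classes = class_order(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    k = _effective_folds(y, k)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    flags: list[str] = []
    global_X = None
    if from_features and cfg.codebook_scope == "global":
        global_X, _ = _subject_signatures(ds, ids, ids, seed, cfg)
        flags.append("codebook built on all subjects (leaked variant)")

    fold_true, fold_pred, fold_scores, all_artifacts = [], [], [], []
    for tr, te in skf.split(np.zeros(len(y)), y):
        if from_features and global_X is None:
            X, book_art = _subject_signatures(
                ds, [ids[i] for i in tr], ids, seed, cfg
            )
        elif from_features:
            X, book_art = global_X, {}
        else:
            X, book_art = ds.X, {}
        pred, scores, art = _fit_fold(X[tr], y[tr], X[te], seed, cfg)
        art.update(book_art)
        art["test_index"] = te.copy()
        fold_true.append(y[te])
        fold_pred.append(pred)
        fold_scores.append(scores)
        all_artifacts.append(art)
    return _aggregate(
        name,
        classes,
        fold_true,
        fold_pred,
        fold_scores if len(classes) == 2 else None,
        all_artifacts if cfg.store_artifacts else None,
        flags,
    )


def cross_validate_decision_fusion(
    per_map: dict[str, FeatureDataset],
    k: int = 10,
    seed: int = 0,
    config: CVConfig | None = None,
    name: str = "decision_fusion",
) -> EvalReport:
    """Cross-validate the majority-vote fusion of the three per-map pipelines.

    All three map datasets must cover the same subjects and labels; fold
    assignment is shared so each map votes on the same test subjects.
    """
    cfg = config or CVConfig()
    for kind in ("MD", "FA", "RD"):
        if kind not in per_map:
            raise ValueError(f"decision fusion requires the {kind} map")
    ids = per_map["MD"].subject_ids
    y = per_map["MD"].y
    for kind, ds in per_map.items():
        if ds.subject_ids != ids or not (ds.y == y).all():
            raise ValueError("per-map datasets must share subjects and labels")
    classes = class_order(y)
    flags: list[str] = []
    if len(classes) > 2:
        flags.append("multiclass decision fusion (beyond the binary-only setting)")
    k = _effective_folds(y, k)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_true, fold_pred = [], []
    for tr, te in skf.split(np.zeros(len(y)), y):
        votes = {}
        for kind in ("MD", "FA", "RD"):
            ds = per_map[kind]
            X, _ = _subject_signatures(ds, [ids[i] for i in tr], ids, seed, cfg)
            pred, _, _ = _fit_fold(X[tr], y[tr], X[te], seed, cfg)
            votes[kind] = pred
        fused = np.array(
            [
                decision_fusion(votes["MD"][i], votes["FA"][i], votes["RD"][i])
                for i in range(len(te))
            ]
        )
        fold_true.append(y[te])
        fold_pred.append(fused)
    return _aggregate(name, classes, fold_true, fold_pred, None, None, flags)
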