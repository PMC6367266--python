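"""Classifier training and k-fold cross-validated evaluation.

Binary classifiers (random forest, SVM, logistic regression) are trained on
fused-feature matrices and evaluated with six metrics — Accuracy,
Sensitivity, Specificity, Precision, Matthews correlation coefficient and
AUC — plus their arithmetic total ("Sum"), averaged over stratified
k-fold cross-validation. Per-fold feature selection (the default) fits the
ranking forest on the training split only, so held-out scores are free of
selection leakage; a 'global' scope that ranks once on the whole dataset is
also available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .base_features import (
    KmerConfig,
    protein_kmer_vector,
    rna_kmer_vector,
)
from .complex_features import (
    FusionConfig,
    build_complex_vector,
    complex_feature_names,
    concat_base_vector,
    fuse_values,
)
from .feature_selection import (
    SelectionConfig,
    apply_selection,
    rank_by_forest_importance,
    select_top_k,
)
from .sequence_io import InteractionDataset

ClassifierKind = Literal["rf", "svm", "lr"]
VARIANTS = ("BaseFeat", "CFRP-raw", "CFRP")

METRIC_NAMES = ("acc", "sen", "spe", "pre", "mcc", "auc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class FoldMetrics:
    acc: float
    sen: float
    spe: float
    pre: float
    mcc: float
    auc: float

    @property
    def sum(self) -> float:
        return self.acc + self.sen + self.spe + self.pre + self.mcc + self.auc

    def as_dict(self) -> dict[str, float]:
        d = {k: getattr(self, k) for k in METRIC_NAMES}
        d["sum"] = self.sum
        return d


@dataclass(frozen=True)
class MetricsReport:
    """Six metrics plus Sum; mean over folds with per-fold breakdown."""

    acc: float
    sen: float
    spe: float
    pre: float
    mcc: float
    auc: float
    per_fold: list[FoldMetrics] = field(default_factory=list)
    n_folds: int = 1

    @property
    def sum(self) -> float:
        return self.acc + self.sen + self.spe + self.pre + self.mcc + self.auc

    def to_frame(self) -> pd.DataFrame:
        rows = [f.as_dict() for f in self.per_fold]
        rows.append(
            {**{k: getattr(self, k) for k in METRIC_NAMES}, "sum": self.sum}
        )
        index = [f"fold{i + 1}" for i in range(len(self.per_fold))] + ["mean"]
        df = pd.DataFrame(rows, index=index)
        df.index.name = "split"
        return df


@dataclass(frozen=True)
class CVConfig:
    n_folds: int = 10
    stratified: bool = True
    seed: int = 0
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass
class TrainedModel:
    """A fitted classifier plus the configuration that produced it."""

    classifier_kind: ClassifierKind
    estimator: object
    feature_names: tuple[str, ...]
    kmer_config: KmerConfig | None = None
    fusion_config: FusionConfig | None = None
    selection_config: SelectionConfig | None = None
    seed: int = 0

    def predict_scores(self, X) -> np.ndarray:
        """Probability of class 1 per sample."""
        if isinstance(X, pd.DataFrame):
            X = apply_selection(X, self.feature_names).to_numpy(dtype=np.float64)
        proba = self.estimator.predict_proba(X)
        classes = list(self.estimator.classes_)
        return proba[:, classes.index(1)]


def _make_estimator(kind: ClassifierKind, seed: int):
    if kind == "rf":
        return RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    if kind == "svm":
        # Platt sigmoid fitted on the training split so the SVM emits a
        # [0,1] ranking score for AUC
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "svc",
                    CalibratedClassifierCV(
                        SVC(kernel="rbf", random_state=seed),
                        method="sigmoid",
                        ensemble=False,
                    ),
                ),
            ]
        )
    if kind == "lr":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("lr", LogisticRegression(max_iter=2000, random_state=seed)),
            ]
        )
    raise ValueError(f"unknown classifier kind {kind!r}; expected rf, svm or lr")


def train_classifier(X, y, kind: ClassifierKind, seed: int) -> TrainedModel:
    """Fit one classifier; deterministic given ``seed``."""
    if isinstance(X, pd.DataFrame):
        names = tuple(str(c) for c in X.columns)
        mat = X.to_numpy(dtype=np.float64)
    else:
        mat = np.asarray(X, dtype=np.float64)
        names = tuple(f"f{i}" for i in range(mat.shape[1]))
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training requires samples of both classes")
    est = _make_estimator(kind, seed)
    est.fit(mat, y)
    return TrainedModel(
        classifier_kind=kind, estimator=est, feature_names=names, seed=seed
    )


def _auc_by_ranks(scores: np.ndarray, y: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney rank statistic (ties averaged)."""
    ranks = rankdata(scores)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    rank_sum = float(ranks[y == 1].sum())
    return (rank_sum - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def confusion_at_threshold(
    scores: np.ndarray, y: np.ndarray, threshold: float = 0.5
) -> ConfusionCounts:
    pred = np.asarray(scores) >= threshold
    y = np.asarray(y).astype(bool)
    return ConfusionCounts(
        tp=int((pred & y).sum()),
        tn=int((~pred & ~y).sum()),
        fp=int((pred & ~y).sum()),
        fn=int((~pred & y).sum()),
    )


def compute_metrics(scores, y, threshold: float = 0.5) -> MetricsReport:
    """Six-metric panel for one scored evaluation.

    Accuracy, sensitivity (recall on class 1), specificity, precision and
    MCC are computed from the confusion matrix at ``threshold``; AUC is the
    rank-based Mann-Whitney statistic over the raw scores. Precision is 0
    when nothing is predicted positive; MCC is 0 when its denominator
    vanishes. Requires both classes present (AUC is undefined otherwise).
    """
    scores = np.asarray(scores, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    if scores.shape != y.shape:
        raise ValueError("scores and labels must align")
    if len(np.unique(y)) < 2:
        raise ValueError(
            "metrics require both classes in y: AUC is undefined on a "
            "single-class sample (check fold stratification)"
        )
    c = confusion_at_threshold(scores, y, threshold)
    acc = (c.tp + c.tn) / c.total
    sen = c.tp / (c.tp + c.fn)
    spe = c.tn / (c.tn + c.fp)
    pre = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else 0.0
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = (
        (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom) if denom > 0 else 0.0
    )
    auc = _auc_by_ranks(scores, y)
    fold = FoldMetrics(acc=acc, sen=sen, spe=spe, pre=pre, mcc=mcc, auc=auc)
    return MetricsReport(
        acc=acc, sen=sen, spe=spe, pre=pre, mcc=mcc, auc=auc,
        per_fold=[fold], n_folds=1,
    )


def _fold_iterator(y: np.ndarray, config: CVConfig):
    cls = StratifiedKFold if config.stratified else KFold
    splitter = cls(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
    return splitter.split(np.zeros(len(y)), y)


def k_fold_cross_validate(
    X,
    y,
    cv_config: CVConfig,
    classifier_kind: ClassifierKind = "rf",
    selection_config: SelectionConfig | None = None,
) -> MetricsReport:
    """Cross-validated six-metric report; the mean row averages fold metrics.

    When ``selection_config`` is given, features are ranked and the top-k
    kept — on the training split of each fold (scope='per_fold') or once on
    the full matrix (scope='global').
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=np.float64))
        X.columns = [f"f{i}" for i in range(X.shape[1])]
    y = np.asarray(y, dtype=int)
    global_selected: list[str] | None = None
    if selection_config is not None and selection_config.scope == "global":
        ranking = rank_by_forest_importance(X, y, selection_config)
        global_selected = select_top_k(ranking, selection_config.k)
    folds: list[FoldMetrics] = []
    for train_idx, test_idx in _fold_iterator(y, cv_config):
        X_tr, X_te = X.iloc[train_idx], X.iloc[test_idx]
        y_tr, y_te = y[train_idx], y[test_idx]
        if selection_config is not None:
            if global_selected is not None:
                selected = global_selected
            else:
                ranking = rank_by_forest_importance(X_tr, y_tr, selection_config)
                selected = select_top_k(ranking, selection_config.k)
            X_tr = apply_selection(X_tr, selected)
            X_te = apply_selection(X_te, selected)
        model = train_classifier(X_tr, y_tr, classifier_kind, cv_config.seed)
        scores = model.predict_scores(X_te)
        folds.append(compute_metrics(scores, y_te, cv_config.threshold).per_fold[0])
    means = {k: float(np.mean([getattr(f, k) for f in folds])) for k in METRIC_NAMES}
    return MetricsReport(per_fold=folds, n_folds=cv_config.n_folds, **means)


def featurize_dataset(
    dataset: InteractionDataset,
    kmer_config: KmerConfig = KmerConfig(),
    fusion_config: FusionConfig = FusionConfig(),
    variant: Literal["complex", "basefeat"] = "complex",
) -> pd.DataFrame:
    """Feature matrix (rows = pairs, in dataset order) for a whole dataset.

    Base vectors are computed once per unique sequence; fused rows are
    filled pair by pair (the protein axis is chunked inside ``fuse_values``)
    so the only full-size allocation is the output matrix itself. The index
    is '<rna_id>|<protein_id>'.
    """
    rna_ids = {p.rna_id for p in dataset.pairs}
    prot_ids = {p.protein_id for p in dataset.pairs}
    rna_vecs = {
        rid: rna_kmer_vector(dataset.rna_map[rid], kmer_config) for rid in sorted(rna_ids)
    }
    prot_vecs = {
        pid: protein_kmer_vector(dataset.protein_map[pid], kmer_config)
        for pid in sorted(prot_ids)
    }
    any_r = next(iter(rna_vecs.values()))
    any_p = next(iter(prot_vecs.values()))
    if variant == "basefeat":
        names = tuple(f"R:{n}" for n in any_r.names) + tuple(
            f"P:{n}" for n in any_p.names
        )
        rows = np.empty((len(dataset.pairs), len(names)), dtype=np.float64)
        for i, pair in enumerate(dataset.pairs):
            rows[i] = np.concatenate(
                [rna_vecs[pair.rna_id].values, prot_vecs[pair.protein_id].values]
            )
    else:
        names = complex_feature_names(
            any_r.names, any_p.names, fusion_config.families
        )
        rows = np.empty((len(dataset.pairs), len(names)), dtype=np.float64)
        for i, pair in enumerate(dataset.pairs):
            rows[i] = fuse_values(
                rna_vecs[pair.rna_id].values,
                prot_vecs[pair.protein_id].values,
                fusion_config,
            )
    index = [f"{p.rna_id}|{p.protein_id}" for p in dataset.pairs]
    df = pd.DataFrame(rows, columns=list(names), index=index)
    df.index.name = "pair_id"
    return df


def run_variant(
    dataset: InteractionDataset,
    variant: str,
    kmer_config: KmerConfig = KmerConfig(),
    fusion_config: FusionConfig = FusionConfig(),
    selection_config: SelectionConfig = SelectionConfig(),
    cv_config: CVConfig = CVConfig(),
    classifier_kind: ClassifierKind = "rf",
) -> MetricsReport:
    """Evaluate one pipeline variant under shared-fold cross-validation.

    BaseFeat: concatenated k-mer vectors, no selection. CFRP-raw: all fused
    complex features, no selection. CFRP: fused features with top-k
    forest-importance selection. Because the fold seed lives in
    ``cv_config``, variants run with the same config are paired fold-wise.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    y = dataset.labels()
    if variant == "BaseFeat":
        X = featurize_dataset(dataset, kmer_config, fusion_config, variant="basefeat")
        return k_fold_cross_validate(X, y, cv_config, classifier_kind, None)
    X = featurize_dataset(dataset, kmer_config, fusion_config, variant="complex")
    sel = selection_config if variant == "CFRP" else None
    return k_fold_cross_validate(X, y, cv_config, classifier_kind, sel)


# re-exported for convenience in pipeline code
__all__ = [
    "ConfusionCounts",
    "FoldMetrics",
    "MetricsReport",
    "CVConfig",
    "TrainedModel",
    "train_classifier",
    "compute_metrics",
    "confusion_at_threshold",
    "k_fold_cross_validate",
    "featurize_dataset",
    "run_variant",
    "build_complex_vector",
    "concat_base_vector",
    "VARIANTS",
    "METRIC_NAMES",
]
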