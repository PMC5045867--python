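"""Feature filtering, the hard-voting ensemble, stratified cross-validation
and evaluation metrics.

The classifier is a committee of three base learners — an RBF-kernel
support vector machine, a random forest and an L2 logistic regression —
fitted on z-scored features.  Class calls are the hard majority vote of
the three members; the ranking score (used for ROC/AUC and the reported
per-site probability) is the mean of the members' class-1 probability
estimates, since a hard vote alone yields no graded confidence.

Before fitting, zero-variance (unary) features are dropped and the
remainder filtered by a univariate one-way ANOVA F-test with
Benjamini-Hochberg false-discovery-rate control at level q (default 0.1).
Inside cross-validation both steps and the scaler are re-fit on each
training fold only, so no information leaks from held-out folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests


@dataclass
class ModelConfig:
    """Ensemble and cross-validation settings."""

    q_fdr: float = 0.1
    cv_folds: int = 10
    random_seed: int = 0
    svm_C: float = 1.0
    svm_gamma: str | float = "auto"  # 1 / n_features
    rf_trees: int = 500
    logreg_C: float = 1.0
    vote_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.q_fdr < 1:
            raise ValueError("q_fdr must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class MetricsReport:
    """The six evaluation metrics plus the confusion counts behind them."""

    auc: float
    accuracy: float
    sensitivity: float
    precision: float
    specificity: float
    f1: float
    tp: int
    fp: int
    tn: int
    fn: int

    def as_dict(self) -> dict[str, float]:
        return {
            "auc": self.auc,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "precision": self.precision,
            "specificity": self.specificity,
            "f1": self.f1,
        }


@dataclass
class CVReport:
    """Per-fold metrics, their mean, and pooled-prediction metrics."""

    folds: list[MetricsReport]
    pooled: MetricsReport

    @property
    def mean(self) -> dict[str, float]:
        keys = ("auc", "accuracy", "sensitivity", "precision", "specificity", "f1")
        return {k: float(np.mean([getattr(f, k) for f in self.folds])) for k in keys}


def remove_unary(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Drop features whose value is identical across all rows.

    Returns the reduced matrix and the names of the dropped features.
    """
    if len(X) == 0:
        raise ValueError("empty feature matrix")
    varying = X.columns[(X != X.iloc[0]).any(axis=0)]
    dropped = [c for c in X.columns if c not in set(varying)]
    return X[varying], dropped


def select_features_fdr(
    X: pd.DataFrame, y: np.ndarray, q: float = 0.1
) -> list[str]:
    """Univariate selection: one-way ANOVA F-test per feature, then
    Benjamini-Hochberg step-up at FDR level ``q``; returns passing names."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present for feature selection")
    with warnings.catch_warnings():
        # constant features get p = NaN -> treated as 1 below
        warnings.simplefilter("ignore")
        _, pvals = f_classif(X.values, y)
    pvals = np.nan_to_num(pvals, nan=1.0)
    keep, _, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return [c for c, k in zip(X.columns, keep) if k]


@dataclass
class TrainedEnsemble:
    """Fitted selector, scaler and the three-member voting committee."""

    feature_names: list[str]
    scaler: StandardScaler
    members: list
    config: ModelConfig
    dropped_unary: list[str] = dc_field(default_factory=list)

    def _check(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in X.columns]
        if missing:
            raise ValueError(
                f"prediction input lacks {len(missing)} trained feature(s), "
                f"e.g. {missing[:3]}; was it built with the same feature profile?"
            )
        return self.scaler.transform(X[self.feature_names].values)

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Mean of the members' class-1 probability estimates."""
        Z = self._check(X)
        return np.mean([m.predict_proba(Z)[:, 1] for m in self.members], axis=0)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Hard majority vote of the three members' class calls."""
        Z = self._check(X)
        votes = np.stack([m.predict(Z) for m in self.members])
        return (votes.sum(axis=0) >= 2).astype(int)


def _make_members(cfg: ModelConfig) -> list:
    return [
        SVC(
            kernel="rbf",
            C=cfg.svm_C,
            gamma=cfg.svm_gamma,
            probability=True,
            random_state=cfg.random_seed,
        ),
        RandomForestClassifier(
            n_estimators=cfg.rf_trees, random_state=cfg.random_seed, n_jobs=1
        ),
        LogisticRegression(C=cfg.logreg_C, max_iter=2000),
    ]


def fit_ensemble(
    X: pd.DataFrame, y: Sequence[int], cfg: ModelConfig = ModelConfig()
) -> TrainedEnsemble:
    """Fit the full training pipeline on ``(X, y)``.

    Steps: drop unary features, ANOVA-F + BH selection at ``q_fdr``,
    z-score standardization, then fit the three base learners.  All steps
    are fit on the given data only, so the function can be applied
    per-fold without leakage.  Deterministic for a fixed seed.
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    Xv, dropped = remove_unary(X)
    selected = select_features_fdr(Xv, y, cfg.q_fdr)
    if not selected:  # fall back to all varying features rather than fail
        selected = list(Xv.columns)
    scaler = StandardScaler().fit(Xv[selected].values)
    Z = scaler.transform(Xv[selected].values)
    members = _make_members(cfg)
    with warnings.catch_warnings():
        # sklearn >= 1.9 deprecates SVC's probability flag; Platt-scaled
        # SVM probabilities are part of this model's scoring contract.
        warnings.simplefilter("ignore", FutureWarning)
        for m in members:
            m.fit(Z, y)
    return TrainedEnsemble(
        feature_names=selected,
        scaler=scaler,
        members=members,
        config=cfg,
        dropped_unary=dropped,
    )


def auc_score(truth: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve via the rank statistic, ties at midrank."""
    truth = np.asarray(truth, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(truth.sum())
    n_neg = len(truth) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes required")
    ranks = rankdata(scores)
    return float((ranks[truth == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def compute_metrics(
    truth: Sequence[int],
    scores: Sequence[float],
    threshold: float = 0.5,
    calls: Optional[Sequence[int]] = None,
) -> MetricsReport:
    """Confusion counts and the six summary metrics.

    ``scores`` rank the samples for AUC; class calls default to
    ``scores > threshold`` but explicit ``calls`` (e.g. a hard majority
    vote) may be supplied.  Sensitivity (recall) = TP/(TP+FN), precision =
    TP/(TP+FP), specificity = TN/(TN+FP), F1 = harmonic mean of precision
    and sensitivity; a ratio with zero denominator is reported as 0.
    """
    truth = np.asarray(truth, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(truth) != len(scores):
        raise ValueError("truth and scores must have equal length")
    calls = (scores > threshold).astype(int) if calls is None else np.asarray(calls, int)
    tp = int(((calls == 1) & (truth == 1)).sum())
    fp = int(((calls == 1) & (truth == 0)).sum())
    tn = int(((calls == 0) & (truth == 0)).sum())
    fn = int(((calls == 0) & (truth == 1)).sum())

    def _ratio(a: float, b: float) -> float:
        return a / b if b else 0.0

    sens = _ratio(tp, tp + fn)
    prec = _ratio(tp, tp + fp)
    return MetricsReport(
        auc=auc_score(truth, scores),
        accuracy=_ratio(tp + tn, len(truth)),
        sensitivity=sens,
        precision=prec,
        specificity=_ratio(tn, tn + fp),
        f1=_ratio(2 * prec * sens, prec + sens),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
    )


def stratified_cv(
    X: pd.DataFrame,
    y: Sequence[int],
    cfg: ModelConfig = ModelConfig(),
    scores_out: Optional[list] = None,
) -> CVReport:
    """Stratified k-fold cross-validation of the full pipeline.

    Folds preserve the class ratio to within one sample.  Unary removal,
    FDR selection and scaling are re-fit inside every training fold.
    Returns per-fold metrics, their mean and pooled-prediction metrics.
    """
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < cfg.cv_folds:
        raise ValueError(
            f"minority class has {counts.min()} samples < {cfg.cv_folds} folds; "
            "reduce cv_folds"
        )
    skf = StratifiedKFold(
        n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.random_seed
    )
    folds = []
    pooled_truth, pooled_scores, pooled_calls = [], [], []
    for tr, te in skf.split(X, y):
        model = fit_ensemble(X.iloc[tr], y[tr], cfg)
        scores = model.predict_proba(X.iloc[te])
        calls = model.predict(X.iloc[te])
        folds.append(compute_metrics(y[te], scores, cfg.vote_threshold, calls=calls))
        pooled_truth.append(y[te])
        pooled_scores.append(scores)
        pooled_calls.append(calls)
        if scores_out is not None:
            scores_out.append((te, scores))
    pooled = compute_metrics(
        np.concatenate(pooled_truth),
        np.concatenate(pooled_scores),
        cfg.vote_threshold,
        calls=np.concatenate(pooled_calls),
    )
    return CVReport(folds=folds, pooled=pooled)


def predict_sites(
    seqs,
    model: TrainedEnsemble,
    feature_config,
) -> pd.DataFrame:
    """Score every candidate site of unlabeled sequences.

    Returns a frame with columns seq_id, position, residue, probability
    and call (probability > 0.5).  Residues outside the candidate set
    (non-K/R or too close to a terminus) are not scored — they are
    non-sites by definition.
    """
    from .assemble import build_feature_matrix
    from .windowing import extract_windows, filter_candidates

    wcfg = feature_config.window
    rows = []
    all_windows = []
    for seq in seqs:
        cands = filter_candidates(extract_windows(seq, wcfg), wcfg)
        for w in cands:
            rows.append((seq.id, w.site_index, w.site_residue(wcfg)))
            all_windows.append(w)
    if not all_windows:
        return pd.DataFrame(columns=["seq_id", "position", "residue", "probability", "call"])
    X, _ = build_feature_matrix(all_windows, feature_config)
    proba = model.predict_proba(X)
    out = pd.DataFrame(rows, columns=["seq_id", "position", "residue"])
    out["probability"] = proba
    out["call"] = (proba > 0.5).astype(int)
    return out
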