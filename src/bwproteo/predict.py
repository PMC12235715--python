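"""Leakage-free prediction of birth-weight group from MoM profiles.

Each sample at one visit is predicted by leave-one-out cross-validation
(LOO-CV): the held-out sample is removed, proteins are ranked by
moderated-t p-value on the remaining samples only (within-fold screening),
the learner is tuned (elastic net: inner stratified 5-fold CV over a
10×10 α/λ grid maximising inner ROC-AUC) and fitted on the remaining
samples, and the held-out probability of the minority (case) class is
recorded. Screening, tuning and fitting never see the held-out sample.

Evaluation is imbalance-aware: ROC-AUC (Mann–Whitney with tie correction,
DeLong confidence interval), PR-AUC by step summation, F1 and balanced
accuracy at probability threshold 0.5 with the minority class positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .diff import ModeratedLinearModel

__all__ = [
    "ModelSpec",
    "CvResult",
    "MetricsReport",
    "rank_proteins_by_moderated_t",
    "loo_cv_predict",
    "evaluate_predictions",
    "roc_auc",
    "delong_ci",
    "pr_auc",
]


@dataclass
class ModelSpec:
    """Learner configuration for the LOO-CV experiment.

    learner
        "elastic_net" or "random_forest".
    n_features
        "all" or an int: proteins kept after within-fold moderated-t
        screening (the study's reduced models used 50/40/30/20/10/5).
    en_alphas / en_lambdas
        Elastic-net mixing and penalty grids (default 10×10; λ log-spaced
        over [1e-3, 1e1] after within-fold standardisation).
    rf_trees
        Random-forest size (default 500, features-per-split = sqrt(p)).
    inner_folds
        Inner stratified CV folds for elastic-net tuning.
    """

    learner: str = "random_forest"
    n_features: int | str = 20
    en_alphas: np.ndarray = field(default_factory=lambda: np.linspace(0.0, 1.0, 10))
    en_lambdas: np.ndarray = field(default_factory=lambda: np.logspace(-3, 1, 10))
    rf_trees: int = 500
    inner_folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.learner not in ("elastic_net", "random_forest"):
            raise ValueError(f"unknown learner {self.learner!r}")
        if self.n_features != "all" and (not isinstance(self.n_features, int) or self.n_features < 1):
            raise ValueError("n_features must be 'all' or a positive int")


@dataclass
class CvResult:
    """Out-of-fold predictions: one probability per held-out sample."""

    predictions: pd.DataFrame  # sample_id, y_true, prob (positive class)
    selected_features: list[list[str]]
    positive_label: str
    spec: ModelSpec
    seed: int


@dataclass
class MetricsReport:
    roc_auc: float
    roc_auc_ci: tuple[float, float]
    ci_level: float
    pr_auc: float
    f1: float
    balanced_accuracy: float
    confusion: dict[str, int]  # tp, fp, tn, fn at threshold 0.5
    positive_label: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "roc_auc": self.roc_auc,
                    "roc_auc_ci_lo": self.roc_auc_ci[0],
                    "roc_auc_ci_hi": self.roc_auc_ci[1],
                    "ci_level": self.ci_level,
                    "pr_auc": self.pr_auc,
                    "f1": self.f1,
                    "balanced_accuracy": self.balanced_accuracy,
                    **self.confusion,
                    "positive_label": self.positive_label,
                }
            ]
        )


def rank_proteins_by_moderated_t(
    train_mom: pd.DataFrame,
    train_labels: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> list[str]:
    """Rank proteins ascending by moderated-t p-value on the training fold.

    Ties break by |t| descending, then protein id — so reduced feature
    lists of different sizes are prefixes of one another.
    """
    y = np.asarray(train_labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2 or counts.min() < 3:
        raise ValueError(f"need two classes with >= 3 samples each, got {dict(zip(classes, counts))}")
    cols = {"intercept": np.ones(len(y)), "case": (y == classes[1]).astype(float)}
    design = pd.DataFrame(cols, index=train_mom.index)
    if covariates is not None:
        for c in covariates.columns:
            design[c] = covariates.loc[train_mom.index, c].astype(float).to_numpy()
    res = ModeratedLinearModel(train_mom, design, "case").fit()
    order = pd.DataFrame(
        {
            "protein": np.asarray(res.proteins),
            "p": np.nan_to_num(res.p, nan=np.inf),
            "neg_abs_t": -np.abs(np.nan_to_num(res.t, nan=0.0)),
        }
    ).sort_values(["p", "neg_abs_t", "protein"], kind="stable")
    return order["protein"].tolist()


def _fold_seed(master: int, fold: int) -> int:
    return int(np.random.SeedSequence([master, fold]).generate_state(1)[0] % (2**31))


def _tune_and_fit_en(x, y, spec: ModelSpec, seed: int):
    """Standardise, tune (α, λ) by inner stratified CV on ROC-AUC, refit."""
    mu, sd = x.mean(axis=0), x.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    xs = (x - mu) / sd
    n_splits = spec.inner_folds
    counts = np.bincount(y)
    if counts.min() < n_splits:
        n_splits = max(2, int(counts.min()))
        if counts.min() < 2:
            warnings.warn("inner fold with a single case; tuning on 2 folds with repetition")
            n_splits = 2
    best = (-np.inf, None)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    splits = list(skf.split(xs, y))
    for alpha in spec.en_alphas:
        for lam in spec.en_lambdas:
            aucs = []
            for tr, te in splits:
                if len(np.unique(y[te])) < 2:
                    continue
                m = _make_en(alpha, lam, len(tr))
                m.fit(xs[tr], y[tr])
                aucs.append(roc_auc(y[te], m.predict_proba(xs[te])[:, 1]))
            score = float(np.mean(aucs)) if aucs else -np.inf
            if score > best[0] + 1e-12:
                best = (score, (alpha, lam))
    alpha, lam = best[1] if best[1] is not None else (0.5, 0.1)
    model = _make_en(alpha, lam, len(y))
    model.fit(xs, y)

    def predict(xnew):
        return model.predict_proba((xnew - mu) / sd)[:, 1]

    return predict


def _make_en(alpha: float, lam: float, n: int) -> LogisticRegression:
    # glmnet-style parameterisation: C = 1 / (n·λ); α is the l1 ratio
    return LogisticRegression(
        solver="saga",
        l1_ratio=float(alpha),
        C=1.0 / (n * lam),
        max_iter=5000,
        tol=1e-4,
    )


def loo_cv_predict(
    mom: pd.DataFrame,
    samples: pd.DataFrame,
    spec: ModelSpec,
    contrast: str = "LGA-AGA",
    visit: int | None = None,
    leak_screening: bool = False,
) -> CvResult:
    """LOO-CV prediction of ``contrast`` (case vs AGA) at one visit.

    leak_screening
        Deliberately screen features once on ALL samples before CV instead
        of within each fold. Exists only as a negative control for
        selection-bias regression tests; never use it for real evaluation.
    """
    case, ref = contrast.split("-")
    sub = samples.loc[mom.index]
    if visit is not None:
        sub = sub[sub["visit"] == visit]
    sub = sub[sub["group"].isin([case, ref])]
    x_all = mom.loc[sub.index]
    y_all = (sub["group"] == case).astype(int).to_numpy()
    if y_all.sum() < 2 or (1 - y_all).sum() < 2:
        raise ValueError("need at least 2 samples per class")

    leaked_list = None
    if leak_screening and spec.n_features != "all":
        ranked = rank_proteins_by_moderated_t(x_all, y_all)
        leaked_list = ranked[: spec.n_features]

    n = len(y_all)
    probs = np.empty(n)
    selected: list[list[str]] = []
    for i in range(n):
        train_idx = np.delete(np.arange(n), i)
        xtr_df = x_all.iloc[train_idx]
        ytr = y_all[train_idx]
        if spec.n_features == "all":
            feats = list(x_all.columns)
        elif leak_screening:
            feats = leaked_list
        else:
            ranked = rank_proteins_by_moderated_t(xtr_df, ytr)
            feats = ranked[: spec.n_features]
        selected.append(feats)
        xtr = xtr_df[feats].to_numpy(float)
        xte = x_all.iloc[[i]][feats].to_numpy(float)
        fseed = _fold_seed(spec.seed, i)
        if spec.learner == "elastic_net":
            predict = _tune_and_fit_en(xtr, ytr, spec, fseed)
            probs[i] = float(predict(xte)[0])
        else:
            rf = RandomForestClassifier(
                n_estimators=spec.rf_trees,
                max_features="sqrt",
                random_state=fseed,
            )
            rf.fit(xtr, ytr)
            pos = list(rf.classes_).index(1)
            probs[i] = float(rf.predict_proba(xte)[0, pos])

    pred = pd.DataFrame(
        {"sample_id": sub.index, "y_true": y_all, "prob": probs}
    ).reset_index(drop=True)
    return CvResult(pred, selected, positive_label=case, spec=spec, seed=spec.seed)


def roc_auc(y_true, scores) -> float:
    """ROC-AUC via the Mann–Whitney rank formulation with tie correction."""
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both classes to compute ROC-AUC")
    ranks = stats.rankdata(s, method="average")
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def delong_ci(y_true, scores, level: float = 0.95) -> tuple[float, float]:
    """DeLong variance-based confidence interval for the ROC-AUC."""
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, float)
    pos = s[y == 1]
    neg = s[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("need both classes")
    # placement values
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    auc = float(v10.mean())
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return (max(0.0, auc - half), min(1.0, auc + half))


def pr_auc(y_true, scores) -> float:
    """Area under the precision-recall curve by interpolation-free step
    summation: sum over recall increments of the precision at each
    threshold (equivalent to average precision)."""
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, float)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("no positive samples")
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1 - y_sorted)
    precision = tp / (tp + fp)
    recall = tp / n_pos
    # evaluate only at distinct-threshold boundaries
    distinct = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    prec = precision[distinct]
    rec = recall[distinct]
    rec_prev = np.r_[0.0, rec[:-1]]
    return float(np.sum((rec - rec_prev) * prec))


def evaluate_predictions(cv: CvResult, ci_level: float = 0.95, threshold: float = 0.5) -> MetricsReport:
    """Imbalance-aware metrics from out-of-fold predictions."""
    y = cv.predictions["y_true"].to_numpy(int)
    p = cv.predictions["prob"].to_numpy(float)
    if len(np.unique(y)) < 2:
        raise ValueError("single-class truth; metrics undefined")
    auc = roc_auc(y, p)
    ci = delong_ci(y, p, level=ci_level)
    ap = pr_auc(y, p)
    pred = (p >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    bal = 0.5 * (rec + (tn / (tn + fp) if tn + fp else 0.0))
    return MetricsReport(
        roc_auc=auc,
        roc_auc_ci=ci,
        ci_level=ci_level,
        pr_auc=ap,
        f1=f1,
        balanced_accuracy=bal,
        confusion={"tp": tp, "fp": fp, "tn": tn, "fn": fn},
        positive_label=cv.positive_label,
    )
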