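"""Per-protein moderated linear models.

For each protein at one visit an ordinary least-squares model of the MoM
value on a group indicator (or the birth-weight z-score) plus BMI and
nulliparity is fitted. Residual variances are then shrunk across proteins
toward an empirical-Bayes prior: the scaled inverse-chi-square prior
(d0, s0²) is estimated by moment matching on log s² (digamma/trigamma
expressions, trigamma inverted by Newton iteration), and the posterior
variance

    s̃²_g = (d0·s0² + d·s²_g) / (d0 + d)

replaces s²_g in the t statistic, which then has d0 + d degrees of
freedom. p-values are adjusted by Benjamini–Hochberg across proteins.

The machinery is exposed both as spec-level functions and as a
Model/Results pair: ``ModeratedLinearModel(Y, X).fit()`` returns a
``ModeratedLMResults`` with per-protein estimates, shrunken variances and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "build_design",
    "fit_linear_models",
    "empirical_bayes_moderation",
    "trigamma_inverse",
    "bh_adjust",
    "ModeratedLinearModel",
    "ModeratedLMResults",
    "moderated_t_table",
    "associate_with_zscore",
    "cross_visit_overlap",
]

Q_SIGNIFICANT = 0.05


def build_design(
    samples: pd.DataFrame,
    visit: int,
    contrast: str | None = None,
    zscore: bool = False,
    covariates: tuple[str, ...] = ("bmi", "nulliparous"),
) -> tuple[pd.DataFrame, pd.Index]:
    """Design matrix for one visit: intercept + group indicator (or z-score)
    + covariates; returns (design, sample index).

    contrast
        "LGA-AGA" or "SGA-AGA": restricts to the two groups, AGA reference.
    zscore
        Use the continuous birth-weight z-score instead of a group column.
    """
    sub = samples[samples["visit"] == visit]
    if zscore:
        effect = sub["birth_weight_z"].astype(float)
        effect_name = "birth_weight_z"
    else:
        if contrast is None:
            raise ValueError("need a contrast (e.g. 'LGA-AGA') or zscore=True")
        case, ref = contrast.split("-")
        sub = sub[sub["group"].isin([case, ref])]
        effect = (sub["group"] == case).astype(float)
        effect_name = contrast
    cols = {"intercept": np.ones(len(sub)), effect_name: effect.to_numpy(float)}
    for cov in covariates:
        cols[cov] = sub[cov].astype(float).to_numpy()
    design = pd.DataFrame(cols, index=sub.index)
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        raise ValueError(f"design matrix is rank-deficient (rank {rank} < {design.shape[1]} columns)")
    if len(design) < design.shape[1] + 2:
        raise ValueError(f"too few samples ({len(design)}) for {design.shape[1]} design columns")
    return design, design.index


def fit_linear_models(mom: pd.DataFrame, design: pd.DataFrame):
    """Vectorised OLS of every protein on the design.

    Returns (beta [p_proteins × p_cols], unscaled variances v [same shape],
    s² [per protein], residual df d, zero-residual mask).
    """
    x = design.to_numpy(float)
    y = mom.loc[design.index].to_numpy(float)
    n, pc = x.shape
    if n != y.shape[0]:
        raise ValueError("sample mismatch between matrix and design")
    xtx = x.T @ x
    if np.linalg.matrix_rank(xtx) < pc:
        corr = np.corrcoef(x, rowvar=False)
        raise ValueError(f"rank-deficient design; column correlations:\n{corr}")
    xtx_inv = np.linalg.inv(xtx)
    beta = y.T @ x @ xtx_inv  # proteins × cols
    fitted = x @ beta.T
    resid = y - fitted
    d = n - pc
    rss = np.sum(resid**2, axis=0)
    s2 = rss / d
    v = np.diag(xtx_inv)  # unscaled variance of each coefficient
    zero_resid = s2 <= 1e-12 * np.maximum(np.sum(y**2, axis=0) / n, 1e-300)
    return beta, np.broadcast_to(v, beta.shape), s2, d, zero_resid


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by monotone Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(100):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) / max(x, 1e-12) < 1e-10:
            return x
    raise RuntimeError(f"trigamma inversion did not converge for y={y}")


def empirical_bayes_moderation(s2: np.ndarray, d: int):
    """Estimate the scaled inverse-chi-square prior (d0, s0²) and posterior
    variances by moment matching on log s².

    With s²|σ² ~ σ²·χ²_d/d, E[log s²] and Var[log s²] have closed forms in
    digamma/trigamma; matching the observed mean and variance of
    log s² − ψ(d/2) + log(d/2) gives s0² and d0 (trigamma inverted by
    Newton). If the observed variance does not exceed the sampling
    contribution, d0 = ∞ and every posterior variance equals s0².

    Returns (d0, s0², s̃² vector).
    """
    s2 = np.asarray(s2, float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 10:
        raise ValueError(f"need >= 10 positive finite variances, have {ok.sum()}")
    if d < 1:
        raise ValueError("residual df must be >= 1")
    z = np.log(s2[ok])
    e = z - float(special.digamma(d / 2.0)) + np.log(d / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, d / 2.0))
    if evar <= 0:
        # no excess dispersion beyond sampling: infinite prior df; the prior
        # scale is the geometric mean of the observed s2 (== the common value
        # when they are all identical)
        d0 = np.inf
        s02 = float(np.exp(z.mean()))
        post = np.full_like(s2, s02)
        post[~ok] = np.nan
        return d0, s02, post
    d0 = 2.0 * trigamma_inverse(evar)
    s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    post = (d0 * s02 + d * s2) / (d0 + d)
    post[~ok] = np.nan
    return d0, s02, post


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment: q_i = min_{j>=i} p_(j)·m/j."""
    p = np.asarray(p, float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class ModeratedLMResults:
    """Per-protein moderated inference for one design column of interest.

    Attributes mirror the classical decomposition: ``coef`` (log2FC or
    slope), ``s2`` the residual variances, ``s2_post`` their empirically
    shrunken versions, ``t``/``p``/``q`` the moderated statistics on
    ``df_total`` = d0 + d degrees of freedom.
    """

    proteins: pd.Index
    coef: np.ndarray
    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    s2: np.ndarray
    s2_post: np.ndarray
    d0: float
    s02: float
    df_resid: int
    effect_name: str
    excluded: np.ndarray = field(default=None)

    @property
    def df_total(self) -> float:
        return self.d0 + self.df_resid

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "protein": np.asarray(self.proteins),
                "coef": self.coef,
                "t": self.t,
                "p": self.p,
                "q": self.q,
                "s2": self.s2,
                "s2_post": self.s2_post,
                "significant": self.q < Q_SIGNIFICANT,
            }
        )
        df.attrs.update(d0=self.d0, s02=self.s02, df_resid=self.df_resid,
                        effect=self.effect_name)
        return df

    def significant_proteins(self, q_cut: float = Q_SIGNIFICANT) -> set[str]:
        mask = np.nan_to_num(self.q, nan=1.0) < q_cut
        return set(np.asarray(self.proteins)[mask])


class ModeratedLinearModel:
    """Moderated per-protein linear model (limma-style empirical Bayes).

    Parameters
    ----------
    mom : DataFrame
        Samples × proteins matrix of MoM values (or any log2-scale matrix).
    design : DataFrame
        Samples × covariates design (aligned on index).
    effect : str
        Design column whose coefficient is tested.
    """

    def __init__(self, mom: pd.DataFrame, design: pd.DataFrame, effect: str):
        if effect not in design.columns:
            raise ValueError(f"effect column {effect!r} not in design")
        self.mom = mom
        self.design = design
        self.effect = effect

    @classmethod
    def from_dataframe(
        cls,
        mom: pd.DataFrame,
        samples: pd.DataFrame,
        visit: int,
        contrast: str | None = None,
        zscore: bool = False,
        covariates: tuple[str, ...] = ("bmi", "nulliparous"),
    ) -> "ModeratedLinearModel":
        design, idx = build_design(samples.loc[mom.index], visit, contrast, zscore, covariates)
        effect = "birth_weight_z" if zscore else contrast
        return cls(mom.loc[idx], design, effect)

    def fit(self, moderate: bool = True) -> ModeratedLMResults:
        beta, v, s2, d, zero_resid = fit_linear_models(self.mom, self.design)
        j = list(self.design.columns).index(self.effect)
        coef = beta[:, j]
        vj = v[:, j]
        usable = ~zero_resid
        if moderate:
            d0, s02, s2_post = empirical_bayes_moderation(s2[usable], d)
            post = np.full_like(s2, np.nan)
            post[usable] = s2_post
            df_total = d0 + d
        else:
            d0, s02 = 0.0, np.nan
            post = np.where(usable, s2, np.nan)
            df_total = d
        with np.errstate(divide="ignore", invalid="ignore"):
            t = coef / np.sqrt(post * vj)
        p = np.full_like(t, np.nan)
        finite = np.isfinite(t)
        if np.isinf(df_total):
            p[finite] = 2.0 * stats.norm.sf(np.abs(t[finite]))
        else:
            p[finite] = 2.0 * stats.t.sf(np.abs(t[finite]), df_total)
        q = np.full_like(p, np.nan)
        q[finite] = bh_adjust(p[finite])  # BH m excludes unmoderatable proteins
        return ModeratedLMResults(
            proteins=self.mom.columns,
            coef=coef,
            t=t,
            p=p,
            q=q,
            s2=s2,
            s2_post=post,
            d0=d0,
            s02=s02,
            df_resid=d,
            effect_name=self.effect,
            excluded=zero_resid,
        )


def moderated_t_table(
    mom: pd.DataFrame,
    samples: pd.DataFrame,
    visit: int,
    contrast: str,
    covariates: tuple[str, ...] = ("bmi", "nulliparous"),
) -> pd.DataFrame:
    """Per-protein moderated group contrast at one visit.

    Columns: protein, visit, contrast, log2fc, t, p, q, significant.
    """
    res = ModeratedLinearModel.from_dataframe(
        mom, samples, visit, contrast=contrast, covariates=covariates
    ).fit()
    out = res.summary().rename(columns={"coef": "log2fc"})
    out.insert(1, "visit", visit)
    out.insert(2, "contrast", contrast)
    return out.drop(columns=["s2", "s2_post"])


def associate_with_zscore(
    mom: pd.DataFrame,
    samples: pd.DataFrame,
    visit: int,
    covariates: tuple[str, ...] = ("bmi", "nulliparous"),
) -> pd.DataFrame:
    """Per-protein association with the birth-weight z-score at one visit,
    adjusted for the covariates; adds the unadjusted Spearman rho."""
    from .clinical import spearman_corr

    res = ModeratedLinearModel.from_dataframe(
        mom, samples, visit, zscore=True, covariates=covariates
    ).fit()
    out = res.summary().rename(columns={"coef": "slope"})
    out.insert(1, "visit", visit)
    sub = samples[samples["visit"] == visit]
    z = sub["birth_weight_z"].to_numpy(float)
    momv = mom.loc[sub.index]
    rho = [spearman_corr(momv[prot].to_numpy(), z)[0] for prot in momv.columns]
    out["spearman_rho"] = rho
    return out.drop(columns=["s2", "s2_post"])


def cross_visit_overlap(sets_by_visit: dict[int, set[str]]) -> dict[str, int]:
    """Counts of the 7 Venn regions of the three per-visit significant sets.

    Keys are visit-label combinations like "1", "1&2", "1&2&3"; "union" adds
    the total number of distinct proteins.
    """
    visits = sorted(sets_by_visit)
    if len(visits) != 3:
        raise ValueError("expected significant sets for exactly 3 visits")
    a, b, c = (sets_by_visit[v] for v in visits)
    la, lb, lc = (str(v) for v in visits)
    regions = {
        la: len(a - b - c),
        lb: len(b - a - c),
        lc: len(c - a - b),
        f"{la}&{lb}": len((a & b) - c),
        f"{la}&{lc}": len((a & c) - b),
        f"{lb}&{lc}": len((b & c) - a),
        f"{la}&{lb}&{lc}": len(a & b & c),
    }
    regions["union"] = len(a | b | c)
    return regions
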