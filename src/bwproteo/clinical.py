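"""Group comparisons of clinical variables.

Continuous variables are compared between birth-weight groups by Welch's
two-sample t test (unequal variances, Welch–Satterthwaite degrees of
freedom); categorical variables by Fisher's exact test on 2×2 or 2×3
tables via full enumeration of the conditional (multivariate
hypergeometric) distribution; correlations with the birth-weight z-score
use Spearman's rank correlation with the t approximation for the p-value.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import Z_CUTOFF

__all__ = [
    "TestResult",
    "classify_birth_weight",
    "welch_t",
    "welch_t_from_data",
    "fisher_exact_rxc",
    "spearman_corr",
    "clinical_summary",
]

MAX_ENUMERATION = 10**7


@dataclass
class TestResult:
    statistic: float
    p_value: float
    test: str
    df: float | None = None
    groups: tuple[str, str] | None = None


def classify_birth_weight(z: float) -> str:
    """Map a birth-weight z-score to its group: z > 1.3 → LGA, z < −1.3 →
    SGA, otherwise (boundaries included) AGA."""
    if not np.isfinite(z):
        raise ValueError(f"non-finite z-score: {z!r}")
    if z > Z_CUTOFF:
        return "LGA"
    if z < -Z_CUTOFF:
        return "SGA"
    return "AGA"


def welch_t(mean1, sd1, n1, mean2, sd2, n2, groups=None) -> TestResult:
    """Welch's two-sample t test from summary statistics.

    t = (m1 − m2) / sqrt(s1²/n1 + s2²/n2), with Welch–Satterthwaite df and a
    two-sided p from the t distribution.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    se2 = v1 + v2
    if se2 == 0:
        if mean1 == mean2:
            return TestResult(0.0, 1.0, "welch_t", df=np.nan, groups=groups)
        raise ValueError("zero variance in both groups with unequal means")
    t = (mean1 - mean2) / math.sqrt(se2)
    df = se2**2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(t, min(p, 1.0), "welch_t", df=df, groups=groups)


def welch_t_from_data(x, y, groups=None) -> TestResult:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    return welch_t(x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y), groups=groups)


def _log_table_prob(table: np.ndarray, lgfact_row, lgfact_col, lgfact_n) -> float:
    # multivariate hypergeometric probability of a 2×C table with its margins
    return (
        lgfact_row + lgfact_col - lgfact_n
        - sum(math.lgamma(v + 1) for v in table.ravel())
    )


def fisher_exact_rxc(table) -> TestResult:
    """Fisher's exact test for a 2×C table (C = 2 or 3) by full enumeration.

    The two-sided p-value sums the conditional probabilities of all tables
    with the observed margins whose probability does not exceed that of the
    observed table (relative tolerance 1 + 1e−7, matching the convention
    needed to reproduce published knife-edge values).
    """
    obs = np.asarray(table, dtype=int)
    if obs.ndim != 2 or obs.shape[0] != 2 or obs.shape[1] not in (2, 3):
        raise ValueError(f"table must be 2×2 or 2×3, got shape {obs.shape}")
    if (obs < 0).any():
        raise ValueError("table entries must be nonnegative integers")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    n = int(obs.sum())
    if n == 0:
        return TestResult(np.nan, 1.0, "fisher_exact")
    if row.min() == 0 or (col > 0).sum() <= 1:
        # only one attainable table with these margins
        return TestResult(np.nan, 1.0, "fisher_exact")

    lg_row = sum(math.lgamma(r + 1) for r in row)
    lg_col = sum(math.lgamma(c + 1) for c in col)
    lg_n = math.lgamma(n + 1)

    # enumerate first-row entries; second row is forced by the column margins
    ranges = [range(min(row[0], c) + 1) for c in col[:-1]]
    n_tables = int(np.prod([len(r) for r in ranges]))
    if n_tables > MAX_ENUMERATION:
        raise ValueError(f"enumeration too large ({n_tables} candidate tables)")

    lp_obs = _log_table_prob(obs, lg_row, lg_col, lg_n)
    log_tol = math.log1p(1e-7)
    total = 0.0
    p_two = 0.0
    for first in itertools.product(*ranges):
        last = row[0] - sum(first)
        if last < 0 or last > col[-1]:
            continue
        top = np.array(list(first) + [last])
        bottom = col - top
        if (bottom < 0).any():
            continue
        cand = np.vstack([top, bottom])
        lp = _log_table_prob(cand, lg_row, lg_col, lg_n)
        pr = math.exp(lp)
        total += pr
        if lp <= lp_obs + log_tol:
            p_two += pr
    assert abs(total - 1.0) < 1e-9, f"enumeration probabilities sum to {total}"
    return TestResult(math.exp(lp_obs), min(p_two, 1.0), "fisher_exact")


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def spearman_corr(x, y, exact: bool = False) -> tuple[float, float]:
    """Spearman rho on mid-ranks with a two-sided p-value.

    The default p uses the t approximation t = rho·sqrt((n−2)/(1−rho²));
    ``exact=True`` enumerates all permutations (n ≤ 9 only).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-D arrays with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    rx, ry = _midranks(x), _midranks(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = len(x)
    if exact:
        if n > 9:
            raise ValueError("exact permutation p only supported for n <= 9")
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = float(np.corrcoef(rx, ry[list(perm)])[0, 1])
            total += 1
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        return rho, count / total
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1 - rho**2))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return rho, min(p, 1.0)


_PAIRS = (("SGA", "AGA"), ("LGA", "AGA"), ("SGA", "LGA"))


def clinical_summary(samples: pd.DataFrame, continuous=("gestational_age", "bmi", "birth_weight_z")) -> pd.DataFrame:
    """Demographics-style table: per-group mean (SD) of continuous variables
    and pairwise Welch p-values; nulliparity and sex by Fisher's exact test.

    Operates on one row per participant (visit-level variables like
    gestational age are summarised per visit).
    """
    per_part = samples.drop_duplicates("participant_id")
    rows = []

    def add_continuous(name, frame, col):
        entry = {"variable": name}
        vals = {}
        for g in ("SGA", "AGA", "LGA"):
            v = frame.loc[frame["group"] == g, col].to_numpy(float)
            vals[g] = v
            entry[f"{g}_mean"] = v.mean() if len(v) else np.nan
            entry[f"{g}_sd"] = v.std(ddof=1) if len(v) > 1 else np.nan
        for a, b in _PAIRS:
            if len(vals[a]) >= 2 and len(vals[b]) >= 2:
                entry[f"p_{a}_vs_{b}"] = welch_t_from_data(vals[a], vals[b]).p_value
            else:
                entry[f"p_{a}_vs_{b}"] = np.nan
        rows.append(entry)

    def add_binary(name, series):
        entry = {"variable": name}
        for g in ("SGA", "AGA", "LGA"):
            s = series[per_part["group"] == g]
            entry[f"{g}_mean"] = s.mean()
            entry[f"{g}_sd"] = np.nan
        for a, b in _PAIRS:
            tab = []
            for g in (a, b):
                s = series[per_part["group"] == g].astype(bool)
                tab.append([int(s.sum()), int((~s).sum())])
            entry[f"p_{a}_vs_{b}"] = fisher_exact_rxc(tab).p_value
        rows.append(entry)

    for col in continuous:
        if col == "gestational_age":
            for v in (1, 2, 3):
                add_continuous(f"gestational_age_v{v}", samples[samples["visit"] == v], col)
        else:
            add_continuous(col, per_part, col)
    if "nulliparous" in per_part.columns:
        add_binary("nulliparous", per_part["nulliparous"])
    if "sex" in per_part.columns:
        add_binary("sex_female", per_part["sex"] == "F")
    return pd.DataFrame(rows)
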