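"""Synthetic longitudinal cohort generator.

Emulates the statistical structure of a three-visit pregnancy proteomics
study: group sizes, gestational-age windows, smooth per-protein gestational
trends, participant random intercepts, group effects on a configurable
protein subset, and multiplicative outliers — together with a ground-truth
record so parameter recovery is testable downstream.

The generative model for the log2 abundance of protein g in sample
(participant i, visit v) is

    log2 RFU = b_g + f_g(GA_iv) + u_i + delta_g(group_i, v) + eps,

with b_g a protein baseline, f_g a smooth trend in gestational age
(random quadratic plus optional sinusoid), u_i ~ N(0, sigma_u^2) a
participant intercept, delta_g a group effect on flagged proteins only,
and eps ~ N(0, sigma_e^2) measurement noise. RFU = 2**log2RFU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import CohortConfig, ConfigError, GROUPS, Z_CUTOFF

GA_CENTER = 23.0  # weeks; trend polynomials are centered here

__all__ = ["TruthRecord", "generate_cohort", "inject_outliers"]


@dataclass
class TruthRecord:
    """Ground truth of a generated cohort.

    proteins
        One row per protein: differential flags per contrast, per-visit true
        effects (log2 units) and the trend-function parameters.
    participants
        One row per participant: the random-intercept value (log2 units).
    """

    proteins: pd.DataFrame
    participants: pd.DataFrame

    def to_csv(self, path) -> None:
        self.proteins.to_csv(path, index=False)


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _sample_zscores(rng, group: str, mean: float, sd: float, n: int) -> np.ndarray:
    # truncate to the group's defining interval so labels always hold;
    # a hair inside the cutoff keeps the strict inequalities strict
    eps = 1e-9
    if group == "SGA":
        lo, hi = -np.inf, -Z_CUTOFF - eps
    elif group == "LGA":
        lo, hi = Z_CUTOFF + eps, np.inf
    else:
        lo, hi = -Z_CUTOFF, Z_CUTOFF
    return _truncnorm(rng, mean, sd, lo, hi, n)


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Generate (sample table, RFU matrix, truth record) from ``config``.

    Returns
    -------
    samples : DataFrame
        One row per participant-visit with columns participant_id, visit,
        gestational_age, group, birth_weight_z, bmi, nulliparous, sex.
    rfu : DataFrame
        Samples (rows, indexed by sample id "<participant>_v<visit>") ×
        proteins (columns P0001..), strictly positive RFU values.
    truth : TruthRecord
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_part = config.n_sga + config.n_aga + config.n_lga
    groups = np.repeat(GROUPS, [config.n_sga, config.n_aga, config.n_lga])
    pid = np.array([f"P{i + 1:03d}" for i in range(n_part)])

    z = np.empty(n_part)
    for g in GROUPS:
        mask = groups == g
        mean, sd = config.zscore_params[g]
        z[mask] = _sample_zscores(rng, g, mean, sd, int(mask.sum()))

    bmi = rng.normal(*config.bmi_params, size=n_part)
    nullip = rng.random(n_part) < config.nullip_prob
    sex = np.where(rng.random(n_part) < config.female_prob, "F", "M")
    u = rng.normal(0.0, config.random_intercept_sd, size=n_part)

    rows = []
    for v, ((lo, hi), (mean, sd)) in enumerate(zip(config.visit_windows, config.ga_mean_sd), start=1):
        ga = _truncnorm(rng, mean, sd, lo, hi, n_part)
        for i in range(n_part):
            rows.append(
                {
                    "participant_id": pid[i],
                    "visit": v,
                    "gestational_age": ga[i],
                    "group": groups[i],
                    "birth_weight_z": z[i],
                    "bmi": bmi[i],
                    "nulliparous": nullip[i],
                    "sex": sex[i],
                }
            )
    samples = pd.DataFrame(rows).sort_values(["participant_id", "visit"], kind="stable")
    samples.index = samples["participant_id"] + "_v" + samples["visit"].astype(str)
    samples.index.name = "sample_id"

    # protein-level truth
    p = config.n_proteins
    prot = np.array([f"G{j + 1:04d}" for j in range(p)])  # synthetic gene-style names
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=p)
    slope = rng.normal(0.0, config.trend_slope_sd, size=p)
    quad = rng.normal(0.0, config.trend_quad_sd, size=p)
    amp = np.full(p, config.trend_sin_amplitude)
    phase = rng.uniform(0.0, 2 * np.pi, size=p)

    is_lga = np.zeros(p, bool)
    is_sga = np.zeros(p, bool)
    is_lga[: config.n_diff_lga] = True
    is_sga[config.n_diff_lga : config.n_diff_lga + config.n_diff_sga] = True
    eff = np.asarray(config.effect_by_visit())

    ga_all = samples["gestational_age"].to_numpy()
    visit_all = samples["visit"].to_numpy()
    grp_all = samples["group"].to_numpy()
    u_all = samples["participant_id"].map(dict(zip(pid, u))).to_numpy()

    du = ga_all - GA_CENTER
    # n_samples × p trend surface
    trend = (
        np.outer(du, slope)
        + np.outer(du**2, quad)
        + amp * np.sin(2 * np.pi * ga_all[:, None] / config.trend_sin_period + phase)
    )
    log2 = baseline + trend + u_all[:, None]
    eff_v = eff[visit_all - 1]  # per-sample effect magnitude
    log2[:, is_lga] += np.where(grp_all == "LGA", eff_v, 0.0)[:, None]
    log2[:, is_sga] += np.where(grp_all == "SGA", eff_v, 0.0)[:, None]
    log2 += rng.normal(0.0, config.noise_sd, size=log2.shape)

    rfu = pd.DataFrame(np.exp2(log2), index=samples.index, columns=prot)
    if config.outlier_rate > 0:
        rfu = inject_outliers(rfu, config.outlier_rate, config.outlier_factor,
                              seed=int(rng.integers(2**31)))

    truth_prot = pd.DataFrame(
        {
            "protein_id": prot,
            "is_diff_lga": is_lga,
            "is_diff_sga": is_sga,
            "baseline": baseline,
            "trend_slope": slope,
            "trend_quad": quad,
            "trend_sin_amplitude": amp,
            "trend_sin_phase": phase,
        }
    )
    for v in (1, 2, 3):
        truth_prot[f"lga_effect_v{v}"] = np.where(is_lga, eff[v - 1], 0.0)
        truth_prot[f"sga_effect_v{v}"] = np.where(is_sga, eff[v - 1], 0.0)
    truth_part = pd.DataFrame({"participant_id": pid, "group": groups, "random_intercept": u})
    return samples, rfu, TruthRecord(truth_prot, truth_part)


def inject_outliers(matrix: pd.DataFrame, rate: float, factor: float, seed: int = 0) -> pd.DataFrame:
    """Multiply ⌊rate·n_entries⌋ uniformly chosen entries by ``factor``.

    Returns a new matrix; the input is not modified.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate must be in [0, 1], got {rate}")
    if factor <= 1.0:
        raise ValueError(f"factor must be > 1, got {factor}")
    out = matrix.copy()
    n_entries = out.size
    k = int(np.floor(rate * n_entries))
    if k == 0:
        return out
    rng = np.random.default_rng(seed)
    flat = rng.choice(n_entries, size=k, replace=False)
    vals = out.to_numpy()
    vals.flat[flat] = vals.flat[flat] * factor
    out.iloc[:, :] = vals
    return out
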