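"""Preprocessing of raw RFU matrices into MoM (multiples-of-the-mean) values.

Pipeline order: winsorize → log2 → fit per-protein gestational reference
curves on the AGA samples → subtract the fitted value from every sample's
log2 abundance. The resulting MoM matrix is a detrended log2-deviation
scale on which gestational-age variability within a visit no longer
confounds group comparisons. Per-visit PCA summarises sample structure on
that scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .splines import CANDIDATE_K, SplineFit, fit_penalized_spline, select_best_k

__all__ = [
    "winsorize",
    "log2_transform",
    "GamFit",
    "fit_reference_curve",
    "fit_all_reference_curves",
    "compute_mom",
    "pca_by_visit",
    "PcaResult",
    "preprocess_pipeline",
]


def winsorize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Clip each protein's values at twice its 98th percentile.

    The threshold is 2 × Q98 computed per protein (column) on the incoming
    values, pooled across all samples and visits; values above it are set to
    exactly the threshold. Quantiles use linear interpolation between order
    statistics. Values at or below the threshold are untouched, so the
    operation never increases a value and is idempotent in practice
    (re-clipping can only raise thresholds, never produce new exceedances).
    """
    out = matrix.copy()
    vals = out.to_numpy(float)
    n_rows = vals.shape[0]
    if n_rows < 2:
        warnings.warn("winsorize: fewer than 2 samples; matrix returned unchanged")
        return out
    q98 = np.quantile(vals, 0.98, axis=0)  # linear-interpolation convention
    thresh = 2.0 * q98
    clipped = np.minimum(vals, thresh)
    out.iloc[:, :] = clipped
    return out


def log2_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2; rejects non-positive cells with coordinates."""
    vals = matrix.to_numpy(float)
    bad = ~np.isfinite(vals) | (vals <= 0)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"non-positive value at sample {matrix.index[r]!r}, "
            f"protein {matrix.columns[c]!r}: {vals[r, c]!r}"
        )
    out = matrix.copy()
    out.iloc[:, :] = np.log2(vals)
    return out


@dataclass
class GamFit:
    """Per-protein reference curve of log2 abundance over gestational age,
    fitted on the reference (AGA) samples only."""

    protein_id: str
    spline: SplineFit
    fallback_linear: bool = False

    @property
    def k(self) -> int:
        return self.spline.k

    @property
    def r_squared(self) -> float:
        return self.spline.r_squared

    @property
    def fit_range(self) -> tuple[float, float]:
        return self.spline.x_range

    def predict(self, ga) -> np.ndarray:
        return self.spline.predict(ga)


def fit_reference_curve(
    log_values: np.ndarray,
    gestational_ages: np.ndarray,
    aga_mask: np.ndarray,
    candidate_k=CANDIDATE_K,
    smoothing: float | None = None,
    protein_id: str = "",
) -> GamFit:
    """Fit the gestational reference smooth for one protein.

    For each basis dimension k in ``candidate_k`` a penalized spline is
    fitted to the AGA samples; the k with the highest r² on those points
    wins (ties toward smaller k). With too few AGA points the fit falls back
    to a least-squares line with a warning.

    smoothing
        Fixed penalty weight; ``None`` = GCV. Pass 0 for the unpenalized
        regression-spline variant.
    """
    y = np.asarray(log_values, float)[aga_mask]
    x = np.asarray(gestational_ages, float)[aga_mask]
    kmax = max(candidate_k)
    if len(np.unique(x)) < kmax + 2:
        warnings.warn(
            f"protein {protein_id!r}: too few distinct reference ages "
            f"({len(np.unique(x))} < {kmax + 2}); falling back to a line"
        )
        # degree-1 basis of dimension 2 == least-squares line
        fit = fit_penalized_spline(x, y, k=2, smoothing=0.0)
        return GamFit(protein_id, fit, fallback_linear=True)
    fit = select_best_k(x, y, candidate_k, smoothing=smoothing)
    return GamFit(protein_id, fit)


def fit_all_reference_curves(
    log_matrix: pd.DataFrame,
    samples: pd.DataFrame,
    candidate_k=CANDIDATE_K,
    smoothing: float | None = None,
    reference_group: str = "AGA",
) -> dict[str, GamFit]:
    """Fit reference curves for every protein in the matrix."""
    aligned = samples.loc[log_matrix.index]
    ga = aligned["gestational_age"].to_numpy(float)
    mask = (aligned["group"] == reference_group).to_numpy()
    if mask.sum() < 3:
        raise ValueError(f"need at least 3 {reference_group} samples, have {mask.sum()}")
    return {
        prot: fit_reference_curve(
            log_matrix[prot].to_numpy(), ga, mask, candidate_k, smoothing, protein_id=prot
        )
        for prot in log_matrix.columns
    }


def compute_mom(log_matrix: pd.DataFrame, fits: dict[str, GamFit], samples: pd.DataFrame) -> pd.DataFrame:
    """MoM[s, g] = log2RFU[s, g] − fitted reference curve g evaluated at GA_s.

    Applied to ALL samples (non-reference groups included); ages outside a
    protein's fitted range use the spline's linear boundary extrapolation.
    """
    missing = [p for p in log_matrix.columns if p not in fits]
    if missing:
        raise ValueError(f"missing reference fits for proteins: {missing[:5]}")
    ga = samples.loc[log_matrix.index, "gestational_age"].to_numpy(float)
    out = log_matrix.copy()
    for prot in log_matrix.columns:
        out[prot] = log_matrix[prot].to_numpy(float) - fits[prot].predict(ga)
    return out


@dataclass
class PcaResult:
    """Column-centered PCA of one visit's MoM submatrix."""

    visit: int
    scores: pd.DataFrame  # samples × components
    loadings: pd.DataFrame  # proteins × components
    explained_variance_ratio: np.ndarray


def pca_by_visit(mom: pd.DataFrame, samples: pd.DataFrame, visit: int, n_components: int | None = None) -> PcaResult:
    """PCA of the centered MoM values of one visit (no variance scaling:
    MoM values already share a common log2-deviation scale)."""
    vmask = (samples.loc[mom.index, "visit"] == visit).to_numpy()
    sub = mom.loc[vmask]
    if len(sub) < 3:
        raise ValueError(f"visit {visit}: need >= 3 samples for PCA, have {len(sub)}")
    x = sub.to_numpy(float)
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    if n_components is None:
        n_components = len(s)
    n_components = min(n_components, len(s))
    var = s**2 / (len(sub) - 1)
    ratio = var / var.sum() if var.sum() > 0 else var
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    scores = pd.DataFrame((u * s)[:, :n_components], index=sub.index, columns=comp_names)
    loadings = pd.DataFrame(vt[:n_components].T, index=mom.columns, columns=comp_names)
    return PcaResult(visit, scores, loadings, ratio[:n_components])


def preprocess_pipeline(
    rfu: pd.DataFrame,
    samples: pd.DataFrame,
    candidate_k=CANDIDATE_K,
    smoothing: float | None = None,
    pass_list: list[str] | None = None,
):
    """winsorize → log2 → reference fits → MoM, returning every stage.

    pass_list
        Optional protein pass-list filter (quality filtration analogue):
        restrict the matrix to these ids before any other step.
    """
    if pass_list is not None:
        missing = [p for p in pass_list if p not in rfu.columns]
        if missing:
            raise ValueError(f"pass_list proteins absent from matrix: {missing[:5]}")
        rfu = rfu[pass_list]
    wins = winsorize(rfu)
    logm = log2_transform(wins)
    fits = fit_all_reference_curves(logm, samples, candidate_k, smoothing)
    mom = compute_mom(logm, fits, samples)
    return wins, logm, fits, mom


def fit_summary_table(fits: dict[str, GamFit]) -> pd.DataFrame:
    rows = [
        {
            "protein": p,
            "k": f.k,
            "r_squared": f.r_squared,
            "smoothing_parameter": f.spline.smoothing_parameter,
            "fit_lo": f.fit_range[0],
            "fit_hi": f.fit_range[1],
            "fallback_linear": f.fallback_linear,
        }
        for p, f in fits.items()
    ]
    return pd.DataFrame(rows)
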