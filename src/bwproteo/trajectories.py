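"""Mean longitudinal abundance curves per birth-weight group.

For selected proteins, a penalized-spline smooth of winsorized log2 RFU on
gestational age is fitted separately within each group (basis dimension
k in {3,4,5,6}, highest r² wins) and sampled on a 100-point grid spanning
that group's observed gestational-age range. Shares the spline engine with
the MoM reference curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .splines import CANDIDATE_K, SplineFit, select_best_k

__all__ = ["TrajectoryFit", "fit_group_trajectories", "export_trajectories"]

GRID_POINTS = 100


@dataclass
class TrajectoryFit:
    protein: str
    group: str
    spline: SplineFit
    grid: np.ndarray  # gestational-age grid (weeks)
    values: np.ndarray  # fitted log2 RFU on the grid

    @property
    def k(self) -> int:
        return self.spline.k

    @property
    def r_squared(self) -> float:
        return self.spline.r_squared


def fit_group_trajectories(
    log_matrix: pd.DataFrame,
    samples: pd.DataFrame,
    protein: str,
    groups=("SGA", "AGA", "LGA"),
    candidate_k=CANDIDATE_K,
) -> list[TrajectoryFit]:
    """One fitted curve per group for ``protein``; under-sized groups
    (fewer than max(k)+2 distinct gestational ages) are skipped with a
    warning."""
    if protein not in log_matrix.columns:
        raise KeyError(f"protein {protein!r} not in matrix")
    aligned = samples.loc[log_matrix.index]
    fits = []
    kmax = max(candidate_k)
    for group in groups:
        mask = (aligned["group"] == group).to_numpy()
        ga = aligned.loc[mask, "gestational_age"].to_numpy(float)
        y = log_matrix.loc[mask, protein].to_numpy(float)
        if len(np.unique(ga)) < kmax + 2:
            warnings.warn(
                f"group {group}: only {len(np.unique(ga))} distinct gestational "
                f"ages (< {kmax + 2}); trajectory skipped"
            )
            continue
        order = np.argsort(ga, kind="stable")
        spline = select_best_k(ga[order], y[order], candidate_k)
        grid = np.linspace(ga.min(), ga.max(), GRID_POINTS)
        fits.append(TrajectoryFit(protein, group, spline, grid, spline.predict(grid)))
    return fits


def export_trajectories(fits: list[TrajectoryFit], path) -> pd.DataFrame:
    """Write a TSV of (protein, group, gestational_age, fitted_log2_rfu),
    sorted by (protein, group, gestational_age)."""
    rows = []
    for f in fits:
        for ga, val in zip(f.grid, f.values):
            rows.append(
                {
                    "protein": f.protein,
                    "group": f.group,
                    "gestational_age": ga,
                    "fitted_log2_rfu": val,
                    "k": f.k,
                    "r_squared": f.r_squared,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["protein", "group", "gestational_age", "fitted_log2_rfu", "k", "r_squared"],
    )
    df = df.sort_values(["protein", "group", "gestational_age"], kind="stable")
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return df
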