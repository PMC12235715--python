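"""Run configuration for the synthetic cohort generator.

The defaults mirror the design of the study cohort the pipeline targets:
70 pregnant participants (7 SGA / 58 AGA / 5 LGA by birth-weight z-score
cutoffs at ±1.3), sampled at three gestational-age windows (12–19, 21–27
and 28–34 weeks), with thousands of plasma proteins measured in relative
fluorescence units (RFU).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml

GROUPS = ("SGA", "AGA", "LGA")

#: z-score cutoff defining SGA (< -1.3) and LGA (> 1.3); boundaries are AGA.
Z_CUTOFF = 1.3


class ConfigError(ValueError):
    """Raised when a cohort configuration violates an invariant."""


@dataclass
class CohortConfig:
    """Parameters of the synthetic longitudinal cohort.

    Attributes
    ----------
    n_sga, n_aga, n_lga
        Participants per birth-weight group.
    visit_windows
        Three non-overlapping, increasing gestational-age intervals (weeks).
    ga_mean_sd
        Per-visit (mean, sd) of gestational age at sampling; draws are
        truncated to the visit window.
    n_proteins
        Number of simulated proteins. 500 keeps the full pipeline fast at
        desk scale; the study's assay scale (~4565 post-QC) is available by
        raising this.
    n_diff_lga, n_diff_sga
        Number of proteins with a true LGA-vs-AGA (resp. SGA-vs-AGA) group
        effect. Defaults keep the study's differential fractions
        (148/4565 and 4/4565) roughly proportional at 500 proteins.
    effect_size
        True group effect in log2 units; a scalar (constant across visits)
        or a length-3 sequence (per visit).
    zscore_params
        Per-group (mean, sd) of birth-weight z; sampling is truncated to the
        group's defining interval so labels are always consistent.
    bmi_params
        (mean, sd) of maternal BMI in kg/m².
    nullip_prob, female_prob
        Bernoulli probabilities for nulliparity and fetal sex (female).
    trend_slope_sd, trend_quad_sd, trend_sin_amplitude, trend_sin_period
        Per-protein smooth gestational trend f(GA): a random quadratic
        (slope/curvature SDs in log2 per week, per week²) plus an optional
        sinusoid (amplitude log2 units, period weeks).
    baseline_mean, baseline_sd
        Per-protein baseline log2 RFU level.
    random_intercept_sd
        Between-participant SD (log2 units) shared across a participant's
        three samples.
    noise_sd
        Residual measurement noise SD (log2 units).
    outlier_rate, outlier_factor
        Fraction of matrix entries multiplied by ``outlier_factor`` on the
        RFU scale (heavy-tailed spikes); 0 disables.
    seed
        Master seed; the generator is fully reproducible from it.
    """

    n_sga: int = 7
    n_aga: int = 58
    n_lga: int = 5
    visit_windows: Sequence[tuple[float, float]] = ((12.0, 19.0), (21.0, 27.0), (28.0, 34.0))
    ga_mean_sd: Sequence[tuple[float, float]] = ((15.7, 1.2), (23.4, 1.0), (31.3, 0.97))
    n_proteins: int = 500
    n_diff_lga: int = 16
    n_diff_sga: int = 4
    effect_size: float | Sequence[float] = 1.0
    zscore_params: dict = field(
        default_factory=lambda: {"SGA": (-1.9, 0.35), "AGA": (-0.12, 0.58), "LGA": (1.7, 0.30)}
    )
    bmi_params: tuple[float, float] = (24.1, 2.8)
    nullip_prob: float = 0.5
    female_prob: float = 0.44
    trend_slope_sd: float = 0.03
    trend_quad_sd: float = 0.003
    trend_sin_amplitude: float = 0.1
    trend_sin_period: float = 20.0
    baseline_mean: float = 10.0
    baseline_sd: float = 1.5
    random_intercept_sd: float = 0.3
    noise_sd: float = 0.25
    outlier_rate: float = 0.0
    outlier_factor: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("n_sga", "n_aga", "n_lga", "n_proteins", "n_diff_lga", "n_diff_sga"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 0:
                raise ConfigError(f"{name} must be a nonnegative integer, got {v!r}")
        if self.n_diff_lga + self.n_diff_sga > self.n_proteins:
            raise ConfigError(
                "n_diff_lga + n_diff_sga exceeds n_proteins "
                f"({self.n_diff_lga}+{self.n_diff_sga} > {self.n_proteins})"
            )
        if len(self.visit_windows) != 3 or len(self.ga_mean_sd) != 3:
            raise ConfigError("visit_windows and ga_mean_sd must each have 3 entries")
        prev_hi = -float("inf")
        for lo, hi in self.visit_windows:
            if not lo < hi:
                raise ConfigError(f"visit_windows interval ({lo}, {hi}) is not increasing")
            if lo < prev_hi:
                raise ConfigError("visit_windows overlap or are out of order")
            prev_hi = hi
        for name in ("trend_slope_sd", "trend_quad_sd", "trend_sin_amplitude",
                     "baseline_sd", "random_intercept_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for g in GROUPS:
            if g not in self.zscore_params:
                raise ConfigError(f"zscore_params missing group {g}")
            if self.zscore_params[g][1] <= 0:
                raise ConfigError(f"zscore_params[{g}] sd must be > 0")
        for _, sd in self.ga_mean_sd:
            if sd <= 0:
                raise ConfigError("ga_mean_sd sds must be > 0")
        if self.bmi_params[1] <= 0:
            raise ConfigError("bmi_params sd must be > 0")
        for name in ("nullip_prob", "female_prob", "outlier_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.outlier_factor <= 1.0:
            raise ConfigError(f"outlier_factor must be > 1, got {self.outlier_factor}")
        eff = self.effect_size
        if not isinstance(eff, (int, float)) and len(eff) != 3:
            raise ConfigError("effect_size must be a scalar or a length-3 sequence")

    def effect_by_visit(self) -> tuple[float, float, float]:
        """Resolve ``effect_size`` to one value per visit."""
        if isinstance(self.effect_size, (int, float)):
            return (float(self.effect_size),) * 3
        return tuple(float(e) for e in self.effect_size)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["visit_windows"] = [list(w) for w in self.visit_windows]
        d["ga_mean_sd"] = [list(w) for w in self.ga_mean_sd]
        d["zscore_params"] = {k: list(v) for k, v in self.zscore_params.items()}
        d["bmi_params"] = list(self.bmi_params)
        if not isinstance(d["effect_size"], (int, float)):
            d["effect_size"] = list(d["effect_size"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        for key in ("visit_windows", "ga_mean_sd"):
            if key in d:
                d[key] = [tuple(w) for w in d[key]]
        if "zscore_params" in d:
            d["zscore_params"] = {k: tuple(v) for k, v in d["zscore_params"].items()}
        if "bmi_params" in d:
            d["bmi_params"] = tuple(d["bmi_params"])
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)
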