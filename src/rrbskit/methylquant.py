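"""MethylQuant-style qPCR validation statistics.

Bisulfite-converted DNA is amplified with a discriminatory (D) primer pair
ending on the methylation-state-specific base and a nondiscriminatory (ND)
pair. The methylation ratio between two conditions is the
efficiency-corrected fold change of the D signal normalized by the ND
signal:

    ratio = eff_D ** (mean Ct_D,2 - mean Ct_D,1)
          / eff_ND ** (mean Ct_ND,2 - mean Ct_ND,1)

Amplification efficiency per replicate comes from a window-of-linearity
fit: the sliding window of the log-fluorescence curve with the best
linear fit gives the slope s and efficiency 10**s. Significance is a
permutation test that reallocates condition labels within each primer
class and compares |log ratio| of the reallocations against the observed
value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError


@dataclass(frozen=True)
class AmplificationCurve:
    """One qPCR amplification curve (fluorescence by cycle)."""

    cycles: tuple[int, ...]
    fluorescence: tuple[float, ...]
    replicate_id: str = "r1"
    sample_id: str = "s1"
    primer_class: str = "D"  # D | ND
    condition: str = "treated"  # treated | control

    def __post_init__(self):
        if len(self.cycles) != len(self.fluorescence):
            raise ConfigurationError("cycles/fluorescence length mismatch")
        if any(b <= a for a, b in zip(self.cycles, self.cycles[1:])):
            raise ConfigurationError("cycles must be strictly increasing")
        if any(f < 0 for f in self.fluorescence):
            raise ConfigurationError("fluorescence must be non-negative")


@dataclass(frozen=True)
class EfficiencyEstimate:
    efficiency: float  # fold amplification per cycle, ~ (1, 2]
    r_squared: float
    window_start: int  # cycle at which the best window begins
    flagged: bool  # no convincing exponential phase found


@dataclass(frozen=True)
class RatioResult:
    ratio: float
    p_value: float
    n_permutations: int
    seed: int

    def __post_init__(self):
        if self.ratio <= 0:
            raise ConfigurationError("ratio must be positive")
        if self.p_value < 1.0 / (self.n_permutations + 1) - 1e-12:
            raise ConfigurationError("p-value below attainable minimum")

    def as_dict(self) -> dict:
        return {
            "ratio": self.ratio,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }


def estimate_efficiency(
    curve: AmplificationCurve,
    window: int = 5,
    min_r_squared: float = 0.99,
    baseline_factor: float = 3.0,
) -> EfficiencyEstimate:
    """Window-of-linearity efficiency estimate from one curve.

    Points above baseline (``baseline_factor`` times the median of the
    first five fluorescence readings) are scanned with a sliding window of
    ``window`` cycles; the window maximizing the coefficient of
    determination of the log10-linear fit yields slope s and efficiency
    10**s. If even the best window fits worse than ``min_r_squared`` the
    estimate is flagged (no clean exponential phase).
    """
    if window < 2:
        raise ConfigurationError("window must be >= 2")
    f = np.asarray(curve.fluorescence, dtype=float)
    cyc = np.asarray(curve.cycles, dtype=float)
    baseline = baseline_factor * float(np.median(f[:5]))
    mask = f > max(baseline, 0.0)
    if mask.sum() < window:
        raise ConfigurationError(
            "not enough above-baseline points for the requested window"
        )
    cyc, logf = cyc[mask], np.log10(f[mask])
    best: Optional[tuple[float, float, float]] = None  # (r2, slope, start)
    for i in range(len(cyc) - window + 1):
        x, y = cyc[i : i + window], logf[i : i + window]
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
        if best is None or r2 > best[0]:
            best = (r2, slope, x[0])
    r2, slope, start = best
    return EfficiencyEstimate(
        efficiency=float(10.0**slope),
        r_squared=r2,
        window_start=int(start),
        flagged=r2 < min_r_squared,
    )


def average_efficiency(
    curves: Sequence[AmplificationCurve], window: int = 5, **kwargs
) -> float:
    """Arithmetic mean of per-replicate window-of-linearity efficiencies."""
    if not curves:
        raise ConfigurationError("no curves supplied")
    return float(
        np.mean([estimate_efficiency(c, window=window, **kwargs).efficiency for c in curves])
    )


def methylation_ratio(
    ct_D_cond1: Sequence[float],
    ct_D_cond2: Sequence[float],
    ct_ND_cond1: Sequence[float],
    ct_ND_cond2: Sequence[float],
    eff_D: float,
    eff_ND: float,
) -> float:
    """Efficiency-corrected, ND-normalized condition1/condition2 ratio."""
    for eff in (eff_D, eff_ND):
        if not 1.0 < eff <= 2.0:
            raise ConfigurationError("efficiencies must lie in (1, 2]")
    for ct in (ct_D_cond1, ct_D_cond2, ct_ND_cond1, ct_ND_cond2):
        if len(ct) == 0:
            raise ConfigurationError("empty Ct list")
    d_delta = float(np.mean(ct_D_cond2)) - float(np.mean(ct_D_cond1))
    nd_delta = float(np.mean(ct_ND_cond2)) - float(np.mean(ct_ND_cond1))
    return eff_D**d_delta / eff_ND**nd_delta


def permutation_test(
    ct_D_cond1: Sequence[float],
    ct_D_cond2: Sequence[float],
    ct_ND_cond1: Sequence[float],
    ct_ND_cond2: Sequence[float],
    eff_D: float,
    eff_ND: float,
    n_perm: int = 2000,
    seed: int = 0,
) -> RatioResult:
    """Two-sided permutation test of the methylation ratio against 1.

    Condition labels are reallocated uniformly at random within each primer
    class; the null statistic is |log ratio| of each reallocation and the
    add-one estimator p = (1 + #{null >= observed}) / (n_perm + 1) avoids
    p = 0.
    """
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    groups = [ct_D_cond1, ct_D_cond2, ct_ND_cond1, ct_ND_cond2]
    if any(len(g) < 2 for g in groups):
        raise ConfigurationError(
            "need >= 2 observations per condition per primer class"
        )
    observed = methylation_ratio(*groups, eff_D=eff_D, eff_ND=eff_ND)
    stat_obs = abs(math.log(observed))

    d_pool = np.concatenate([np.asarray(ct_D_cond1, float), np.asarray(ct_D_cond2, float)])
    nd_pool = np.concatenate([np.asarray(ct_ND_cond1, float), np.asarray(ct_ND_cond2, float)])
    n_d1, n_nd1 = len(ct_D_cond1), len(ct_ND_cond1)
    log_eff_d, log_eff_nd = math.log(eff_D), math.log(eff_ND)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        dp = d_pool[rng.permutation(len(d_pool))]
        ndp = nd_pool[rng.permutation(len(nd_pool))]
        d_delta = dp[n_d1:].mean() - dp[:n_d1].mean()
        nd_delta = ndp[n_nd1:].mean() - ndp[:n_nd1].mean()
        stat = abs(d_delta * log_eff_d - nd_delta * log_eff_nd)
        if stat >= stat_obs - 1e-12:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return RatioResult(ratio=observed, p_value=p, n_permutations=n_perm, seed=seed)
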