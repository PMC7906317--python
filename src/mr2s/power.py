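"""Binary-outcome MR power and log-SD ↔ absolute-concentration conversion.

Power follows the summary-data non-centrality approximation for a case-control
outcome: with N total subjects, case fraction K, instrument variance explained
R², and a detectable odds ratio OR, the IVW test statistic is approximately
normal with non-centrality λ = |ln OR|·√(N·R²·K(1−K)), giving

    power = Φ(λ − z_{1−α/2}).

The symmetric lower rejection tail is ignored; at OR = 1 this evaluates to α/2.

Because the exposure is analyzed as a standardized natural-log concentration,
a 1 SD shift corresponds to different absolute changes at different baseline
levels: Δ = baseline·(e^σ − 1), with σ the SD of the log concentration.  σ can
be calibrated from one published (baseline, Δ) anchor pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of the binary-outcome power formula."""

    n_total: float
    case_fraction: float
    r2: float
    odds_ratio: float
    alpha: float = 0.05

    def __post_init__(self):
        if not self.n_total > 0:
            raise ValueError("n_total must be positive")
        if not 0.0 < self.case_fraction < 1.0:
            raise ValueError("case_fraction must lie in (0, 1)")
        if not 0.0 < self.r2 < 1.0:
            raise ValueError("r2 must lie in (0, 1)")
        if not self.odds_ratio > 0:
            raise ValueError("odds_ratio must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class LogScaleCalibration:
    """SD of the natural-log exposure plus a reference baseline level (nmol/l)."""

    sigma_log: float
    baseline: float

    def __post_init__(self):
        if not self.sigma_log > 0:
            raise ValueError("sigma_log must be positive")
        if not self.baseline > 0:
            raise ValueError("baseline must be positive")


def mr_power_binary(spec: PowerSpec) -> float:
    """Power to detect ``spec.odds_ratio`` at two-sided level ``spec.alpha``."""
    k = spec.case_fraction
    lam = abs(math.log(spec.odds_ratio)) * math.sqrt(
        spec.n_total * spec.r2 * k * (1.0 - k)
    )
    return float(stats.norm.cdf(lam - stats.norm.ppf(1.0 - spec.alpha / 2.0)))


def calibrate_sigma(baseline: float, delta: float) -> float:
    """Log-scale SD implied by a 1 SD change of ``delta`` at ``baseline`` (nmol/l).

    σ = ln(1 + Δ/baseline).  Inverse of :func:`sd_to_absolute_change`.
    """
    if not baseline > 0:
        raise ValueError("baseline must be positive")
    if not delta > -baseline:
        raise ValueError("delta must exceed -baseline (log of nonpositive value)")
    return math.log1p(delta / baseline)


def sd_to_absolute_change(baseline: float, sigma_log: float) -> float:
    """Absolute change (nmol/l) at ``baseline`` for a 1 SD shift of the log exposure.

    Δ = baseline·(e^σ − 1); strictly proportional to the baseline at fixed σ.
    """
    if not baseline > 0:
        raise ValueError("baseline must be positive")
    return baseline * math.expm1(sigma_log)
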