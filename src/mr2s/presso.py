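"""MR-PRESSO: simulation-based detection and correction of pleiotropic outliers.

The framework regresses each instrument's outcome effect on its exposure effect
through the leave-one-out IVW slope and asks whether the observed residual sum
of squares (RSS) is larger than expected under a no-pleiotropy parametric null:

* global test — Monte-Carlo p-value for the total RSS;
* outlier test — per-instrument Monte-Carlo p for each squared residual,
  Bonferroni-adjusted; flagged instruments are removed and the IVW estimate
  recomputed;
* distortion test — percent change of the causal estimate after outlier
  removal, referenced against removal of random same-size instrument subsets.

All Monte-Carlo p-values carry a plus-one correction, so they are never zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import AllOutliersError, InsufficientInstrumentsError
from .estimators import MREstimate, ivw, wald_ratios
from .instruments import InstrumentSet


@dataclass(frozen=True)
class PressoResult:
    """Global, outlier and distortion test output of one MR-PRESSO run."""

    rss_observed: float
    global_p: float
    per_variant_p: Mapping[str, float]
    per_variant_p_bonferroni: Mapping[str, float]
    outliers: frozenset[str]
    theta_all: Optional[MREstimate] = None
    theta_outlier_removed: Optional[MREstimate] = None
    distortion_coefficient: Optional[float] = None
    distortion_p: Optional[float] = None
    n_sim: int = 0
    seed: Optional[int] = None


def _arrays(instruments: InstrumentSet):
    bx = np.array([i.beta_exposure for i in instruments.instruments])
    by = np.array([i.beta_outcome for i in instruments.instruments])
    sx = np.array([i.se_exposure for i in instruments.instruments])
    sy = np.array([i.se_outcome for i in instruments.instruments])
    return bx, by, sx, sy


def _loo_ivw(bx, by, sy):
    """Leave-one-out fixed-effects IVW slope for every instrument, vectorized.

    Works row-wise on 2-D inputs (replicates x instruments).
    """
    t = by / bx
    w = (bx / sy) ** 2
    sw = w.sum(axis=-1, keepdims=True)
    swt = (w * t).sum(axis=-1, keepdims=True)
    return (swt - w * t) / (sw - w)


def _residuals_observed(instruments: InstrumentSet):
    bx, by, sx, sy = _arrays(instruments)
    theta_loo = _loo_ivw(bx, by, sy)
    resid2 = (by - theta_loo * bx) ** 2
    return bx, by, sx, sy, theta_loo, resid2


def _simulate_rss(bx, sx, sy, theta_loo, n_sim, rng):
    """Simulated squared residuals under the per-instrument no-pleiotropy null.

    Each replicate redraws both effect vectors (β*_X from the observed exposure
    effects, β*_Y from the leave-one-out fitted line) and recomputes its own
    leave-one-out residuals, mirroring the observed statistic exactly.
    """
    j = bx.size
    bx_star = rng.normal(bx, sx, size=(n_sim, j))
    by_star = rng.normal(theta_loo * bx, sy, size=(n_sim, j))
    theta_loo_star = _loo_ivw(bx_star, by_star, sy)
    resid2_star = (by_star - theta_loo_star * bx_star) ** 2
    return resid2_star


def _check(instruments: InstrumentSet, n_sim: int):
    if len(instruments) < 4:
        raise InsufficientInstrumentsError(
            f"MR-PRESSO needs at least 4 instruments, got {len(instruments)}"
        )
    if n_sim < 1000:
        raise ValueError("n_sim must be at least 1000 for a usable Monte-Carlo p")


def presso_global(
    instruments: InstrumentSet, n_sim: int = 10_000, seed: Optional[int] = None
) -> PressoResult:
    """Global pleiotropy test: Monte-Carlo tail probability of the observed RSS."""
    _check(instruments, n_sim)
    rng = np.random.default_rng(seed)
    bx, by, sx, sy, theta_loo, resid2 = _residuals_observed(instruments)
    rss_obs = float(resid2.sum())
    resid2_star = _simulate_rss(bx, sx, sy, theta_loo, n_sim, rng)
    rss_star = resid2_star.sum(axis=1)
    global_p = (1 + int(np.sum(rss_star >= rss_obs))) / (n_sim + 1)
    return PressoResult(
        rss_observed=rss_obs,
        global_p=global_p,
        per_variant_p={},
        per_variant_p_bonferroni={},
        outliers=frozenset(),
        n_sim=n_sim,
        seed=seed,
    )


def presso_outliers(
    instruments: InstrumentSet,
    n_sim: int = 10_000,
    alpha: float = 0.05,
    seed: Optional[int] = None,
) -> PressoResult:
    """Outlier test: flag instruments whose squared residual is extreme under
    the simulated null (Bonferroni-adjusted p < alpha) and recompute IVW without
    them."""
    _check(instruments, n_sim)
    rng = np.random.default_rng(seed)
    bx, by, sx, sy, theta_loo, resid2 = _residuals_observed(instruments)
    rss_obs = float(resid2.sum())
    resid2_star = _simulate_rss(bx, sx, sy, theta_loo, n_sim, rng)
    rss_star = resid2_star.sum(axis=1)
    global_p = (1 + int(np.sum(rss_star >= rss_obs))) / (n_sim + 1)

    j = len(instruments)
    ids = [i.variant_id for i in instruments.instruments]
    p_raw = (1 + np.sum(resid2_star >= resid2[None, :], axis=0)) / (n_sim + 1)
    p_adj = np.minimum(1.0, p_raw * j)
    outliers = frozenset(v for v, p in zip(ids, p_adj) if p < alpha)

    theta_all = ivw(wald_ratios(instruments), model="random")
    if len(outliers) == j:
        raise AllOutliersError("every instrument flagged as an outlier")
    theta_removed = None
    if outliers:
        kept = instruments.excluding(outliers, label=f"{instruments.label} (outliers removed)")
        theta_removed = ivw(wald_ratios(kept), model="random")
    return PressoResult(
        rss_observed=rss_obs,
        global_p=global_p,
        per_variant_p=dict(zip(ids, p_raw.tolist())),
        per_variant_p_bonferroni=dict(zip(ids, p_adj.tolist())),
        outliers=outliers,
        theta_all=theta_all,
        theta_outlier_removed=theta_removed,
        n_sim=n_sim,
        seed=seed,
    )


def presso_distortion(
    before: MREstimate,
    after: MREstimate,
    instruments: InstrumentSet,
    outliers: Sequence[str],
    n_sim: int = 10_000,
    seed: Optional[int] = None,
) -> tuple[Optional[float], float]:
    """Distortion test: is the estimate shift after outlier removal larger than
    removing random subsets of the same size would produce?

    Returns ``(coefficient, p)`` where coefficient = 100·(θ_after − θ_before)/|θ_before|
    in percent.  If θ_before is exactly zero the coefficient is undefined
    (returned as None) and the p-value is computed on the absolute difference.
    """
    outliers = list(outliers)
    if not outliers:
        raise ValueError("distortion test requires a nonempty outlier set")
    k = len(outliers)
    ids = [i.variant_id for i in instruments.instruments]
    if k >= len(ids):
        raise AllOutliersError("cannot remove every instrument")
    rng = np.random.default_rng(seed)
    bx, by, sx, sy = _arrays(instruments)
    w = (bx / sy) ** 2
    t = by / bx

    null_thetas = np.empty(n_sim)
    for s in range(n_sim):
        drop = rng.choice(len(ids), size=k, replace=False)
        keep = np.ones(len(ids), dtype=bool)
        keep[drop] = False
        null_thetas[s] = np.sum(w[keep] * t[keep]) / np.sum(w[keep])

    if before.theta == 0.0:
        obs = abs(after.theta - before.theta)
        null = np.abs(null_thetas - before.theta)
        p = (1 + int(np.sum(null >= obs))) / (n_sim + 1)
        return None, p
    coef = 100.0 * (after.theta - before.theta) / abs(before.theta)
    null_coef = 100.0 * (null_thetas - before.theta) / abs(before.theta)
    p = (1 + int(np.sum(np.abs(null_coef) >= abs(coef)))) / (n_sim + 1)
    return float(coef), p


def run_presso(
    instruments: InstrumentSet,
    n_sim: int = 10_000,
    alpha: float = 0.05,
    seed: Optional[int] = None,
) -> PressoResult:
    """Global + outlier + (if outliers found) distortion tests in one pass."""
    res = presso_outliers(instruments, n_sim=n_sim, alpha=alpha, seed=seed)
    if not res.outliers:
        return res
    coef, p = presso_distortion(
        res.theta_all,
        res.theta_outlier_removed,
        instruments,
        sorted(res.outliers),
        n_sim=n_sim,
        seed=None if seed is None else seed + 1,
    )
    return PressoResult(
        rss_observed=res.rss_observed,
        global_p=res.global_p,
        per_variant_p=res.per_variant_p,
        per_variant_p_bonferroni=res.per_variant_p_bonferroni,
        outliers=res.outliers,
        theta_all=res.theta_all,
        theta_outlier_removed=res.theta_outlier_removed,
        distortion_coefficient=coef,
        distortion_p=p,
        n_sim=n_sim,
        seed=seed,
    )
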