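"""Synthetic two-sample GWAS summary statistics with known ground truth.

Summary statistics are simulated directly — no individual-level genotypes —
because two-sample MR consumes only per-variant effects and SEs, and the
summary-level model keeps the generator exact and fast:

* effect-allele frequencies f_j ~ Uniform(eaf_range);
* true exposure effects drawn positive and rescaled so that Σ 2β²f(1−f)
  equals ``r2_target`` exactly (the instruments jointly explain a fixed share
  of a unit-variance standardized exposure);
* exposure SEs follow the standardized-trait formula 1/√(2f(1−f)·n);
* the outcome is a case-control log-odds scale; its SEs use the effective
  sample size n_cases·n_controls/n_total;
* true outcome effects are θ·β_X + α with the per-variant pleiotropic effect
  α from a configurable model (none / balanced / directional / InSIDE-violating);
* observed effects add independent Normal(0, se²) noise, and a random subset of
  variants has its allele coding flipped in both studies (a flip negates both
  betas and reflects the frequency — estimators must be invariant to it).

Defaults mirror the scale of a large European 25OHD GWAS (n≈443,734, 69
independent common instruments explaining 3.1% of variance) feeding a type 1
diabetes case-control GWAS (9,358 cases / 15,705 controls).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import ConfigurationError
from .instruments import InstrumentSet, TraitAnnotation
from .sumstats import HarmonizedInstrument, VariantAssociation

_P_FLOOR = 1e-300  # two-sided p underflows for |z| > ~37; keep p in (0, 1]


@dataclass(frozen=True)
class Pleiotropy:
    """Per-variant direct (pleiotropic) outcome-effect model.

    kinds
    -----
    ``none``
        α_j = 0 — the exclusion restriction holds.
    ``balanced``
        α_j ~ N(0, σ²) — pleiotropy averages out; IVW stays unbiased but Q grows.
    ``directional``
        α_j ~ N(μ, σ²), independent of instrument strength (InSIDE holds);
        biases IVW by ≈ μ/E[β_X] while the Egger intercept estimates μ.
    ``inside_violating``
        α_j correlated with β_Xj (correlation ρ), breaking InSIDE.
    """

    kind: str = "none"
    mu: float = 0.0
    sigma: float = 0.0
    rho: float = 0.0

    def __post_init__(self):
        if self.kind not in ("none", "balanced", "directional", "inside_violating"):
            raise ValueError(f"unknown pleiotropy kind {self.kind!r}")
        for v in (self.mu, self.sigma, self.rho):
            if not np.isfinite(v):
                raise ValueError("pleiotropy parameters must be finite")
        if self.kind == "inside_violating" and not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [-1, 1]")

    @classmethod
    def none(cls) -> "Pleiotropy":
        return cls("none")

    @classmethod
    def balanced(cls, sigma: float) -> "Pleiotropy":
        return cls("balanced", sigma=sigma)

    @classmethod
    def directional(cls, mu: float, sigma: float) -> "Pleiotropy":
        return cls("directional", mu=mu, sigma=sigma)

    @classmethod
    def inside_violating(cls, rho: float, sigma: float) -> "Pleiotropy":
        return cls("inside_violating", rho=rho, sigma=sigma)


@dataclass(frozen=True)
class SyntheticScenario:
    """Generative parameters of one two-sample GWAS simulation."""

    seed: int
    n_snps: int = 69
    theta: float = 0.0
    r2_target: float = 0.031
    n_exposure: int = 443_734
    n_cases: int = 9_358
    n_controls: int = 15_705
    pleiotropy: Pleiotropy = field(default_factory=Pleiotropy.none)
    eaf_range: tuple[float, float] = (0.05, 0.5)
    coding_flip_fraction: float = 0.3

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_snps < 3:
            raise ValueError("n_snps must be at least 3")
        if not 0.0 < self.r2_target < 1.0:
            raise ValueError("r2_target must lie in (0, 1)")
        lo, hi = self.eaf_range
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("eaf_range must satisfy 0 < lo < hi < 1")
        if not 0.0 <= self.coding_flip_fraction <= 1.0:
            raise ValueError("coding_flip_fraction must lie in [0, 1]")
        # the rescaling step can always hit r2_target unless a single common
        # variant would need beta^2*2f(1-f) > 1 on a unit-variance trait
        if self.r2_target >= 1.0:
            raise ConfigurationError("r2_target unreachable")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth behind one simulated dataset (allele-orientation where
    all exposure effects are positive)."""

    theta: float
    beta_exposure: tuple[float, ...]
    alpha: tuple[float, ...]
    eaf: tuple[float, ...]
    r2_realized: float
    seed: int


@dataclass(frozen=True)
class SimulatedStudy:
    """Simulated exposure and outcome tables plus their generating truth."""

    exposure: tuple[VariantAssociation, ...]
    outcome: tuple[VariantAssociation, ...]
    truth: TruthRecord


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.maximum(p, _P_FLOOR)


def _draw_alpha(pleio: Pleiotropy, beta_x: np.ndarray, rng) -> np.ndarray:
    j = beta_x.size
    if pleio.kind == "none":
        return np.zeros(j)
    if pleio.kind == "balanced":
        return rng.normal(0.0, pleio.sigma, j)
    if pleio.kind == "directional":
        return rng.normal(pleio.mu, pleio.sigma, j)
    # inside_violating: correlate alpha with instrument strength
    z = (beta_x - beta_x.mean()) / beta_x.std()
    eps = rng.normal(0.0, 1.0, j)
    return pleio.mu + pleio.sigma * (pleio.rho * z + np.sqrt(1 - pleio.rho**2) * eps)


def simulate_two_sample(scenario: SyntheticScenario) -> SimulatedStudy:
    """Simulate one exposure table, one outcome table and their truth record.

    Same seed → bit-identical output.
    """
    rng = np.random.default_rng(scenario.seed)
    j = scenario.n_snps
    f = rng.uniform(*scenario.eaf_range, j)

    # draw per-variant variance-explained shares and normalize so the set
    # explains r2_target exactly; bounding the share keeps every instrument
    # genuinely genome-wide significant at the exposure sample size (the
    # per-variant association chi2 is n_exposure times its variance explained)
    shares = rng.uniform(0.5, 2.0, j)
    v = scenario.r2_target * shares / shares.sum()
    beta_x = np.sqrt(v / (2.0 * f * (1.0 - f)))
    r2_realized = float(np.sum(2.0 * beta_x**2 * f * (1.0 - f)))

    alpha = _draw_alpha(scenario.pleiotropy, beta_x, rng)
    beta_y = scenario.theta * beta_x + alpha

    n_total = scenario.n_cases + scenario.n_controls
    n_eff = scenario.n_cases * scenario.n_controls / n_total
    se_x = 1.0 / np.sqrt(2.0 * f * (1.0 - f) * scenario.n_exposure)
    se_y = 1.0 / np.sqrt(2.0 * f * (1.0 - f) * n_eff)

    bx_obs = beta_x + rng.normal(0.0, se_x)
    by_obs = beta_y + rng.normal(0.0, se_y)

    # flip the allele coding of a random subset, identically in both studies
    flip = rng.random(j) < scenario.coding_flip_fraction
    sign = np.where(flip, -1.0, 1.0)
    eaf_coded = np.where(flip, 1.0 - f, f)

    p_x = _two_sided_p(bx_obs, se_x)
    p_y = _two_sided_p(by_obs, se_y)

    exposure = []
    outcome = []
    for i in range(j):
        vid = f"rs{i + 1:06d}"
        ea, oa = ("G", "A") if flip[i] else ("A", "G")
        exposure.append(
            VariantAssociation(
                variant_id=vid,
                effect_allele=ea,
                other_allele=oa,
                eaf=float(eaf_coded[i]),
                beta=float(sign[i] * bx_obs[i]),
                se=float(se_x[i]),
                pvalue=float(p_x[i]),
                n=scenario.n_exposure,
            )
        )
        outcome.append(
            VariantAssociation(
                variant_id=vid,
                effect_allele=ea,
                other_allele=oa,
                eaf=float(eaf_coded[i]),
                beta=float(sign[i] * by_obs[i]),
                se=float(se_y[i]),
                pvalue=float(p_y[i]),
                n=n_total,
            )
        )
    truth = TruthRecord(
        theta=scenario.theta,
        beta_exposure=tuple(beta_x.tolist()),
        alpha=tuple(alpha.tolist()),
        eaf=tuple(f.tolist()),
        r2_realized=r2_realized,
        seed=scenario.seed,
    )
    return SimulatedStudy(tuple(exposure), tuple(outcome), truth)


def simulate_instruments(
    scenario: SyntheticScenario, label: str = "simulated"
) -> tuple[InstrumentSet, TruthRecord]:
    """Simulate and pair the two studies directly into an InstrumentSet.

    Convenience for calibration studies: skips table round-tripping but applies
    the same harmonization identity (both tables share allele coding).
    """
    study = simulate_two_sample(scenario)
    instruments = tuple(
        HarmonizedInstrument(
            variant_id=e.variant_id,
            beta_exposure=e.beta,
            se_exposure=e.se,
            beta_outcome=o.beta,
            se_outcome=o.se,
            eaf=e.eaf,
        )
        for e, o in zip(study.exposure, study.outcome)
    )
    return InstrumentSet(label=label, instruments=instruments), study.truth


def plant_outlier(
    instruments: InstrumentSet, index: int, offset_se: float = 10.0
) -> InstrumentSet:
    """Return a copy with one instrument's outcome effect shifted by
    ``offset_se`` times its outcome SE — a planted pleiotropic outlier."""
    items = list(instruments.instruments)
    tgt = items[index]
    items[index] = HarmonizedInstrument(
        variant_id=tgt.variant_id,
        beta_exposure=tgt.beta_exposure,
        se_exposure=tgt.se_exposure,
        beta_outcome=tgt.beta_outcome + offset_se * tgt.se_outcome,
        se_outcome=tgt.se_outcome,
        eaf=tgt.eaf,
        proxy_of=tgt.proxy_of,
        proxy_r2=tgt.proxy_r2,
    )
    return InstrumentSet(label=instruments.label, instruments=tuple(items))


def simulate_annotations(
    instrument_ids: Sequence[str],
    categories: Sequence[str],
    hit_rate: float,
    seed: int,
    planted: Optional[Mapping[str, Sequence[str]]] = None,
) -> tuple[list[TraitAnnotation], dict[str, frozenset[str]]]:
    """Random phenome-scan annotations with known per-category membership.

    Each (variant, category) pair becomes a significant annotation with
    probability ``hit_rate`` (p drawn well below any Bonferroni threshold);
    significant hits are duplicated under a second study name to exercise
    (variant, trait) de-duplication, and (when ``hit_rate > 0``) each variant
    also gets one non-significant decoy row; a zero hit rate yields an empty
    table.  ``planted`` forces specific category memberships regardless of
    ``hit_rate``.

    Returns the annotation rows and the ground-truth mapping
    category → member variant IDs.
    """
    if not 0.0 <= hit_rate <= 1.0:
        raise ValueError("hit_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    planted = {c: set(v) for c, v in (planted or {}).items()}
    rows: list[TraitAnnotation] = []
    membership: dict[str, set[str]] = {c: set() for c in categories}

    for vid in instrument_ids:
        for cat in categories:
            hit = vid in planted.get(cat, ()) or rng.random() < hit_rate
            if not hit:
                continue
            membership[cat].add(vid)
            trait = f"{cat} trait {rng.integers(1, 4)}"
            p = float(10.0 ** rng.uniform(-30, -8))
            rows.append(TraitAnnotation(vid, trait, cat, p, study="study-A"))
            # same association re-reported by a second GWAS: must count once
            rows.append(TraitAnnotation(vid, trait, cat, p * 3.0, study="study-B"))
        if hit_rate > 0:
            # decoy association far above any plausible threshold
            cat = categories[int(rng.integers(len(categories)))]
            rows.append(
                TraitAnnotation(
                    vid, f"{cat} weak trait", cat, float(rng.uniform(0.05, 1.0)),
                    study="study-A",
                )
            )
    return rows, {c: frozenset(v) for c, v in membership.items()}
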