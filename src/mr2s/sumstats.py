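"""GWAS summary-statistics I/O, allele harmonization, and LD-proxy substitution.

A two-sample Mendelian randomization analysis consumes two per-variant association
tables — one for the exposure, one for the (binary) outcome — and must place both
effect estimates on a shared effect-allele orientation before any causal estimator
can run.  This module owns that plumbing:

* :func:`read_sumstats` / :func:`write_sumstats` — tab-separated tables with a
  header, canonical columns ``variant_id, chrom, pos, effect_allele, other_allele,
  eaf, beta, se, pvalue, n``; arbitrary source headers via a column map.
* :func:`harmonize` — orient one outcome record onto the exposure's effect allele,
  handling allele swaps, strand complements and ambiguous palindromic variants.
* :func:`substitute_proxies` — replace instruments absent from the outcome study
  with precomputed LD proxies (r² above a threshold, 0.7 by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import (
    ConfigurationError,
    IncompatibleAllelesError,
    SumstatsValidationError,
)

CANONICAL_COLUMNS = (
    "variant_id",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
)
OPTIONAL_COLUMNS = ("chrom", "pos")

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC_PAIRS = (frozenset("AT"), frozenset("GC"))


@dataclass(frozen=True)
class VariantAssociation:
    """One GWAS summary record for a biallelic variant.

    ``beta`` is the per-effect-allele association: SD units of the (log) exposure
    for a continuous trait, log-odds for a case-control outcome.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: float
    chrom: Optional[str] = None
    pos: Optional[int] = None

    def __post_init__(self):
        object.__setattr__(self, "effect_allele", self.effect_allele.upper())
        object.__setattr__(self, "other_allele", self.other_allele.upper())
        if self.effect_allele not in _VALID_ALLELES:
            raise ValueError(f"effect_allele {self.effect_allele!r} not in A/C/G/T")
        if self.other_allele not in _VALID_ALLELES:
            raise ValueError(f"other_allele {self.other_allele!r} not in A/C/G/T")
        if self.effect_allele == self.other_allele:
            raise ValueError("effect_allele equals other_allele")
        if not 0.0 <= self.eaf <= 1.0:
            raise ValueError(f"eaf {self.eaf} outside [0, 1]")
        if not self.se > 0:
            raise ValueError(f"se {self.se} not positive")
        if not 0.0 < self.pvalue <= 1.0:
            raise ValueError(f"pvalue {self.pvalue} outside (0, 1]")
        if not self.n > 0:
            raise ValueError(f"n {self.n} not positive")
        if not math.isfinite(self.beta):
            raise ValueError("beta not finite")

    @property
    def maf(self) -> float:
        return min(self.eaf, 1.0 - self.eaf)

    @property
    def is_palindromic(self) -> bool:
        return frozenset((self.effect_allele, self.other_allele)) in _PALINDROMIC_PAIRS

    def flipped(self) -> "VariantAssociation":
        """The same association expressed on the other allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            eaf=1.0 - self.eaf,
            beta=-self.beta,
        )


@dataclass(frozen=True)
class HarmonizedInstrument:
    """Exposure and outcome effects of one instrument on a shared effect allele."""

    variant_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    eaf: float
    proxy_of: Optional[str] = None
    proxy_r2: Optional[float] = None

    def __post_init__(self):
        if not self.se_exposure > 0:
            raise ValueError("se_exposure not positive")
        if not self.se_outcome > 0:
            raise ValueError("se_outcome not positive")
        if (self.proxy_of is None) != (self.proxy_r2 is None):
            raise ValueError("proxy_of and proxy_r2 must be set together")
        if self.proxy_r2 is not None and not 0.0 < self.proxy_r2 <= 1.0:
            raise ValueError("proxy_r2 outside (0, 1]")


@dataclass(frozen=True)
class HarmonizationResult:
    """Outcome of harmonizing one exposure/outcome record pair.

    Either ``instrument`` is set, or ``dropped`` is True with a ``reason``.
    """

    variant_id: str
    instrument: Optional[HarmonizedInstrument]
    dropped: bool
    reason: Optional[str] = None
    allele_swapped: bool = False
    strand_complemented: bool = False


def _coerce_row(row: Mapping, idx: int, problems: list) -> Optional[VariantAssociation]:
    kwargs = {}
    for col in CANONICAL_COLUMNS:
        kwargs[col] = row[col]
    for col in ("eaf", "beta", "se", "pvalue", "n"):
        try:
            kwargs[col] = float(kwargs[col])
        except (TypeError, ValueError):
            problems.append((idx, f"column '{col}': unparsable numeric {kwargs[col]!r}"))
            return None
        if not math.isfinite(kwargs[col]):
            problems.append((idx, f"column '{col}': non-finite value"))
            return None
    kwargs["variant_id"] = str(kwargs["variant_id"])
    kwargs["effect_allele"] = str(kwargs["effect_allele"]).strip()
    kwargs["other_allele"] = str(kwargs["other_allele"]).strip()
    if "chrom" in row and not pd.isna(row["chrom"]):
        kwargs["chrom"] = str(row["chrom"])
    if "pos" in row and not pd.isna(row["pos"]):
        kwargs["pos"] = int(row["pos"])
    try:
        return VariantAssociation(**kwargs)
    except ValueError as exc:
        problems.append((idx, str(exc)))
        return None


def read_sumstats(
    path, column_map: Optional[Mapping[str, str]] = None
) -> list[VariantAssociation]:
    """Read a tab-separated summary-statistics table.

    Parameters
    ----------
    path
        A TSV file with a header row.
    column_map
        Optional mapping from canonical column name to the source header, e.g.
        ``{"variant_id": "SNP", "pvalue": "P"}``.  Unmapped canonical names are
        looked up verbatim.

    Raises
    ------
    ConfigurationError
        if a mandatory column is absent after applying the map.
    SumstatsValidationError
        listing every offending row (1-based, header excluded) if any row fails
        numeric parsing or a field invariant.
    """
    df = pd.read_csv(
        path, sep="\t", dtype={"variant_id": str}, float_precision="round_trip"
    )
    if column_map:
        rename = {src: canon for canon, src in column_map.items()}
        missing_src = [s for s in rename if s not in df.columns]
        if missing_src:
            raise ConfigurationError(
                f"column_map refers to absent source columns: {missing_src}"
            )
        df = df.rename(columns=rename)
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"missing mandatory columns: {missing}")

    problems: list = []
    records: list[VariantAssociation] = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        rec = _coerce_row(row, i, problems)
        if rec is not None:
            records.append(rec)
    if problems:
        raise SumstatsValidationError(problems)
    return records


def to_frame(records: Iterable[VariantAssociation]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "variant_id": r.variant_id,
                "chrom": r.chrom,
                "pos": r.pos,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": r.eaf,
                "beta": r.beta,
                "se": r.se,
                "pvalue": r.pvalue,
                "n": r.n,
            }
        )
    return pd.DataFrame(rows)


def write_sumstats(records: Iterable[VariantAssociation], path) -> None:
    """Write records as a canonical tab-separated table (lossless round-trip)."""
    df = to_frame(records)
    if df["chrom"].isna().all() and df["pos"].isna().all():
        df = df.drop(columns=["chrom", "pos"])
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def harmonize(
    exposure: VariantAssociation,
    outcome: VariantAssociation,
    palindrome_eaf_window: float = 0.08,
    proxy_of: Optional[str] = None,
    proxy_r2: Optional[float] = None,
) -> HarmonizationResult:
    """Orient an outcome record onto the exposure's effect allele.

    Rules, in order:

    1. identical allele labels — copy the outcome effect through;
    2. swapped labels — negate ``beta_outcome`` and reflect its frequency;
    3. labels matching only after strand complement — complement, then rule 1/2;
    4. otherwise the pair is irreconcilable.

    Palindromic variants (A/T, G/C) cannot distinguish a swap from a complement
    by labels alone, so they are retained only when the exposure EAF and the
    (post-orientation) outcome EAF fall on the same side of 0.5 and both lie
    outside ``0.5 ± palindrome_eaf_window``; otherwise they are dropped with
    reason ``"palindromic_ambiguous"``.
    """
    if exposure.variant_id != outcome.variant_id:
        raise ValueError(
            f"variant mismatch: {exposure.variant_id} vs {outcome.variant_id}"
        )
    e_pair = (exposure.effect_allele, exposure.other_allele)
    o_pair = (outcome.effect_allele, outcome.other_allele)
    c_pair = (_COMPLEMENT[o_pair[0]], _COMPLEMENT[o_pair[1]])

    complemented = False
    if o_pair == e_pair:
        swapped = False
    elif o_pair == (e_pair[1], e_pair[0]):
        swapped = True
    elif c_pair == e_pair:
        swapped, complemented = False, True
    elif c_pair == (e_pair[1], e_pair[0]):
        swapped, complemented = True, True
    else:
        raise IncompatibleAllelesError(
            f"{exposure.variant_id}: exposure {e_pair} vs outcome {o_pair} "
            "irreconcilable after strand complement"
        )

    beta_out = -outcome.beta if swapped else outcome.beta
    eaf_out = 1.0 - outcome.eaf if swapped else outcome.eaf

    if exposure.is_palindromic:
        lo, hi = 0.5 - palindrome_eaf_window, 0.5 + palindrome_eaf_window
        same_side = (exposure.eaf - 0.5) * (eaf_out - 0.5) > 0
        both_outside = not (lo <= exposure.eaf <= hi) and not (lo <= eaf_out <= hi)
        if not (same_side and both_outside):
            return HarmonizationResult(
                exposure.variant_id,
                None,
                dropped=True,
                reason="palindromic_ambiguous",
                allele_swapped=swapped,
                strand_complemented=complemented,
            )

    instrument = HarmonizedInstrument(
        variant_id=exposure.variant_id,
        beta_exposure=exposure.beta,
        se_exposure=exposure.se,
        beta_outcome=beta_out,
        se_outcome=outcome.se,
        eaf=exposure.eaf,
        proxy_of=proxy_of,
        proxy_r2=proxy_r2,
    )
    return HarmonizationResult(
        exposure.variant_id,
        instrument,
        dropped=False,
        allele_swapped=swapped,
        strand_complemented=complemented,
    )


def harmonize_pairs(
    exposures: Sequence[VariantAssociation],
    outcomes: Sequence[VariantAssociation],
    palindrome_eaf_window: float = 0.08,
) -> tuple[list[HarmonizedInstrument], list[tuple[str, str]]]:
    """Harmonize every exposure variant found in the outcome table.

    Returns the harmonized instruments (input order preserved) and a list of
    ``(variant_id, reason)`` drops, where reason is ``"absent_in_outcome"``,
    ``"palindromic_ambiguous"`` or ``"incompatible_alleles"``.
    """
    out_index = {o.variant_id: o for o in outcomes}
    instruments: list[HarmonizedInstrument] = []
    drops: list[tuple[str, str]] = []
    for exp in exposures:
        out = out_index.get(exp.variant_id)
        if out is None:
            drops.append((exp.variant_id, "absent_in_outcome"))
            continue
        try:
            res = harmonize(exp, out, palindrome_eaf_window)
        except IncompatibleAllelesError:
            drops.append((exp.variant_id, "incompatible_alleles"))
            continue
        if res.dropped:
            drops.append((exp.variant_id, res.reason))
        else:
            instruments.append(res.instrument)
    return instruments, drops


@dataclass(frozen=True)
class ProxyResolution:
    """Result of LD-proxy substitution for instruments absent from the outcome."""

    resolved: Mapping[str, tuple[str, float]]  # original -> (proxy, r2)
    unresolved: tuple[str, ...]


def substitute_proxies(
    missing: Sequence[str],
    proxy_table: pd.DataFrame,
    r2_min: float,
    outcome: Mapping[str, VariantAssociation],
) -> ProxyResolution:
    """Pick, per missing instrument, the best LD proxy present in the outcome data.

    ``proxy_table`` has columns ``variant, proxy, r2`` (an LD-lookup export).
    Only proxies with ``r2 > r2_min`` qualify.  Among qualifying proxies the
    highest r² wins; ties break on the smaller outcome p-value, then on
    lexicographic proxy ID.  Variants with no qualifying proxy are unresolved —
    a normal outcome, not an error.
    """
    required = {"variant", "proxy", "r2"}
    if not required.issubset(proxy_table.columns):
        raise ConfigurationError(
            f"proxy table must have columns {sorted(required)}, "
            f"got {list(proxy_table.columns)}"
        )
    if len(proxy_table) and not (
        (proxy_table["r2"] > 0) & (proxy_table["r2"] <= 1)
    ).all():
        raise ConfigurationError("proxy table r2 values must lie in (0, 1]")

    resolved: dict[str, tuple[str, float]] = {}
    unresolved: list[str] = []
    for variant in missing:
        cand = proxy_table[
            (proxy_table["variant"] == variant) & (proxy_table["r2"] > r2_min)
        ]
        cand = cand[cand["proxy"].isin(outcome.keys())]
        if cand.empty:
            unresolved.append(variant)
            continue
        best = min(
            cand.itertuples(index=False),
            key=lambda row: (-row.r2, outcome[row.proxy].pvalue, row.proxy),
        )
        resolved[variant] = (best.proxy, float(best.r2))
    return ProxyResolution(resolved=resolved, unresolved=tuple(unresolved))
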