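"""Instrument selection, variance explained, and confounder-screen exclusion sets.

Instruments enter a two-sample MR analysis only if they associate with the
exposure at genome-wide significance (default p < 6.6e-9) and are common
(default MAF >= 0.5%).  The strength of a set is summarized by the total
exposure variance explained, Σ 2β²f(1−f).  Sensitivity analyses exclude
instruments that a phenome-wide screen links to potentially pleiotropic trait
categories at a Bonferroni-corrected threshold α / J.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from .errors import EmptyInstrumentSetError
from .sumstats import HarmonizedInstrument, VariantAssociation

UNCATEGORIZED = "uncategorized"


def default_categories() -> tuple[str, ...]:
    """The 14-name trait-category vocabulary shipped with the package."""
    text = resources.files("mr2s.data").joinpath("trait_categories.yaml").read_text()
    return tuple(yaml.safe_load(text)["categories"])


def variance_explained(beta: float, eaf: float) -> float:
    """Exposure variance explained by one biallelic variant: 2·β²·f·(1−f).

    Symmetric in f ↔ 1−f, hence invariant under allele flips (β, f) → (−β, 1−f).
    """
    if not 0.0 <= eaf <= 1.0:
        raise ValueError(f"eaf {eaf} outside [0, 1]")
    return 2.0 * beta * beta * eaf * (1.0 - eaf)


@dataclass(frozen=True)
class InstrumentSet:
    """A labeled collection of harmonized instruments with its total r²."""

    label: str
    instruments: tuple[HarmonizedInstrument, ...]

    def __post_init__(self):
        object.__setattr__(self, "instruments", tuple(self.instruments))
        ids = [i.variant_id for i in self.instruments]
        if len(ids) != len(set(ids)):
            dupes = sorted({v for v in ids if ids.count(v) > 1})
            raise ValueError(f"duplicate variant IDs in instrument set: {dupes}")

    def __len__(self) -> int:
        return len(self.instruments)

    @property
    def variant_ids(self) -> frozenset[str]:
        return frozenset(i.variant_id for i in self.instruments)

    @property
    def r2_total(self) -> float:
        return sum(
            variance_explained(i.beta_exposure, i.eaf) for i in self.instruments
        )

    def excluding(self, variant_ids: Iterable[str], label: str) -> "InstrumentSet":
        drop = set(variant_ids)
        kept = tuple(i for i in self.instruments if i.variant_id not in drop)
        return InstrumentSet(label=label, instruments=kept)

    def restricted_to(self, variant_ids: Iterable[str], label: str) -> "InstrumentSet":
        keep = set(variant_ids)
        unknown = keep - {i.variant_id for i in self.instruments}
        if unknown:
            raise KeyError(f"unknown variant IDs: {sorted(unknown)}")
        kept = tuple(i for i in self.instruments if i.variant_id in keep)
        return InstrumentSet(label=label, instruments=kept)


@dataclass(frozen=True)
class SelectionReport:
    """Instruments passing the p-value and MAF filters, with per-filter tallies.

    A candidate failing both filters is counted in both tallies.
    """

    selected: tuple[VariantAssociation, ...]
    n_input: int
    n_removed_pvalue: int
    n_removed_maf: int


def select_instruments(
    candidates: Sequence[VariantAssociation],
    p_max: float = 6.6e-9,
    maf_min: float = 0.005,
) -> SelectionReport:
    """Retain candidates with ``pvalue < p_max`` and ``MAF >= maf_min``.

    Raises :class:`EmptyInstrumentSetError` if nothing survives.
    """
    selected = []
    n_p = n_maf = 0
    for c in candidates:
        fail_p = not c.pvalue < p_max
        fail_maf = not c.maf >= maf_min
        n_p += fail_p
        n_maf += fail_maf
        if not (fail_p or fail_maf):
            selected.append(c)
    if not selected:
        raise EmptyInstrumentSetError(
            f"no candidate passed p < {p_max} and MAF >= {maf_min} "
            f"({len(candidates)} candidates)"
        )
    return SelectionReport(
        selected=tuple(selected),
        n_input=len(candidates),
        n_removed_pvalue=n_p,
        n_removed_maf=n_maf,
    )


@dataclass(frozen=True)
class TraitAnnotation:
    """One variant-trait association from a phenome-scan export."""

    variant_id: str
    trait: str
    category: str
    pvalue: float
    study: Optional[str] = None


@dataclass(frozen=True)
class ConfounderScreen:
    """Per-category significant-association counts and variant sets.

    ``threshold`` is the exact Bonferroni quotient ``alpha / n_instruments``
    (no rounding).  Duplicate (variant, trait) pairs — the same association
    reported by several studies — count once.
    """

    threshold: float
    counts: Mapping[str, int]
    variants: Mapping[str, frozenset[str]]
    n_annotations: int
    n_below_threshold: int
    unknown_categories: tuple[str, ...] = ()


def confounder_screen(
    annotations: Sequence[TraitAnnotation],
    n_instruments: int,
    alpha: float = 0.05,
    categories: Optional[Sequence[str]] = None,
) -> ConfounderScreen:
    """Screen instruments for associations with potentially confounding traits.

    Annotations with p-value at or above ``alpha / n_instruments`` are dropped;
    the survivors are de-duplicated on (variant, trait) and tallied per category.
    Categories outside the vocabulary are routed to ``"uncategorized"``.
    """
    if n_instruments <= 0:
        raise ValueError("n_instruments must be positive")
    vocab = tuple(categories) if categories is not None else default_categories()
    threshold = alpha / n_instruments

    unknown: list[str] = []
    pairs: set[tuple[str, str, str]] = set()  # (category, variant, trait)
    kept = 0
    for ann in annotations:
        if not ann.pvalue < threshold:
            continue
        kept += 1
        cat = ann.category
        if cat not in vocab:
            if cat not in unknown:
                unknown.append(cat)
            cat = UNCATEGORIZED
        pairs.add((cat, ann.variant_id, ann.trait))

    counts: dict[str, int] = {c: 0 for c in vocab}
    variants: dict[str, set[str]] = {c: set() for c in vocab}
    counts[UNCATEGORIZED] = 0
    variants[UNCATEGORIZED] = set()
    for cat, vid, _trait in pairs:
        counts[cat] += 1
        variants[cat].add(vid)

    return ConfounderScreen(
        threshold=threshold,
        counts=counts,
        variants={c: frozenset(v) for c, v in variants.items()},
        n_annotations=len(annotations),
        n_below_threshold=kept,
        unknown_categories=tuple(unknown),
    )


def build_exclusion_sets(
    full: InstrumentSet,
    category_sets: Mapping[str, Iterable[str]],
    proxy_ids: Iterable[str] = (),
) -> list[InstrumentSet]:
    """Build one labeled sensitivity instrument set per exclusion.

    ``category_sets`` maps a category name to the variant IDs to drop; a
    nonempty ``proxy_ids`` adds an "excluding proxy SNPs" set.  Each resulting
    set recomputes its own total variance explained.
    """
    full_ids = full.variant_ids
    for name, ids in category_sets.items():
        extra = set(ids) - full_ids
        if extra:
            raise ValueError(
                f"category '{name}' lists variants outside the full set: "
                f"{sorted(extra)}"
            )
    sets: list[InstrumentSet] = []
    proxy_ids = set(proxy_ids)
    if proxy_ids:
        sets.append(full.excluding(proxy_ids, label="excluding proxy SNPs"))
    for name, ids in category_sets.items():
        sets.append(full.excluding(set(ids), label=f"excluding {name} SNPs"))
    return sets
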