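"""End-to-end orchestration: harmonize → select → estimate → diagnose → report.

One declarative YAML config drives the whole analysis; thresholds default to
the headline design (genome-wide significance p < 6.6e-9, MAF ≥ 0.5%, proxy
r² > 0.7, Bonferroni α = 0.05) so a bare config reproduces it.  The output is
a bundle of plain tab-separated tables — a results-table-shaped estimates
report, forest- and scatter-plot data, the MR-PRESSO block, power and unit
conversions — plus a per-variant provenance log and a run manifest.  The same
config and seed produce a byte-identical bundle.
"""

from __future__ import annotations

import hashlib
import zlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, InsufficientInstrumentsError, PipelineError
from .estimators import (
    MREstimate,
    egger,
    ivw,
    mode_based_estimate,
    wald_ratios,
    weighted_median,
)
from .instruments import (
    InstrumentSet,
    TraitAnnotation,
    build_exclusion_sets,
    confounder_screen,
    select_instruments,
)
from .power import PowerSpec, calibrate_sigma, mr_power_binary, sd_to_absolute_change
from .presso import PressoResult, run_presso
from .sumstats import harmonize, read_sumstats, substitute_proxies

_FLOAT_FMT = "%.10g"


@dataclass(frozen=True)
class AnalysisConfig:
    """Declarative description of one full MR analysis."""

    exposure_path: str
    outcome_path: str
    seed: int
    proxy_path: Optional[str] = None
    annotation_path: Optional[str] = None
    exposure_columns: Optional[Mapping[str, str]] = None
    outcome_columns: Optional[Mapping[str, str]] = None

    p_max: float = 6.6e-9
    maf_min: float = 0.005
    r2_min: float = 0.7
    alpha: float = 0.05
    palindrome_eaf_window: float = 0.08

    model: str = "random"
    penalized: bool = False
    n_boot: int = 10_000
    mbe_phi: float = 1.0
    presso_n_sim: int = 10_000

    exclusion_categories: tuple[str, ...] = (
        "serum lipids",
        "blood cell counts",
        "body composition",
        "diabetes",
    )

    power_n_total: float = 25_063
    power_case_fraction: float = 9_358 / 25_063
    power_alpha: float = 0.05
    power_odds_ratios: tuple[float, ...] = (1.23, 1.4)

    sigma_anchor_baseline: float = 70.0
    sigma_anchor_delta: float = 40.9
    conversion_baselines: tuple[float, ...] = (25.0, 50.0, 70.0)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config file {path} is not a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("exclusion_categories", "power_odds_ratios", "conversion_baselines"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def digest(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass(frozen=True)
class ReportBundle:
    """All tables produced by one analysis run."""

    estimates: pd.DataFrame
    forest: pd.DataFrame
    scatter: pd.DataFrame
    presso: Optional[PressoResult]
    presso_table: pd.DataFrame
    power: pd.DataFrame
    conversions: pd.DataFrame
    provenance: pd.DataFrame
    manifest: dict

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in (
            ("estimates.tsv", self.estimates),
            ("forest.tsv", self.forest),
            ("scatter.tsv", self.scatter),
            ("presso.tsv", self.presso_table),
            ("power.tsv", self.power),
            ("conversions.tsv", self.conversions),
        ):
            df.to_csv(outdir / name, sep="\t", index=False, float_format=_FLOAT_FMT)
        self.provenance.to_csv(
            outdir / "provenance.log", sep="\t", index=False
        )
        (outdir / "manifest.yaml").write_text(
            yaml.safe_dump(self.manifest, sort_keys=True)
        )


def _analysis_seed(base_seed: int, instruments: InstrumentSet) -> int:
    """Seed derived from the run seed and the instrument *content*, so two
    analyses over the same variants (e.g. excluding an empty set) are
    bit-identical."""
    key = ",".join(sorted(instruments.variant_ids))
    return (int(base_seed) ^ zlib.crc32(key.encode())) % (2**31 - 1)


def _stage(name):
    """Decorator: re-raise any stage failure tagged with the stage name."""

    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc

        wrapper.__name__ = fn.__name__
        return wrapper

    return deco


@_stage("read")
def _read_inputs(config: AnalysisConfig):
    exposure = read_sumstats(config.exposure_path, config.exposure_columns)
    outcome = read_sumstats(config.outcome_path, config.outcome_columns)
    proxies = None
    if config.proxy_path:
        proxies = pd.read_csv(config.proxy_path, sep="\t")
    annotations = None
    if config.annotation_path:
        adf = pd.read_csv(config.annotation_path, sep="\t")
        required = {"variant_id", "trait", "category", "pvalue"}
        if not required.issubset(adf.columns):
            raise ConfigurationError(
                f"annotation table needs columns {sorted(required)}"
            )
        annotations = [
            TraitAnnotation(
                str(r.variant_id),
                str(r.trait),
                str(r.category),
                float(r.pvalue),
                str(getattr(r, "study", "")) or None,
            )
            for r in adf.itertuples(index=False)
        ]
    return exposure, outcome, proxies, annotations


@dataclass(frozen=True)
class PreparedInstruments:
    full: InstrumentSet
    exclusion_sets: tuple[InstrumentSet, ...]
    proxy_ids: frozenset[str]
    provenance: pd.DataFrame
    screen_counts: Optional[Mapping[str, int]]
    selection: object


@_stage("harmonize")
def _prepare(config: AnalysisConfig) -> PreparedInstruments:
    exposure, outcome, proxies, annotations = _read_inputs(config)
    exp_index = {v.variant_id: v for v in exposure}
    out_index = {v.variant_id: v for v in outcome}

    selection = select_instruments(exposure, config.p_max, config.maf_min)
    selected_ids = {v.variant_id for v in selection.selected}
    prov: list[tuple[str, str, str]] = []  # (variant, status, detail)
    for v in exposure:
        if v.variant_id not in selected_ids:
            reason = "pvalue" if not v.pvalue < config.p_max else "maf"
            prov.append((v.variant_id, "dropped-filter", reason))

    missing = [v.variant_id for v in selection.selected if v.variant_id not in out_index]
    resolved: dict = {}
    unresolved: list[str] = list(missing)
    if missing and proxies is not None:
        res = substitute_proxies(missing, proxies, config.r2_min, out_index)
        # the proxy must also carry an exposure record, or its effects cannot
        # be allele-harmonized with the exposure study
        resolved = {
            orig: pr for orig, pr in res.resolved.items() if pr[0] in exp_index
        }
        unresolved = [m for m in missing if m not in resolved]

    instruments = []
    used_ids: set[str] = set()
    for v in selection.selected:
        vid = v.variant_id
        if vid in out_index:
            result = harmonize(
                v, out_index[vid], config.palindrome_eaf_window
            )
            if result.dropped:
                prov.append((vid, "dropped-harmonization", result.reason))
            else:
                instruments.append(result.instrument)
                used_ids.add(vid)
                prov.append((vid, "used", "direct"))
        elif vid in resolved:
            proxy_id, r2 = resolved[vid]
            if proxy_id in used_ids:
                prov.append(
                    (vid, "unresolved", f"proxy {proxy_id} already an instrument")
                )
                continue
            result = harmonize(
                exp_index[proxy_id],
                out_index[proxy_id],
                config.palindrome_eaf_window,
                proxy_of=vid,
                proxy_r2=r2,
            )
            if result.dropped:
                prov.append((vid, "dropped-harmonization", f"proxy {proxy_id}: {result.reason}"))
            else:
                instruments.append(result.instrument)
                used_ids.add(proxy_id)
                prov.append((vid, "substituted", f"proxy {proxy_id} (r2={r2:g})"))
        else:
            prov.append((vid, "unresolved", "absent in outcome, no qualifying proxy"))

    full = InstrumentSet(label="all SNPs", instruments=tuple(instruments))
    proxy_ids = frozenset(i.variant_id for i in full.instruments if i.proxy_of)

    screen_counts = None
    exclusion_sets: tuple[InstrumentSet, ...] = ()
    category_sets: dict[str, frozenset[str]] = {}
    if annotations is not None:
        screen = confounder_screen(annotations, len(full), config.alpha)
        screen_counts = screen.counts
        for cat in config.exclusion_categories:
            members = screen.variants.get(cat, frozenset()) & full.variant_ids
            category_sets[cat] = members
    if category_sets or proxy_ids:
        exclusion_sets = tuple(
            build_exclusion_sets(full, category_sets, proxy_ids)
        )
        for s in exclusion_sets:
            for vid in sorted(full.variant_ids - s.variant_ids):
                prov.append((vid, "excluded-by-label", s.label))

    provenance = pd.DataFrame(prov, columns=["variant_id", "status", "detail"])
    return PreparedInstruments(
        full=full,
        exclusion_sets=exclusion_sets,
        proxy_ids=proxy_ids,
        provenance=provenance,
        screen_counts=screen_counts,
        selection=selection,
    )


def estimate_all_methods(
    instruments: InstrumentSet,
    seed: int,
    model: str = "random",
    penalized: bool = False,
    n_boot: int = 10_000,
    mbe_phi: float = 1.0,
) -> list[MREstimate]:
    """The four-estimator battery for one instrument set."""
    ratios = wald_ratios(instruments)
    return [
        ivw(ratios, model=model, penalized=penalized),
        weighted_median(instruments, n_boot=n_boot, seed=seed),
        egger(instruments, model=model),
        mode_based_estimate(
            instruments, phi=mbe_phi, weighting="simple", n_boot=n_boot, seed=seed + 1
        ),
    ]


def _estimates_frame(rows: list[tuple[str, InstrumentSet, MREstimate]]) -> pd.DataFrame:
    recs = []
    for label, iset, e in rows:
        recs.append(
            {
                "analysis": label,
                "method": e.method,
                "n_snps": e.n_snps,
                "r2_total": iset.r2_total,
                "odds_ratio": e.or_per_sd_decrease,
                "ci_lower": e.or_ci_low,
                "ci_upper": e.or_ci_high,
                "pvalue": e.pvalue,
                "theta": e.theta,
                "se": e.se,
                "egger_intercept": e.egger_intercept,
                "intercept_pvalue": e.egger_intercept_pvalue,
                "q": e.q,
                "q_pvalue": e.q_pvalue,
                "i2_gx": e.i2_gx,
            }
        )
    return pd.DataFrame(recs)


@_stage("estimate")
def _estimate_sets(config: AnalysisConfig, sets: Sequence[InstrumentSet]):
    rows = []
    for iset in sets:
        seed = _analysis_seed(config.seed, iset)
        for est in estimate_all_methods(
            iset,
            seed=seed,
            model=config.model,
            penalized=config.penalized,
            n_boot=config.n_boot,
            mbe_phi=config.mbe_phi,
        ):
            rows.append((iset.label, iset, est))
    return rows


@_stage("presso")
def _run_presso(config: AnalysisConfig, full: InstrumentSet):
    try:
        return run_presso(
            full,
            n_sim=config.presso_n_sim,
            alpha=config.alpha,
            seed=_analysis_seed(config.seed, full) + 7,
        )
    except InsufficientInstrumentsError:
        return None


def _presso_frame(res: Optional[PressoResult]) -> pd.DataFrame:
    if res is None:
        return pd.DataFrame(
            columns=["record", "variant_id", "value", "flagged"]
        )
    rows = [
        {"record": "global_rss", "variant_id": "", "value": res.rss_observed, "flagged": ""},
        {"record": "global_p", "variant_id": "", "value": res.global_p, "flagged": ""},
    ]
    for vid, p in sorted(res.per_variant_p.items()):
        rows.append(
            {
                "record": "outlier_p",
                "variant_id": vid,
                "value": p,
                "flagged": vid in res.outliers,
            }
        )
    if res.theta_outlier_removed is not None:
        rows.append(
            {
                "record": "theta_outlier_removed",
                "variant_id": "",
                "value": res.theta_outlier_removed.theta,
                "flagged": "",
            }
        )
    if res.distortion_coefficient is not None:
        rows.append(
            {
                "record": "distortion_coefficient_pct",
                "variant_id": "",
                "value": res.distortion_coefficient,
                "flagged": "",
            }
        )
    if res.distortion_p is not None:
        rows.append(
            {"record": "distortion_p", "variant_id": "", "value": res.distortion_p, "flagged": ""}
        )
    return pd.DataFrame(rows)


@_stage("power")
def _power_frame(config: AnalysisConfig, r2: float) -> pd.DataFrame:
    rows = []
    for odds in config.power_odds_ratios:
        spec = PowerSpec(
            n_total=config.power_n_total,
            case_fraction=config.power_case_fraction,
            r2=r2,
            odds_ratio=odds,
            alpha=config.power_alpha,
        )
        rows.append(
            {
                "n_total": spec.n_total,
                "case_fraction": spec.case_fraction,
                "r2": r2,
                "alpha": spec.alpha,
                "odds_ratio": odds,
                "power": mr_power_binary(spec),
            }
        )
    return pd.DataFrame(rows)


@_stage("convert")
def _conversion_frame(config: AnalysisConfig) -> pd.DataFrame:
    sigma = calibrate_sigma(config.sigma_anchor_baseline, config.sigma_anchor_delta)
    rows = [
        {
            "baseline_nmol_l": b,
            "sigma_log": sigma,
            "change_per_sd_nmol_l": sd_to_absolute_change(b, sigma),
        }
        for b in config.conversion_baselines
    ]
    return pd.DataFrame(rows)


def _scatter_frame(full: InstrumentSet, rows) -> pd.DataFrame:
    pts = [
        {
            "record": "variant",
            "variant_id": i.variant_id,
            "beta_exposure": i.beta_exposure,
            "se_exposure": i.se_exposure,
            "beta_outcome": i.beta_outcome,
            "se_outcome": i.se_outcome,
        }
        for i in full.instruments
    ]
    for label, iset, e in rows:
        if label != full.label:
            continue
        pts.append(
            {
                "record": "fit",
                "variant_id": e.method,
                "beta_exposure": 0.0,  # line anchor x=0
                "se_exposure": e.egger_intercept or 0.0,  # intercept (0 unless Egger)
                "beta_outcome": e.theta,  # slope
                "se_outcome": float("nan"),
            }
        )
    return pd.DataFrame(pts)


def _forest_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "analysis": label,
                "method": e.method,
                "n_snps": e.n_snps,
                "odds_ratio": e.or_per_sd_decrease,
                "ci_lower": e.or_ci_low,
                "ci_upper": e.or_ci_high,
            }
            for label, _iset, e in rows
        ]
    )


def _bundle(config: AnalysisConfig, prepared: PreparedInstruments, sets) -> ReportBundle:
    rows = _estimate_sets(config, sets)
    presso = _run_presso(config, sets[0])
    power = _power_frame(config, sets[0].r2_total)
    conversions = _conversion_frame(config)
    manifest = {
        "package_version": __version__,
        "config_sha256": config.digest(),
        "seed": int(config.seed),
        "n_instruments_full": len(sets[0]),
        "r2_total_full": float(sets[0].r2_total),
        "n_proxies": len(prepared.proxy_ids & sets[0].variant_ids),
        "analyses": [s.label for s in sets],
        "screen_counts": dict(prepared.screen_counts or {}),
    }
    return ReportBundle(
        estimates=_estimates_frame(rows),
        forest=_forest_frame(rows),
        scatter=_scatter_frame(sets[0], rows),
        presso=presso,
        presso_table=_presso_frame(presso),
        power=power,
        conversions=conversions,
        provenance=prepared.provenance,
        manifest=manifest,
    )


def run_analysis(config: AnalysisConfig) -> ReportBundle:
    """Run the full analysis: main instrument set plus every exclusion set."""
    prepared = _prepare(config)
    sets = [
        replace(prepared.full, label=f"all SNPs (N = {len(prepared.full)})"),
        *prepared.exclusion_sets,
    ]
    return _bundle(config, prepared, sets)


def run_subset_analysis(
    config: AnalysisConfig, variant_ids: Sequence[str]
) -> ReportBundle:
    """Run the analysis restricted to the listed instruments only.

    Unknown IDs raise a KeyError naming the offenders.  The subset's own total
    variance explained feeds the power calculation.
    """
    prepared = _prepare(config)
    subset = prepared.full.restricted_to(
        variant_ids, label=f"subset (N = {len(set(variant_ids))})"
    )
    pruned = replace(
        prepared,
        exclusion_sets=(),
        provenance=prepared.provenance[
            prepared.provenance["variant_id"].isin(set(variant_ids))
            | (prepared.provenance["status"] != "excluded-by-label")
        ].reset_index(drop=True),
    )
    return _bundle(config, pruned, [subset])
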