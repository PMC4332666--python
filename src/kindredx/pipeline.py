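"""End-to-end combined filter: prefilters, kindred/cross-cohort with shared
segments, clinical rescue, sequential database subtraction, gene scoring and
enrichment — plus the per-stage reduction report.

Stage order: (1) strand and proximity prefilters on every sample; (2) the
affected-kindred/cross-cohort filter — cross-cohort key removal first, then
IBD segment detection on the cleaned calls, the kindred concordance rule,
and the shared-segment filter for pairs; (3) clinical rescue of
cross-cohort rejections; (4) sequential panel subtraction (non-clinical
dbSNP-like, male-only population, EVS-male), skipping rescued keys;
(5) gene scoring and known-gene enrichment.  Cross-cohort removal precedes
segment detection so that batch-systematic artifacts shared by unrelated
samples cannot masquerade as discordant points inside true shared segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calls import NONSYN_OR_SPLICING, SampleCallSet, VariantKey
from .cohort import REJECT, RESCUE, RETAIN, CohortDesign, FilterLedger
from .errors import ConfigurationError
from .ibd import SharedSegment, detect_shared_segments, discordance_track, shared_segment_filter
from .kindred import (
    LowCovTracks,
    clinical_rescue,
    cross_cohort_shared_keys,
    kindred_cross_cohort_filter,
)
from .prefilters import apply_prefilters
from .prioritize import (
    DEFAULT_PAIR_BONUS,
    DEFAULT_WEIGHTS,
    EnrichmentResult,
    GeneScore,
    hypergeometric_enrichment,
    score_genes,
)
from .reference import (
    ReferencePanel,
    build_nonclinical_dbsnp,
    evs_male_subset,
    male_only_subset,
    subtract_panel,
)

STAGE_ORDER = (
    "strand",
    "proximity",
    "kindred-cross-cohort",
    "shared-segment",
    "rescue",
    "dbsnp-nonclinical",
    "population-male",
    "evs-male",
)


@dataclass
class PanelSet:
    """The three reference panels consumed by the subtraction filters."""

    dbsnp: ReferencePanel
    population: ReferencePanel
    evs: ReferencePanel


def derive_panel_set(master: ReferencePanel) -> PanelSet:
    """Split a master site table into the dbSNP-like, population and
    EVS-like panels via its presence flags (falling back to all records)."""
    r = master.records
    if "present_dbsnp" in r:
        dbsnp = master.subset(r["present_dbsnp"])
    elif "allele_count" in r:
        dbsnp = master.subset(r["allele_count"] >= 1)
    else:
        dbsnp = master
    population = master.subset(r["present_population"]) if "present_population" in r else master
    evs = master.subset(r["present_evs"]) if "present_evs" in r else master
    return PanelSet(dbsnp=dbsnp, population=population, evs=evs)


@dataclass
class PipelineConfig:
    proximity_bp: int = 10
    window_bp: int = 5_000_000
    max_discordant_per_window: int = 0
    min_depth: int = 4
    min_allele_count: int = 12
    rescue_maf: float = 0.01
    chrom_length: int = 155_000_000
    par_regions: tuple[tuple[int, int], ...] = ((0, 2_700_000), (154_900_000, 155_000_000))
    weights: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    pair_bonus: float = DEFAULT_PAIR_BONUS
    n_target_genes: int = 975
    permissive_strand: bool = False


@dataclass
class ReductionReport:
    """Per-stage mean ± sd variants per sample, as percent of the
    post-prefilter baseline, split into damaging vs other classes."""

    table: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def pct(self, stage: str) -> float:
        row = self.table[self.table["stage"] == stage]
        return float(row["pct_of_baseline"].iloc[0])


@dataclass
class PipelineResult:
    callsets: dict[str, SampleCallSet]
    ledger: FilterLedger
    report: ReductionReport
    gene_scores: list[GeneScore]
    enrichment: EnrichmentResult | None
    segments: dict[str, list[SharedSegment]]
    rescued: set[VariantKey]
    baseline: dict[str, SampleCallSet]


def _check_inputs(cohort, design, panels, gene_map) -> None:
    if not cohort:
        raise ConfigurationError("empty cohort")
    ids = {cs.sample_id for cs in cohort}
    if ids - set(design.sample_ids):
        raise ConfigurationError("cohort contains samples missing from the design")
    for name in ("dbsnp", "population", "evs"):
        if getattr(panels, name, None) is None:
            raise ConfigurationError(f"missing panel {name!r}")
    if gene_map is None:
        raise ConfigurationError("missing gene map")


def run_combined(
    cohort: Sequence[SampleCallSet],
    design: CohortDesign,
    panels: PanelSet,
    gene_map: Mapping[VariantKey, str],
    known_genes: set[str] | None = None,
    config: PipelineConfig | None = None,
    lowcov_tracks: LowCovTracks | None = None,
) -> PipelineResult:
    """Run the combined filter end to end and score the surviving genes."""
    config = config or PipelineConfig()
    _check_inputs(cohort, design, panels, gene_map)
    ledger = FilterLedger()

    # (1) universal prefilters
    pre: dict[str, SampleCallSet] = {}
    for cs in cohort:
        pre[cs.sample_id] = apply_prefilters(
            cs, window_bp=config.proximity_bp,
            permissive_strand=config.permissive_strand, ledger=ledger,
        )
    baseline = dict(pre)

    # (2) kindred/cross-cohort + shared segments
    kin_out, kin_ledger = kindred_cross_cohort_filter(
        list(pre.values()), design, min_depth=config.min_depth, lowcov_tracks=lowcov_tracks
    )
    ledger.extend(kin_ledger)
    cc_keys = cross_cohort_shared_keys(list(pre.values()), design)
    cc_clean = {
        sid: cs.subset(cs.key_set - cc_keys) for sid, cs in pre.items()
    }
    segments: dict[str, list[SharedSegment]] = {}
    current = dict(kin_out)
    for a, b, _rel in design.pairs:
        track = discordance_track(cc_clean[a], cc_clean[b])
        segs = detect_shared_segments(
            track,
            window_bp=config.window_bp,
            max_discordant_per_window=config.max_discordant_per_window,
            chrom_length=config.chrom_length,
        )
        segments[f"{a}|{b}"] = segs
        # restrict the kindred-stage survivors to segment interiors; kin
        # concordance (or the low-coverage accommodation) is already settled
        for sid in (a, b):
            kept = []
            for call in current[sid]:
                if any(s.contains(call.pos) for s in segs):
                    kept.append(call)
                    ledger.add(sid, call.key, "shared-segment", RETAIN, "-")
                else:
                    ledger.add(sid, call.key, "shared-segment", REJECT, "shared-segment")
            current[sid] = SampleCallSet(
                sid, kept, sex=current[sid].sex, batch=current[sid].batch
            )

    # (3) clinical rescue of cross-cohort rejections
    ledger, rescued = clinical_rescue(ledger, panels.dbsnp, maf_max=config.rescue_maf)
    if rescued:
        for sid, cs in current.items():
            restore = [
                baseline[sid].get(k)
                for k in rescued
                if k in baseline[sid] and k not in cs
            ]
            if restore:
                current[sid] = SampleCallSet(
                    sid, list(cs.calls) + restore, sex=cs.sex, batch=cs.batch
                )

    # (4) sequential database subtraction, rescued keys immune
    dbsnp_filter = build_nonclinical_dbsnp(panels.dbsnp, min_allele_count=config.min_allele_count)
    population_filter = male_only_subset(panels.population)
    evs_filter = evs_male_subset(panels.evs, par_mask=config.par_regions)
    for stage, panel in (
        ("dbsnp-nonclinical", dbsnp_filter),
        ("population-male", population_filter),
        ("evs-male", evs_filter),
    ):
        for sid in current:
            current[sid], entries = subtract_panel(current[sid], panel, stage, rescued=rescued)
            ledger.extend(entries)

    # (5) gene scoring and enrichment
    scores = score_genes(
        current, design, gene_map, weights=config.weights, pair_bonus=config.pair_bonus
    )
    enrichment = None
    if known_genes is not None and scores:
        listed = {s.gene_id for s in scores}
        k = len(listed & known_genes)
        enrichment = hypergeometric_enrichment(
            k=k, n=len(listed), K=len(known_genes), N=config.n_target_genes
        )
    report = report_reduction(ledger, baseline)
    return PipelineResult(
        callsets=current,
        ledger=ledger,
        report=report,
        gene_scores=scores,
        enrichment=enrichment,
        segments=segments,
        rescued=rescued,
        baseline=baseline,
    )


def report_reduction(
    ledger: FilterLedger,
    baseline: Mapping[str, SampleCallSet],
    stages: Sequence[str] = STAGE_ORDER,
) -> ReductionReport:
    """Replay the ledger per sample and tabulate per-stage survivors.

    Percentages are relative to the post-prefilter baseline (the output of
    the strand/proximity stages), following the convention of reporting
    database and kindred filters against cleaned calls.
    """
    post_prefilter_stages = {"strand", "proximity"}
    reject_by_stage: dict[str, dict[str, set]] = {s: {} for s in stages}
    rescue_by_sample: dict[str, set] = {}
    for e in ledger:
        if e.decision == REJECT and e.stage in reject_by_stage:
            reject_by_stage[e.stage].setdefault(e.sample_id, set()).add(e.key)
        elif e.decision == RESCUE:
            rescue_by_sample.setdefault(e.sample_id, set()).add(e.key)
    rows = []
    sample_ids = sorted(baseline)
    func_of = {
        sid: {k: baseline[sid].get(k).func_class for k in baseline[sid].key_set}
        for sid in sample_ids
    }
    current = {sid: set(baseline[sid].key_set) for sid in sample_ids}
    report_stages = [s for s in stages if s not in post_prefilter_stages]
    base_counts = {sid: len(current[sid]) for sid in sample_ids}

    def summarize(stage_name: str) -> None:
        totals, damaging = [], []
        for sid in sample_ids:
            keys = current[sid]
            totals.append(len(keys))
            damaging.append(
                sum(1 for k in keys if func_of[sid].get(k) in NONSYN_OR_SPLICING)
            )
        totals = np.array(totals, dtype=float)
        damaging = np.array(damaging, dtype=float)
        base_mean = float(np.mean([base_counts[sid] for sid in sample_ids]))
        rows.append(
            {
                "stage": stage_name,
                "mean_total": float(totals.mean()),
                "sd_total": float(totals.std(ddof=1)) if len(totals) > 1 else 0.0,
                "mean_damaging": float(damaging.mean()),
                "mean_other": float((totals - damaging).mean()),
                "pct_of_baseline": 100.0 * float(totals.mean()) / base_mean if base_mean else 0.0,
            }
        )

    summarize("baseline")
    for stage in report_stages:
        for sid in sample_ids:
            current[sid] -= reject_by_stage[stage].get(sid, set())
            if stage == "rescue":
                restore = rescue_by_sample.get(sid, set()) & set(func_of[sid])
                current[sid] |= restore
        summarize(stage)
    return ReductionReport(table=pd.DataFrame(rows))


def standalone_filter_reductions(
    pre: Mapping[str, SampleCallSet],
    design: CohortDesign,
    panels: PanelSet,
    config: PipelineConfig | None = None,
) -> dict[str, float]:
    """Percent reduction of each individual filter applied alone on top of
    the prefiltered calls — the single-filter comparison view."""
    config = config or PipelineConfig()
    base_total = sum(len(cs) for cs in pre.values())
    out: dict[str, float] = {}

    # shared-segment only
    total = sum(len(cs) for sid, cs in pre.items() if design.kin_of(sid) is None)
    for a, b, _rel in design.pairs:
        track = discordance_track(pre[a], pre[b])
        segs = detect_shared_segments(
            track, window_bp=config.window_bp,
            max_discordant_per_window=config.max_discordant_per_window,
            chrom_length=config.chrom_length,
        )
        filtered, _ = shared_segment_filter(pre[a], pre[b], segs)
        total += sum(len(cs) for cs in filtered.values())
    out["shared-segment"] = 100.0 * (1 - total / base_total)

    kin_out, _ = kindred_cross_cohort_filter(list(pre.values()), design, min_depth=config.min_depth)
    out["kindred-cross-cohort"] = 100.0 * (1 - sum(len(c) for c in kin_out.values()) / base_total)

    for name, panel in (
        ("dbsnp-nonclinical", build_nonclinical_dbsnp(panels.dbsnp, config.min_allele_count)),
        ("population-male", male_only_subset(panels.population)),
        ("evs-male", evs_male_subset(panels.evs, par_mask=config.par_regions)),
    ):
        total = 0
        for cs in pre.values():
            filtered, _ = subtract_panel(cs, panel, name)
            total += len(filtered)
        out[name] = 100.0 * (1 - total / base_total)
    return out
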