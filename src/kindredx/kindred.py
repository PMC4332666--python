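"""The affected-kindred / cross-cohort filter and the clinical rescue.

Causal mutations for a rare X-linked recessive disorder are expected to be
private to individual families, so a variant key observed in two or more
unrelated affected samples is treated as neutral or artifactual and removed
from every carrier — this also self-neutralizes batch-systematic sequencing
errors.  Within a declared kindred pair the causal variant must be shared,
so a surviving variant absent in the kin is removed unless the kin simply
lacks coverage at the site.  Known-pathogenic, rare variants lost to the
cross-cohort rule (the same mutation arising independently in unrelated
families) are rescued afterwards.
"""

from __future__ import annotations

from bisect import bisect_right
from typing import Mapping, Sequence

from .calls import SampleCallSet, VariantKey
from .cohort import REJECT, RESCUE, RETAIN, CohortDesign, FilterLedger, LedgerEntry
from .errors import ConfigurationError
from .reference import PATHOGENIC, ReferencePanel

STAGE_KINDRED = "kindred-cross-cohort"
STAGE_RESCUE = "rescue"

REASON_CROSS_COHORT = "cross-cohort"
REASON_UNSHARED = "kindred-unshared"
REASON_LOWCOV = "kindred-lowcov-accommodation"

#: Low-coverage tracks: sample_id -> sorted (start, end) 0-based half-open intervals
LowCovTracks = Mapping[str, Sequence[tuple[int, int]]]


def cross_cohort_shared_keys(
    cohort: Sequence[SampleCallSet], design: CohortDesign
) -> set[VariantKey]:
    """Variant keys carried by at least two samples that are not declared kin."""
    carriers: dict[VariantKey, list[str]] = {}
    for cs in cohort:
        for key in cs.key_set:
            carriers.setdefault(key, []).append(cs.sample_id)
    shared: set[VariantKey] = set()
    for key, samples in carriers.items():
        if len(samples) > 2:
            # pairs have exactly two members, so >2 carriers always include
            # an unrelated pair of samples
            shared.add(key)
        elif len(samples) == 2 and not design.are_kin(samples[0], samples[1]):
            shared.add(key)
    return shared


def _in_lowcov(intervals: Sequence[tuple[int, int]], pos: int) -> bool:
    starts = [iv[0] for iv in intervals]
    i = bisect_right(starts, pos - 1) - 1
    return i >= 0 and intervals[i][0] <= pos - 1 < intervals[i][1]


def _kin_depth_ok(
    kin_calls: SampleCallSet,
    pos: int,
    min_depth: int,
    lowcov: Sequence[tuple[int, int]] | None,
) -> bool:
    """True when the kin has confident (>= min_depth) coverage at the site."""
    at_pos = kin_calls.calls_at(pos)
    if at_pos:
        depths = [c.depth for c in at_pos if c.depth is not None]
        if depths:
            return max(depths) >= min_depth
        return True  # a call with unknown depth counts as observed
    if lowcov is not None and _in_lowcov(lowcov, pos):
        return False
    # no depth track: absence of a call is treated as a confident reference call
    return True


def kindred_cross_cohort_filter(
    cohort: Sequence[SampleCallSet],
    design: CohortDesign,
    min_depth: int = 4,
    lowcov_tracks: LowCovTracks | None = None,
) -> tuple[dict[str, SampleCallSet], FilterLedger]:
    """Apply the cross-cohort removal then the kindred concordance rule.

    Order of rules per variant per sample:

    1. keys shared by any two unrelated samples are rejected in *every*
       carrier (including kindred pairs that share the key with an
       unrelated sample);
    2. for a paired sample, a surviving key absent in its kin is rejected
       unless the kin's depth at the site is below ``min_depth``;
    3. surviving keys present in both kin, and all surviving sporadic keys,
       are retained.
    """
    by_id = {cs.sample_id: cs for cs in cohort}
    missing = set(by_id) - set(design.sample_ids)
    if missing:
        raise ConfigurationError(f"samples missing from design: {sorted(missing)}")
    shared_unrelated = cross_cohort_shared_keys(cohort, design)
    ledger = FilterLedger()
    out: dict[str, SampleCallSet] = {}
    for cs in cohort:
        kin_id = design.kin_of(cs.sample_id)
        kin_calls = by_id.get(kin_id) if kin_id is not None else None
        kin_lowcov = (
            lowcov_tracks.get(kin_id) if (lowcov_tracks is not None and kin_id) else None
        )
        kept = []
        for call in cs:
            key = call.key
            if key in shared_unrelated:
                ledger.add(cs.sample_id, key, STAGE_KINDRED, REJECT, REASON_CROSS_COHORT)
                continue
            if kin_calls is not None and key not in kin_calls:
                if _kin_depth_ok(kin_calls, call.pos, min_depth, kin_lowcov):
                    ledger.add(cs.sample_id, key, STAGE_KINDRED, REJECT, REASON_UNSHARED)
                    continue
                kept.append(call)
                ledger.add(cs.sample_id, key, STAGE_KINDRED, RETAIN, REASON_LOWCOV)
                continue
            kept.append(call)
            reason = "kindred-shared" if kin_calls is not None else "sporadic"
            ledger.add(cs.sample_id, key, STAGE_KINDRED, RETAIN, reason)
        out[cs.sample_id] = SampleCallSet(cs.sample_id, kept, sex=cs.sex, batch=cs.batch)
    return out, ledger


def clinical_rescue(
    ledger: FilterLedger,
    clinical_panel: ReferencePanel,
    maf_max: float = 0.01,
) -> tuple[FilterLedger, set[VariantKey]]:
    """Re-introduce cross-cohort-rejected variants that are annotated
    pathogenic with population MAF below ``maf_max``.

    A rescue entry is appended for every (sample, variant) pair originally
    rejected with reason "cross-cohort"; rescued keys are immune to the
    downstream database-subtraction filters.
    """
    r = clinical_panel.records
    for col in ("clin_sig", "maf"):
        if col not in r.columns:
            raise ConfigurationError(f"clinical panel lacks column {col!r}")
    eligible = r[r["clin_sig"].isin(PATHOGENIC) & (r["maf"] < maf_max)]
    eligible_keys = set(
        zip(eligible["chrom"], eligible["pos"].astype(int), eligible["ref"], eligible["alt"])
    )
    rescued: set[VariantKey] = set()
    new_entries: list[LedgerEntry] = []
    for e in ledger:
        if e.decision == REJECT and e.reason == REASON_CROSS_COHORT and e.key in eligible_keys:
            rescued.add(e.key)
            new_entries.append(
                LedgerEntry(
                    e.sample_id, e.chrom, e.pos, e.ref, e.alt,
                    STAGE_RESCUE, RESCUE, "clinical-rescue",
                )
            )
    ledger.extend(new_entries)
    return ledger, rescued
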