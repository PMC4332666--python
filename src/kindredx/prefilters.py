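"""Universal strand-representation and inter-variant proximity prefilters.

False-positive calls are often supported by reads from only one sequencing
strand, or aggregate in tight clusters; a single individual is not expected
to carry more than a couple of true variants per kilobase.  Both filters run
before any other stage, on every sample.
"""

from __future__ import annotations

import numpy as np

from .calls import SampleCallSet
from .cohort import REJECT, RETAIN, FilterLedger, LedgerEntry
from .errors import ConfigurationError

STAGE_STRAND = "strand"
STAGE_PROXIMITY = "proximity"


def strand_filter(
    callset: SampleCallSet, permissive: bool = False
) -> tuple[SampleCallSet, list[LedgerEntry]]:
    """Retain calls with at least one alternate read on each strand.

    Calls lacking strand counts raise a configuration error unless
    ``permissive`` is set, in which case they pass through.
    """
    entries: list[LedgerEntry] = []
    kept = []
    for call in callset:
        if call.alt_fwd is None or call.alt_rev is None:
            if not permissive:
                raise ConfigurationError(
                    f"strand counts missing at {call.chrom}:{call.pos} in "
                    f"{callset.sample_id}; supply ADF/ADR or a sidecar, or set permissive"
                )
            ok = True
        else:
            ok = call.alt_fwd >= 1 and call.alt_rev >= 1
        k = call.key
        if ok:
            kept.append(call)
            entries.append(LedgerEntry(callset.sample_id, *k, STAGE_STRAND, RETAIN, "-"))
        else:
            entries.append(LedgerEntry(callset.sample_id, *k, STAGE_STRAND, REJECT, "strand"))
    out = SampleCallSet(callset.sample_id, kept, sex=callset.sex, batch=callset.batch)
    return out, entries


def proximity_filter(
    callset: SampleCallSet, window_bp: int = 10
) -> tuple[SampleCallSet, list[LedgerEntry]]:
    """Reject every call with another call within ``window_bp`` nucleotides.

    Distances are evaluated once on the original call set ("within" is
    inclusive: distance <= window_bp rejects, and both members of a close
    pair are removed); the rule is not re-applied after removals, so the
    result is order-independent and idempotent.
    """
    entries: list[LedgerEntry] = []
    pos = callset.positions()
    n = pos.size
    reject = np.zeros(n, dtype=bool)
    if n > 1:
        # calls are sorted by position; only neighbours can be within range
        gaps = np.diff(pos)
        close = gaps <= window_bp
        reject[:-1] |= close
        reject[1:] |= close
    kept = []
    for call, bad in zip(callset.calls, reject):
        k = call.key
        if bad:
            entries.append(LedgerEntry(callset.sample_id, *k, STAGE_PROXIMITY, REJECT, "proximity"))
        else:
            kept.append(call)
            entries.append(LedgerEntry(callset.sample_id, *k, STAGE_PROXIMITY, RETAIN, "-"))
    out = SampleCallSet(callset.sample_id, kept, sex=callset.sex, batch=callset.batch)
    return out, entries


def apply_prefilters(
    callset: SampleCallSet,
    window_bp: int = 10,
    permissive_strand: bool = False,
    ledger: FilterLedger | None = None,
) -> SampleCallSet:
    """Strand filter then proximity filter, logging to ``ledger`` if given."""
    after_strand, e1 = strand_filter(callset, permissive=permissive_strand)
    after_prox, e2 = proximity_filter(after_strand, window_bp=window_bp)
    if ledger is not None:
        ledger.extend(e1)
        ledger.extend(e2)
    return after_prox
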