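"""Pairwise discordance tracks, identical-by-descent segment detection, the
shared-segment filter, and linkage-interval boundary checks.

A kindred pair inherits stretches of the X identical by descent from their
common maternal line; inside such a stretch the two call sets agree at every
site (concordant-alternate, A|A) apart from errors, while discordant (A|R)
sites accumulate outside.  Segments are found by locating stretches of at
least one window length whose discordant-point count stays within a
tolerance, then refining each boundary to the midpoint between the outermost
interior point and the nearest exterior discordant point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .calls import SampleCallSet, VariantKey
from .cohort import REJECT, RETAIN, LedgerEntry
from .errors import ConfigurationError

STAGE_SHARED_SEGMENT = "shared-segment"

STATUS_RR = "RR"
STATUS_AA = "AA"
STATUS_AR = "AR"


@dataclass
class DiscordanceTrack:
    """Ordered (position, status) points for one sample pair.

    Status is AA when both samples carry the same alternate allele(s) at the
    position, AR when exactly one does (or the alleles differ), and RR when
    neither does but some other cohort sample varies there.
    """

    pair: tuple[str, str]
    positions: np.ndarray
    statuses: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.statuses = np.asarray(self.statuses, dtype=object)
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("track positions must be strictly increasing")

    def __len__(self) -> int:
        return int(self.positions.size)

    def ar_positions(self) -> np.ndarray:
        return self.positions[self.statuses == STATUS_AR]


@dataclass(frozen=True)
class SharedSegment:
    """A half-open [start, end) interval (0-based) shared IBD by one pair."""

    pair: tuple[str, str]
    start: int
    end: int
    n_AA: int = 0
    n_AR: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty segment [{self.start}, {self.end})")

    def contains(self, pos: int) -> bool:
        """Whether a 1-based position falls inside the segment."""
        return self.start < pos <= self.end

    @property
    def length(self) -> int:
        return self.end - self.start


def discordance_track(
    calls_a: SampleCallSet,
    calls_b: SampleCallSet,
    cohort_positions: Iterable[int] = (),
) -> DiscordanceTrack:
    """Build the allelic-status track for a pair of samples.

    Positions carried in both (same keys) are AA; positions carried by
    exactly one, or with differing alleles, are AR.  ``cohort_positions``
    optionally adds RR points at sites variant elsewhere in the cohort.
    """
    chroms = {c.chrom for c in calls_a} | {c.chrom for c in calls_b}
    if len(chroms) > 1:
        raise ValueError(f"call sets span multiple chromosomes: {sorted(chroms)}")
    keys_at: dict[int, tuple[frozenset, frozenset]] = {}
    a_by_pos: dict[int, set[VariantKey]] = {}
    b_by_pos: dict[int, set[VariantKey]] = {}
    for c in calls_a:
        a_by_pos.setdefault(c.pos, set()).add(c.key)
    for c in calls_b:
        b_by_pos.setdefault(c.pos, set()).add(c.key)
    status: dict[int, str] = {}
    for pos in set(a_by_pos) | set(b_by_pos):
        status[pos] = (
            STATUS_AA if a_by_pos.get(pos, set()) == b_by_pos.get(pos, set()) else STATUS_AR
        )
    for pos in cohort_positions:
        status.setdefault(pos, STATUS_RR)
    positions = np.array(sorted(status), dtype=np.int64)
    statuses = np.array([status[p] for p in positions], dtype=object)
    return DiscordanceTrack(
        pair=(calls_a.sample_id, calls_b.sample_id), positions=positions, statuses=statuses
    )


def detect_shared_segments(
    track: DiscordanceTrack,
    window_bp: int = 5_000_000,
    max_discordant_per_window: int = 0,
    chrom_length: int | None = None,
    step_bp: int | None = None,
) -> list[SharedSegment]:
    """Detect IBD segments as merged window-length stretches within the
    discordance tolerance, with midpoint boundary refinement.

    By default the sliding window is evaluated exactly (event-driven sweep
    over discordant-point gaps — the dense limit of a stepped window); pass
    ``step_bp`` to evaluate window starts on a coarse grid instead.  With
    ``max_discordant_per_window=0`` the merged stretches are exactly the
    maximal AR-free intervals of length >= ``window_bp``.
    """
    if chrom_length is None:
        raise ConfigurationError("chrom_length is required for segment detection")
    d = int(max_discordant_per_window)
    ar = track.ar_positions()
    # sentinels just outside the 1-based position range [1, chrom_length]
    bounds = np.concatenate(([0], ar, [chrom_length + 1]))
    flagged: list[tuple[int, int]] = []  # 1-based closed covered regions
    if step_bp is None:
        for j in range(len(bounds) - d - 1):
            left, right = int(bounds[j]), int(bounds[j + d + 1])
            if right - left - 1 >= window_bp:
                flagged.append((left + 1, right - 1))
    else:
        for start in range(0, max(1, chrom_length - window_bp + 1), step_bp):
            lo, hi = start + 1, start + window_bp  # 1-based closed window
            if np.sum((ar >= lo) & (ar <= hi)) <= d:
                flagged.append((lo, hi))
    merged: list[list[int]] = []
    for lo, hi in flagged:
        if merged and lo <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    pts = track.positions[track.statuses != STATUS_RR]
    sts = track.statuses[track.statuses != STATUS_RR]
    segments: list[SharedSegment] = []
    for lo, hi in merged:
        inside = (pts >= lo) & (pts <= hi)
        if not inside.any():
            continue
        first_pt, last_pt = int(pts[inside][0]), int(pts[inside][-1])
        left_ar = ar[ar < lo]
        right_ar = ar[ar > hi]
        start = (int(left_ar[-1]) + first_pt) // 2 if left_ar.size else 0
        end = (last_pt + int(right_ar[0])) // 2 if right_ar.size else chrom_length
        if start >= end:
            continue
        sel = (pts > start) & (pts <= end)
        n_aa = int(np.sum(sts[sel] == STATUS_AA))
        n_ar = int(np.sum(sts[sel] == STATUS_AR))
        segments.append(SharedSegment(track.pair, start, end, n_AA=n_aa, n_AR=n_ar))
    return segments


def shared_segment_filter(
    calls_a: SampleCallSet,
    calls_b: SampleCallSet,
    segments: Sequence[SharedSegment],
) -> tuple[dict[str, SampleCallSet], list[LedgerEntry]]:
    """Retain calls that are concordant between the pair and inside a segment.

    Everything else — concordant calls outside all segments, and the rare
    discordant call inside one (residual error or de novo) — is rejected.
    """
    shared_keys = calls_a.key_set & calls_b.key_set
    entries: list[LedgerEntry] = []
    out: dict[str, SampleCallSet] = {}
    for cs in (calls_a, calls_b):
        kept = []
        for call in cs:
            ok = call.key in shared_keys and any(s.contains(call.pos) for s in segments)
            if ok:
                kept.append(call)
                entries.append(
                    LedgerEntry(cs.sample_id, *call.key, STAGE_SHARED_SEGMENT, RETAIN, "-")
                )
            else:
                entries.append(
                    LedgerEntry(
                        cs.sample_id, *call.key, STAGE_SHARED_SEGMENT, REJECT, "shared-segment"
                    )
                )
        out[cs.sample_id] = SampleCallSet(cs.sample_id, kept, sex=cs.sex, batch=cs.batch)
    return out, entries


def check_linkage_crossings(
    segments: Sequence[SharedSegment],
    linked_intervals: Sequence[tuple[int, int]],
) -> tuple[int, list[tuple[int, int]]]:
    """Count linkage intervals that straddle a segment boundary.

    An interval "crosses" when exactly one boundary of some segment lies
    strictly in its interior; intervals fully inside or fully containing a
    segment do not count for that segment.
    """
    offenders = []
    for lo, hi in linked_intervals:
        crossing = False
        for seg in segments:
            n_inside = sum(1 for b in (seg.start, seg.end) if lo < b < hi)
            if n_inside == 1:
                crossing = True
                break
        if crossing:
            offenders.append((lo, hi))
    return len(offenders), offenders


def segments_to_bed(segments: Sequence[SharedSegment], path, chrom: str = "X") -> None:
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"{chrom}\t{s.start}\t{s.end}\t{s.pair[0]}|{s.pair[1]}\t{s.n_AA}\t{s.n_AR}\n")
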