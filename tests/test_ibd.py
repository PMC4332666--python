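"""Discordance tracks, IBD segment detection, and segment-based filtering."""

import numpy as np
import pytest

from kindredx import (
    DiscordanceTrack,
    check_linkage_crossings,
    detect_shared_segments,
    discordance_track,
    shared_segment_filter,
)
from kindredx.errors import ConfigurationError
from kindredx.ibd import STATUS_AA, STATUS_AR, SharedSegment

from conftest import make_callset

CHROM_LEN = 50_000_000


def make_track(aa_positions, ar_positions):
    pts = sorted(set(aa_positions) | set(ar_positions))
    statuses = [STATUS_AR if p in set(ar_positions) else STATUS_AA for p in pts]
    return DiscordanceTrack(("a", "b"), np.array(pts), np.array(statuses, dtype=object))


def oracle_ar_free_intervals(ar_positions, window, chrom_length):
    """Brute force: maximal intervals free of AR points with length >= window.

    Returns the gaps between consecutive AR points (and the chromosome
    ends), as (exclusive-left-AR, exclusive-right-AR) reference stretches.
    """
    bounds = [0] + sorted(ar_positions) + [chrom_length + 1]
    out = []
    for left, right in zip(bounds, bounds[1:]):
        if right - left - 1 >= window:
            out.append((left, right))
    return out


class TestDiscordanceTrack:
    def test_identical_all_aa(self):
        t = discordance_track(make_callset("a", [100, 200]), make_callset("b", [100, 200]))
        assert list(t.statuses) == [STATUS_AA, STATUS_AA]

    def test_disjoint_all_ar(self):
        t = discordance_track(make_callset("a", [100]), make_callset("b", [300]))
        assert list(t.statuses) == [STATUS_AR, STATUS_AR]

    def test_set_algebra(self):
        t = discordance_track(make_callset("a", [100, 200]), make_callset("b", [200, 300]))
        assert dict(zip(t.positions.tolist(), t.statuses)) == {
            100: STATUS_AR, 200: STATUS_AA, 300: STATUS_AR,
        }

    def test_allele_mismatch_is_discordant(self):
        t = discordance_track(
            make_callset("a", [100], alt="G"), make_callset("b", [100], alt="T")
        )
        assert list(t.statuses) == [STATUS_AR]

    def test_rr_points_from_cohort_sites(self):
        t = discordance_track(
            make_callset("a", [100]), make_callset("b", [100]), cohort_positions=[500]
        )
        assert dict(zip(t.positions.tolist(), t.statuses))[500] == "RR"


class TestDetectSegments:
    def test_requires_chrom_length(self):
        with pytest.raises(ConfigurationError):
            detect_shared_segments(make_track([100], []))

    def test_no_discordance_whole_chromosome(self):
        segs = detect_shared_segments(
            make_track([1_000_000, 2_000_000], []), chrom_length=CHROM_LEN
        )
        assert len(segs) == 1
        assert (segs[0].start, segs[0].end) == (0, CHROM_LEN)

    def test_saturated_discordance_no_segments(self):
        ar = list(range(100_000, CHROM_LEN, 100_000))
        segs = detect_shared_segments(make_track([], ar), chrom_length=CHROM_LEN)
        assert segs == []

    def test_planted_segment_recovered(self, rng):
        """One AR-free stretch among dense flanking discordance is found
        with boundaries within one inter-marker gap of the truth."""
        lo, hi = 20_000_000, 40_000_000
        gap = 100_000
        ar = [p for p in range(gap, CHROM_LEN, gap) if not lo < p <= hi]
        aa = list(range(lo + gap, hi, gap))
        segs = detect_shared_segments(make_track(aa, ar), chrom_length=CHROM_LEN)
        assert len(segs) == 1
        seg = segs[0]
        assert abs(seg.start - lo) <= gap
        assert abs(seg.end - hi) <= gap
        assert seg.n_AR == 0
        assert seg.n_AA == len(aa)

    def test_matches_brute_force_oracle_on_random_tracks(self, rng):
        """Detected segments with zero tolerance correspond one-to-one to
        the brute-force maximal AR-free intervals, each refined boundary
        lying inside its oracle gap."""
        window = 1_000_000
        length = 20_000_000
        for _ in range(30):
            n_ar = int(rng.integers(0, 40))
            n_aa = int(rng.integers(1, 40))
            ar = set(map(int, rng.integers(1, length, size=n_ar)))
            aa = set(map(int, rng.integers(1, length, size=n_aa))) - ar
            if not aa:
                continue
            track = make_track(sorted(aa), sorted(ar))
            segs = detect_shared_segments(
                track, window_bp=window, chrom_length=length
            )
            oracle = [
                (left, right)
                for left, right in oracle_ar_free_intervals(ar, window, length)
                if any(left < p < right for p in aa | ar)
            ]
            assert len(segs) == len(oracle)
            for seg, (left, right) in zip(segs, oracle):
                assert left <= seg.start < seg.end <= (right - 1 if right <= length else length)
                assert seg.n_AR == 0

    def test_monotone_in_tolerance(self, rng):
        length = 20_000_000
        ar = sorted(set(map(int, rng.integers(1, length, size=25))))
        aa = sorted(set(map(int, rng.integers(1, length, size=25))))
        track = make_track([p for p in aa if p not in set(ar)], ar)
        prev = -1
        for d in range(0, 4):
            segs = detect_shared_segments(
                track, window_bp=1_000_000, max_discordant_per_window=d, chrom_length=length
            )
            cover = sum(s.length for s in segs)
            assert cover >= prev
            prev = cover

    def test_grid_mode_subset_of_exact(self):
        track = make_track([5_000_000, 9_000_000], [2_000_000, 12_000_000])
        exact = detect_shared_segments(track, chrom_length=CHROM_LEN)
        grid = detect_shared_segments(track, chrom_length=CHROM_LEN, step_bp=1_000_000)
        cover_exact = sum(s.length for s in exact)
        cover_grid = sum(s.length for s in grid)
        assert cover_grid <= cover_exact


class TestSharedSegmentFilter:
    def test_rules(self):
        seg = [SharedSegment(("a", "b"), 0, 1_000_000)]
        a = make_callset("a", [500_000, 900_000, 2_000_000])
        b = make_callset("b", [500_000, 2_000_000])
        out, entries = shared_segment_filter(a, b, seg)
        # concordant inside -> kept in both; concordant outside -> dropped;
        # discordant inside -> dropped
        assert {c.pos for c in out["a"]} == {500_000}
        assert {c.pos for c in out["b"]} == {500_000}
        reasons = {(e.sample_id, e.pos): e.decision for e in entries}
        assert reasons[("a", 900_000)] == "reject"
        assert reasons[("a", 2_000_000)] == "reject"


class TestLinkageCrossings:
    def test_interval_inside_segment_no_crossing(self):
        segs = [SharedSegment(("a", "b"), 1000, 9000)]
        n, _ = check_linkage_crossings(segs, [(2000, 3000)])
        assert n == 0

    def test_interval_straddling_start_crosses(self):
        segs = [SharedSegment(("a", "b"), 1000, 9000)]
        n, offenders = check_linkage_crossings(segs, [(500, 2000)])
        assert n == 1 and offenders == [(500, 2000)]

    def test_interval_containing_whole_segment_no_crossing(self):
        segs = [SharedSegment(("a", "b"), 1000, 2000)]
        n, _ = check_linkage_crossings(segs, [(500, 3000)])
        assert n == 0

    def test_simulated_true_segments_never_cross_linkage_blocks(self, small_sim):
        """Breakpoints are placed at linkage-block boundaries, so true
        segments never end strictly inside a block."""
        _, cohort = small_sim
        for a, b, _rel in cohort.design.pairs:
            family = a[:-1]
            segs = [
                SharedSegment((a, b), lo, hi)
                for lo, hi in cohort.truth.shared_segments[family]
            ]
            n, _ = check_linkage_crossings(segs, cohort.linkage_intervals)
            assert n == 0
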