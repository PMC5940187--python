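"""Interval algebra: overlap semantics, Venn partitioning, windows, distances."""

import numpy as np
import pytest

from gbrkit.intervals import (
    Peak,
    PeakSet,
    overlaps,
    reproducible_peaks,
    summit_window,
    tss_distance,
    venn_partition,
)
from gbrkit.proximity import GeneRecord

from conftest import random_peaks


def brute_overlap_bp(a: Peak, b: Peak) -> int:
    """Independent oracle: count shared bases explicitly."""
    if a.chrom != b.chrom:
        return 0
    return len(set(range(a.start, a.end)) & set(range(b.start, b.end)))


def brute_venn(sets, min_bp=1):
    """Oracle: naive pairwise-merge closure into union regions, then signatures
    from exhaustive overlap checks against every input peak."""
    assert min_bp == 1
    regions = [[p.chrom, p.start, p.end] for s in sets for p in s]
    changed = True
    while changed:
        changed = False
        for i in range(len(regions)):
            for j in range(i + 1, len(regions)):
                a, b = regions[i], regions[j]
                if a[0] == b[0] and min(a[2], b[2]) - max(a[1], b[1]) > 0:
                    regions[i] = [a[0], min(a[1], b[1]), max(a[2], b[2])]
                    del regions[j]
                    changed = True
                    break
            if changed:
                break
    counts = {}
    for chrom, start, end in regions:
        sig = frozenset(
            s.name
            for s in sets
            if any(p.chrom == chrom and min(p.end, end) - max(p.start, start) > 0 for p in s)
        )
        counts[sig] = counts.get(sig, 0) + 1
    return counts


class TestOverlaps:
    def test_one_bp_overlap_at_boundary(self):
        assert overlaps(Peak("chr1", 100, 200), Peak("chr1", 199, 300), 1)

    def test_half_open_adjacency_is_not_overlap(self):
        assert not overlaps(Peak("chr1", 100, 200), Peak("chr1", 200, 300), 1)

    def test_different_chrom_false(self):
        assert not overlaps(Peak("chr1", 100, 200), Peak("chr2", 100, 200), 1)

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(0)
        peaks = random_peaks(rng, 1000, span=2000, max_len=300)
        for a, b in zip(peaks[:500], peaks[500:]):
            min_bp = int(rng.integers(1, 50))
            assert overlaps(a, b, min_bp) == (brute_overlap_bp(a, b) >= min_bp)


class TestVennPartition:
    def test_depletion_only_compartment_arithmetic(self):
        # 2553 control peaks vs 9526 depleted peaks with 2471 shared regions
        a, b = [], []
        pos = 0
        for i in range(2471):  # reciprocally overlapping pairs
            a.append(Peak("chr1", pos, pos + 400, peak_id=f"a{i}"))
            b.append(Peak("chr1", pos + 100, pos + 500, peak_id=f"b{i}"))
            pos += 1000
        for i in range(2553 - 2471):
            a.append(Peak("chr1", pos, pos + 400, peak_id=f"ax{i}"))
            pos += 1000
        for i in range(9526 - 2471):
            b.append(Peak("chr1", pos, pos + 400, peak_id=f"bx{i}"))
            pos += 1000
        vp = venn_partition([PeakSet("ctrl", a), PeakSet("depl", b)])
        assert vp.count("depl") == 7055
        assert vp.count("ctrl", "depl") == 2471
        assert vp.count("ctrl") == 82

    def test_identical_sets_single_intersection_compartment(self):
        peaks = [Peak("chr1", i * 1000, i * 1000 + 500, peak_id=f"p{i}") for i in range(10)]
        vp = venn_partition([PeakSet("A", peaks), PeakSet("B", list(peaks))])
        assert vp.counts == {frozenset({"A", "B"}): 10}

    def test_duplicate_names_rejected(self):
        ps = PeakSet("A", [Peak("chr1", 0, 10)])
        with pytest.raises(ValueError, match="duplicate"):
            venn_partition([ps, PeakSet("A", [Peak("chr1", 50, 60)])])

    def test_empty_set_allowed(self):
        vp = venn_partition([PeakSet("A", [Peak("chr1", 0, 10, peak_id="x")]), PeakSet("B", [])])
        assert vp.count("A") == 1 and vp.count("B") == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_three_sets_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        sets = [
            PeakSet(name, random_peaks(rng, int(rng.integers(1, 50)), span=3000, max_len=200, prefix=name))
            for name in ("A", "B", "C")
        ]
        vp = venn_partition(sets)
        assert {k: v for k, v in vp.counts.items()} == brute_venn(sets)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a = PeakSet("A", random_peaks(rng, 30, prefix="a"))
        b = PeakSet("B", random_peaks(rng, 30, prefix="b"))
        v1, v2 = venn_partition([a, b]), venn_partition([b, a])
        assert v1.counts == v2.counts

    def test_partition_completeness(self):
        rng = np.random.default_rng(4)
        a = PeakSet("A", random_peaks(rng, 40, prefix="a"))
        b = PeakSet("B", random_peaks(rng, 40, prefix="b"))
        vp = venn_partition([a, b])
        oracle = brute_venn([a, b])
        for name in ("A", "B"):
            assert vp.member_total(name) == sum(v for sig, v in oracle.items() if name in sig)


class TestSummitWindow:
    def test_window_arithmetic(self):
        assert summit_window(Peak("chr1", 1000, 1400, 200), 500) == ("chr1", 700, 1700)

    def test_midpoint_fallback(self):
        assert summit_window(Peak("chr1", 1000, 1400, -1), 500) == ("chr1", 700, 1700)

    def test_clipped_at_zero(self):
        assert summit_window(Peak("chr1", 0, 600, 300), 500) == ("chr1", 0, 800)


class TestTssDistance:
    def test_arithmetic_and_identity(self):
        g = GeneRecord("g", "chr1", 15000)
        assert tss_distance(Peak("chr1", 4800, 5200, 200), g) == 10000
        assert tss_distance(Peak("chr1", 14800, 15200, 200), g) == 0

    def test_cross_chromosome_is_infinite(self):
        assert tss_distance(Peak("chr2", 0, 100), GeneRecord("g", "chr1", 50)) == float("inf")

    def test_matches_direct_subtraction(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            start = int(rng.integers(0, 10000))
            length = int(rng.integers(1, 500))
            offset = int(rng.integers(0, length))
            p = Peak("chr1", start, start + length, offset)
            g = GeneRecord("g", "chr1", int(rng.integers(0, 20000)))
            assert tss_distance(p, g) == abs(start + offset - g.tss)


class TestReproduciblePeaks:
    def test_requires_support_in_every_replicate(self):
        r1 = PeakSet("r1", [Peak("chr1", 100, 500, peak_id="a"), Peak("chr1", 2000, 2400, peak_id="b")])
        r2 = PeakSet("r2", [Peak("chr1", 150, 550, peak_id="c")])
        rep = reproducible_peaks([r1, r2])
        assert len(rep) == 1
        assert (rep.peaks[0].start, rep.peaks[0].end) == (100, 550)
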