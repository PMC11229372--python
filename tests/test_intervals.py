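"""Interval model, overlap detection, union logic, and BED/narrowPeak I/O."""

import numpy as np
import pytest

from promcoloc import (
    GenomicInterval,
    ParseError,
    PeakSet,
    ValidationError,
    combination_counts,
    find_overlaps,
    marginal_counts,
    merge_union,
    read_peaks,
    write_bed,
)
from conftest import random_peakset


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def brute_force_overlaps(A, B, min_overlap=1):
    out = []
    for a in A:
        for b in B:
            if a.chrom != b.chrom:
                continue
            ol = min(a.end, b.end) - max(a.start, b.start)
            if ol >= min_overlap:
                out.append((a.name, b.name, ol))
    return sorted(out)


def brute_force_union(sets, min_overlap=1):
    """Union-find over all pairwise overlaps; returns sorted component data."""
    tagged = [(iv, s.label) for s in sets for iv in s]
    parent = list(range(len(tagged)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(tagged)):
        for j in range(i + 1, len(tagged)):
            a, b = tagged[i][0], tagged[j][0]
            if a.chrom == b.chrom and min(a.end, b.end) - max(a.start, b.start) >= min_overlap:
                parent[find(i)] = find(j)

    comps = {}
    for i, (iv, lab) in enumerate(tagged):
        comps.setdefault(find(i), []).append((iv, lab))
    regions = []
    for members in comps.values():
        span = (members[0][0].chrom,
                min(iv.start for iv, _ in members),
                max(iv.end for iv, _ in members))
        regions.append((span, frozenset(lab for _, lab in members),
                        frozenset(iv.name for iv, _ in members)))
    return sorted(regions)


# ---------------------------------------------------------------------------
# Domain-type invariants
# ---------------------------------------------------------------------------

class TestGenomicInterval:
    def test_rejects_degenerate_and_inverted_intervals(self):
        with pytest.raises(ValidationError):
            GenomicInterval("chr1", 100, 100)
        with pytest.raises(ValidationError):
            GenomicInterval("chr1", -1, 10)
        with pytest.raises(ValidationError):
            GenomicInterval("chr1", 50, 40)

    def test_summit_must_lie_inside(self):
        GenomicInterval("chr1", 10, 20, summit=10)
        GenomicInterval("chr1", 10, 20, summit=19)
        with pytest.raises(ValidationError):
            GenomicInterval("chr1", 10, 20, summit=20)

    def test_anchor_prefers_summit_then_midpoint(self):
        iv = GenomicInterval("chr1", 0, 100, summit=7)
        assert iv.anchor("summit") == 7
        assert iv.anchor("midpoint") == 50
        assert GenomicInterval("chr1", 0, 100).anchor("summit") == 50


def test_peakset_rejects_duplicate_names():
    iv = GenomicInterval("chr1", 0, 10, name="p")
    with pytest.raises(ValidationError):
        PeakSet("A", [iv, GenomicInterval("chr1", 20, 30, name="p")])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

class TestReadPeaks:
    def test_bed_field_mapping(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t100\tp1\t5\t+\n")
        ps = read_peaks(p, "bed")
        iv = ps.intervals[0]
        assert (iv.chrom, iv.start, iv.end, iv.name, iv.strand) == ("chr1", 0, 100, "p1", "+")
        assert iv.summit is None

    def test_narrowpeak_summit_offset(self, tmp_path):
        p = tmp_path / "a.narrowPeak"
        p.write_text(
            "chr1\t200\t500\tp1\t100\t.\t4.5\t10.0\t8.0\t50\n"
            "chr1\t600\t800\tp2\t100\t.\t4.5\t10.0\t8.0\t-1\n"
        )
        ps = read_peaks(p, "narrowPeak")
        assert ps.intervals[0].summit == 250
        assert ps.intervals[1].summit is None

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t0\t100\nchr1\tnotanumber\t5\n")
        with pytest.raises(ParseError, match=":2"):
            read_peaks(p, "bed")

    def test_inverted_coordinates_rejected(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t100\t50\tp1\n")
        with pytest.raises(ValidationError):
            read_peaks(p, "bed")

    def test_bed_round_trip(self, tmp_path, rng):
        ps = random_peakset(rng, "A", n=30)
        out = tmp_path / "rt.bed"
        write_bed(ps, out)
        back = read_peaks(out, "bed", label="A")
        assert [(iv.chrom, iv.start, iv.end, iv.name, iv.strand) for iv in ps] == \
               [(iv.chrom, iv.start, iv.end, iv.name, iv.strand) for iv in back]


# ---------------------------------------------------------------------------
# Overlaps
# ---------------------------------------------------------------------------

class TestFindOverlaps:
    def test_half_open_adjacency_is_not_overlap(self):
        A = PeakSet("A", [GenomicInterval("chr1", 0, 100, "a")])
        B = PeakSet("B", [GenomicInterval("chr1", 100, 200, "b")])
        assert find_overlaps(A, B) == []

    def test_single_shared_base(self):
        A = PeakSet("A", [GenomicInterval("chr1", 0, 100, "a")])
        B = PeakSet("B", [GenomicInterval("chr1", 99, 200, "b")])
        [(a, b, ol)] = find_overlaps(A, B)
        assert (a.name, b.name, ol) == ("a", "b", 1)

    def test_min_overlap_must_be_positive(self):
        A = PeakSet("A", [GenomicInterval("chr1", 0, 10, "a")])
        with pytest.raises(ValidationError):
            find_overlaps(A, A, min_overlap=0)

    def test_symmetry(self, rng):
        A = random_peakset(rng, "A", n=40)
        B = random_peakset(rng, "B", n=40)
        ab = {(a.name, b.name, ol) for a, b, ol in find_overlaps(A, B, 5)}
        ba = {(b.name, a.name, ol) for a, b, ol in find_overlaps(B, A, 5)}
        assert ab == ba

    @pytest.mark.parametrize("min_overlap", [1, 10])
    def test_matches_brute_force_on_random_instances(self, rng, min_overlap):
        for _ in range(50):
            A = random_peakset(rng, "A", n=50, chroms=("chr1", "chr2"))
            B = random_peakset(rng, "B", n=50, chroms=("chr1", "chr2"))
            got = sorted((a.name, b.name, ol) for a, b, ol in
                         find_overlaps(A, B, min_overlap))
            assert got == brute_force_overlaps(A, B, min_overlap)


# ---------------------------------------------------------------------------
# Union
# ---------------------------------------------------------------------------

class TestMergeUnion:
    def test_direct_merge(self):
        A = PeakSet("A", [GenomicInterval("chr1", 0, 100, "a")])
        B = PeakSet("B", [GenomicInterval("chr1", 50, 150, "b")])
        m = merge_union([A, B])
        assert len(m) == 1
        assert (m.regions[0].start, m.regions[0].end) == (0, 150)
        assert m.membership[0] == frozenset({"A", "B"})

    def test_transitive_chaining(self):
        A = PeakSet("A", [GenomicInterval("chr1", 0, 100, "a")])
        B = PeakSet("B", [GenomicInterval("chr1", 90, 200, "b")])
        C = PeakSet("C", [GenomicInterval("chr1", 190, 300, "c")])
        m = merge_union([A, B, C])
        assert len(m) == 1
        assert (m.regions[0].start, m.regions[0].end) == (0, 300)
        assert m.membership[0] == frozenset({"A", "B", "C"})

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            merge_union([])

    def test_every_peak_contributes_exactly_once(self, rng):
        sets = [random_peakset(rng, lab, n=60) for lab in "ABC"]
        m = merge_union(sets)
        all_names = sorted(iv.name for s in sets for iv in s)
        assert sorted(n for contrib in m.contributors for n in contrib) == all_names

    def test_base_level_conservation(self, rng):
        """Merged regions cover exactly the union of input bases."""
        sets = [random_peakset(rng, lab, n=30, chrom_length=2000) for lab in "AB"]
        mask_in = np.zeros(3000, bool)
        for s in sets:
            for iv in s:
                mask_in[iv.start:iv.end] = True
        m = merge_union(sets)
        mask_out = np.zeros(3000, bool)
        for r in m.regions:
            assert not mask_out[r.start:r.end].any(), "regions overlap"
            mask_out[r.start:r.end] = True
        assert (mask_in == mask_out).all()

    @pytest.mark.parametrize("min_overlap", [1, 25])
    def test_matches_union_find_oracle(self, rng, min_overlap):
        for _ in range(40):
            sets = [random_peakset(rng, lab, n=40, chroms=("chr1", "chr2"))
                    for lab in "ABC"]
            m = merge_union(sets, min_overlap)
            got = sorted(
                ((r.chrom, r.start, r.end), mem, frozenset(contrib))
                for r, mem, contrib in zip(m.regions, m.membership, m.contributors)
            )
            assert got == brute_force_union(sets, min_overlap)


class TestCombinationCounts:
    def test_chained_merge_counts_single_full_subset(self):
        A = PeakSet("A", [GenomicInterval("chr1", 0, 100, "a")])
        B = PeakSet("B", [GenomicInterval("chr1", 90, 200, "b")])
        C = PeakSet("C", [GenomicInterval("chr1", 190, 300, "c")])
        assert combination_counts(merge_union([A, B, C])) == {frozenset("ABC"): 1}

    def test_disjoint_singletons(self):
        A = PeakSet("A", [GenomicInterval("chr1", 0, 100, "a")])
        B = PeakSet("B", [GenomicInterval("chr1", 500, 600, "b")])
        assert combination_counts(merge_union([A, B])) == {
            frozenset("A"): 1, frozenset("B"): 1,
        }

    def test_peak_units_mode(self):
        A = PeakSet("A", [GenomicInterval("chr1", 0, 100, "a1"),
                          GenomicInterval("chr1", 50, 150, "a2")])
        m = merge_union([A])
        assert combination_counts(m, "regions") == {frozenset("A"): 1}
        assert combination_counts(m, "peaks") == {frozenset("A"): 2}

    def test_counts_reconcile_with_marginals(self, rng):
        sets = [random_peakset(rng, lab, n=50) for lab in "ABC"]
        m = merge_union(sets)
        counts = combination_counts(m)
        assert sum(counts.values()) == len(m)
        marg = marginal_counts(m)
        for lab in "ABC":
            assert marg[lab] == sum(n for mem, n in counts.items() if lab in mem)
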