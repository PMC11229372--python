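"""Genomic-interval data model, overlap computation, and multi-set peak union.

All coordinates are 0-based half-open (BED-native). Formats that use other
conventions (GTF, printed 1-based inclusive spans) are converted on read and
written back out in BED convention.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

STRANDS = {"+", "-", "."}


class ValidationError(ValueError):
    """Input violates a documented precondition or invariant."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` with optional summit.

    The summit, when present, is an absolute coordinate (not an offset) and
    must lie inside the interval.
    """

    chrom: str
    start: int
    end: int
    name: str = ""
    strand: str = "."
    summit: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"interval {self.name!r}: need 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"interval {self.name!r}: bad strand {self.strand!r}")
        if self.summit is not None and not (self.start <= self.summit < self.end):
            raise ValidationError(
                f"interval {self.name!r}: summit {self.summit} outside "
                f"[{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def anchor(self, mode: str = "summit") -> int:
        """Point representative of the interval.

        ``summit`` mode falls back to the midpoint when no summit is stored;
        ``midpoint`` mode always uses the midpoint.
        """
        if mode == "summit" and self.summit is not None:
            return self.summit
        if mode not in ("summit", "midpoint"):
            raise ValidationError(f"unknown anchor mode {mode!r}")
        return self.midpoint

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class PeakSet:
    """A labelled, named collection of peaks (e.g. one protein/antibody/stage)."""

    label: str
    intervals: list[GenomicInterval]
    source_format: str = "memory"

    def __post_init__(self) -> None:
        names = [iv.name for iv in self.intervals]
        dup = [n for n, c in Counter(names).items() if c > 1]
        if dup:
            raise ValidationError(
                f"peak set {self.label!r}: duplicate peak names {dup[:5]}"
            )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def sorted(self) -> "PeakSet":
        ivs = sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        return PeakSet(self.label, ivs, self.source_format)

    def chromosomes(self) -> set[str]:
        return {iv.chrom for iv in self.intervals}


@dataclass
class MergedRegionSet:
    """Non-overlapping union regions with per-region provenance.

    ``membership[i]`` is the set of contributing PeakSet labels for region
    ``i``; ``contributors[i]`` lists the original peak names. With the default
    ``min_overlap=1`` the regions are pairwise non-overlapping; for larger
    minimum overlaps, components are defined by >=min_overlap shared bases and
    their spans may touch.
    """

    regions: list[GenomicInterval]
    membership: list[frozenset[str]]
    contributors: list[list[str]]

    def __len__(self) -> int:
        return len(self.regions)


# ---------------------------------------------------------------------------
# I/O: BED3/BED6 and ENCODE narrowPeak
# ---------------------------------------------------------------------------

def _parse_bed_line(fields: Sequence[str], lineno: int, path: str) -> GenomicInterval:
    try:
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
    except (IndexError, ValueError) as exc:
        raise ParseError(f"{path}:{lineno}: malformed BED line ({exc})") from exc
    name = fields[3] if len(fields) > 3 and fields[3] not in ("", ".") else f"peak_{lineno}"
    strand = fields[5] if len(fields) > 5 and fields[5] in STRANDS else "."
    try:
        return GenomicInterval(chrom, start, end, name=name, strand=strand)
    except ValidationError as exc:
        raise ValidationError(f"{path}:{lineno}: {exc}") from exc


def _parse_narrowpeak_line(fields: Sequence[str], lineno: int, path: str) -> GenomicInterval:
    if len(fields) != 10:
        raise ParseError(
            f"{path}:{lineno}: narrowPeak requires exactly 10 fields, got {len(fields)}"
        )
    try:
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        offset = int(fields[9])
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: malformed narrowPeak line ({exc})") from exc
    name = fields[3] if fields[3] not in ("", ".") else f"peak_{lineno}"
    strand = fields[5] if fields[5] in STRANDS else "."
    summit = start + offset if offset >= 0 else None
    try:
        return GenomicInterval(chrom, start, end, name=name, strand=strand, summit=summit)
    except ValidationError as exc:
        raise ValidationError(f"{path}:{lineno}: {exc}") from exc


def read_peaks(path: str | Path, format: str = "bed", label: Optional[str] = None) -> PeakSet:
    """Read a peak file into a :class:`PeakSet`.

    ``format`` is ``"bed"`` (>=3 columns) or ``"narrowPeak"`` (exactly 10
    columns; column 10 is the point-source offset, converted to an absolute
    summit when >= 0 and dropped when -1). Unnamed peaks get synthetic names
    derived from their line number so that names stay unique within the set.
    """
    path = Path(path)
    fmt = format.lower()
    if fmt not in ("bed", "narrowpeak"):
        raise ValidationError(f"unknown peak format {format!r}")
    parse = _parse_bed_line if fmt == "bed" else _parse_narrowpeak_line
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            intervals.append(parse(line.split("\t"), lineno, str(path)))
    return PeakSet(label or path.stem, intervals, source_format=fmt)


def write_bed(ps: PeakSet | Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED6 (score column 0; summit not representable)."""
    ivs = ps.intervals if isinstance(ps, PeakSet) else list(ps)
    with open(path, "w") as fh:
        for iv in ivs:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# Overlap computation
# ---------------------------------------------------------------------------

def find_overlaps(
    A: PeakSet, B: PeakSet, min_overlap: int = 1
) -> list[tuple[GenomicInterval, GenomicInterval, int]]:
    """All pairs (a, b) sharing >= ``min_overlap`` bases on the same chromosome.

    Half-open adjacency ([0,100) vs [100,200)) is not overlap. The result is
    sorted by (chrom, a.start, b.start) and is symmetric: swapping A and B
    transposes the pair list.
    """
    if min_overlap < 1:
        raise ValidationError(f"min_overlap must be >= 1, got {min_overlap}")
    trees: dict[str, IntervalTree] = {}
    for b in B:
        trees.setdefault(b.chrom, IntervalTree()).addi(b.start, b.end, b)
    out: list[tuple[GenomicInterval, GenomicInterval, int]] = []
    for a in A:
        tree = trees.get(a.chrom)
        if tree is None:
            continue
        hits = []
        for node in tree.overlap(a.start, a.end):
            b = node.data
            ol = min(a.end, b.end) - max(a.start, b.start)
            if ol >= min_overlap:
                hits.append((b, ol))
        hits.sort(key=lambda h: (h[0].start, h[0].end, h[0].name))
        out.extend((a, b, ol) for b, ol in hits)
    out.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end, t[0].name, t[1].start))
    return out


# ---------------------------------------------------------------------------
# Multi-set union with membership (connected components)
# ---------------------------------------------------------------------------

def merge_union(sets: Sequence[PeakSet], min_overlap: int = 1) -> MergedRegionSet:
    """Merge peaks from all sets into connected components of the overlap graph.

    Merging is transitive: if A overlaps B and B overlaps C, all three join
    one region even when A and C never directly overlap. Each region's span is
    the union of its component's peaks and records every contributing set
    label and peak name.
    """
    if not sets:
        raise ValidationError("merge_union requires at least one peak set")
    if min_overlap < 1:
        raise ValidationError(f"min_overlap must be >= 1, got {min_overlap}")
    labels = [s.label for s in sets]
    if len(set(labels)) != len(labels):
        raise ValidationError(f"peak set labels must be unique, got {labels}")

    tagged: list[tuple[GenomicInterval, str]] = [
        (iv, s.label) for s in sets for iv in s
    ]
    tagged.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end, t[0].name))

    regions: list[GenomicInterval] = []
    membership: list[frozenset[str]] = []
    contributors: list[list[str]] = []

    # Sweep per chromosome. An interval joins the open cluster iff it shares
    # >= min_overlap bases with the cluster member reaching furthest right;
    # intervals shorter than min_overlap can never connect to anything.
    cluster: list[tuple[GenomicInterval, str]] = []
    cur_chrom: Optional[str] = None
    max_end = -1  # furthest end among cluster members of width >= min_overlap

    def flush() -> None:
        if not cluster:
            return
        span_start = min(iv.start for iv, _ in cluster)
        span_end = max(iv.end for iv, _ in cluster)
        regions.append(
            GenomicInterval(cluster[0][0].chrom, span_start, span_end,
                            name=f"region_{len(regions) + 1}")
        )
        membership.append(frozenset(lab for _, lab in cluster))
        contributors.append([iv.name for iv, _ in cluster])

    singletons: list[tuple[GenomicInterval, str]] = []

    for iv, lab in tagged:
        if iv.length < min_overlap:
            # can never share >= min_overlap bases; emit standalone without
            # disturbing the open cluster
            singletons.append((iv, lab))
            continue
        if cluster and iv.chrom == cur_chrom and iv.start <= max_end - min_overlap:
            cluster.append((iv, lab))
            max_end = max(max_end, iv.end)
        else:
            flush()
            cluster = [(iv, lab)]
            cur_chrom = iv.chrom
            max_end = iv.end
    flush()
    for iv, lab in singletons:
        regions.append(GenomicInterval(iv.chrom, iv.start, iv.end,
                                       name=f"region_{len(regions) + 1}"))
        membership.append(frozenset([lab]))
        contributors.append([iv.name])
    return MergedRegionSet(regions, membership, contributors)


def combination_counts(
    m: MergedRegionSet, count_units: str = "regions"
) -> dict[frozenset[str], int]:
    """UpSet-style counts of regions (or contributing peaks) per label subset.

    ``count_units="regions"`` counts each merged region once under its full
    membership subset; ``"peaks"`` counts the original peaks that fed each
    region, for users who want Venn counts in peak units when several peaks
    merged into one region.
    """
    if count_units not in ("regions", "peaks"):
        raise ValidationError(f"count_units must be 'regions' or 'peaks', got {count_units!r}")
    counts: Counter[frozenset[str]] = Counter()
    for mem, contrib in zip(m.membership, m.contributors):
        counts[mem] += 1 if count_units == "regions" else len(contrib)
    return dict(counts)


def marginal_counts(m: MergedRegionSet) -> dict[str, int]:
    """Per-label number of regions in which the label participates."""
    out: Counter[str] = Counter()
    for mem in m.membership:
        for lab in mem:
            out[lab] += 1
    return dict(out)


def write_combination_counts(
    counts: dict[frozenset[str], int], path: str | Path, header: Optional[str] = None
) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("labels\tn\n")
        for mem in sorted(counts, key=lambda s: (len(s), sorted(s))):
            fh.write(f"{','.join(sorted(mem))}\t{counts[mem]}\n")
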