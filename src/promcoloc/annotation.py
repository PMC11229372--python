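"""Peak annotation around TSSs and euchromatin/heterochromatin partitioning.

Promoters are symmetric, strand-independent windows of +/-halfwidth bases
around the TSS (inclusive on both sides, so 2*halfwidth+1 bases, default
halfwidth 200). Heterochromatin is a fixed per-chromosome coordinate map; the
built-in dm6 map covers the pericentromeric blocks of the five large
chromosome arms.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .interval_core import GenomicInterval, PeakSet, ValidationError

logger = logging.getLogger(__name__)

SIMPLE_FEATURES = ["promoter", "gene_body", "intergenic"]


@dataclass
class GeneModel:
    """A gene reduced to what promoter annotation needs: one TSS and a span."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    span_start: int
    span_end: int
    housekeeping: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")
        if not (self.span_start <= self.tss < self.span_end):
            raise ValidationError(
                f"gene {self.gene_id}: TSS {self.tss} outside span "
                f"[{self.span_start}, {self.span_end})"
            )


@dataclass
class AnnotationParams:
    promoter_halfwidth: int = 200
    feature_priority: Sequence[str] = tuple(SIMPLE_FEATURES)
    anchor: str = "summit"

    def __post_init__(self) -> None:
        if self.promoter_halfwidth <= 0:
            raise ValidationError("promoter_halfwidth must be positive")
        if not self.feature_priority or self.feature_priority[0] != "promoter":
            raise ValidationError("feature_priority must start with 'promoter'")
        if self.anchor not in ("summit", "midpoint"):
            raise ValidationError(f"anchor must be summit or midpoint, got {self.anchor!r}")


@dataclass
class HeterochromatinMap:
    """Per-chromosome non-overlapping heterochromatin intervals (0-based half-open)."""

    intervals: dict[str, list[GenomicInterval]]

    def __post_init__(self) -> None:
        for chrom, ivs in self.intervals.items():
            ivs.sort(key=lambda iv: iv.start)
            for a, b in zip(ivs, ivs[1:]):
                if b.start < a.end:
                    raise ValidationError(
                        f"heterochromatin intervals overlap on {chrom}: "
                        f"[{a.start},{a.end}) and [{b.start},{b.end})"
                    )

    def contains(self, chrom: str, pos: int) -> bool:
        for iv in self.intervals.get(chrom, ()):
            if iv.start <= pos < iv.end:
                return True
        return False


def _het_map_from_1based(spans: Mapping[str, tuple[int, int]]) -> HeterochromatinMap:
    return HeterochromatinMap(
        {
            chrom: [GenomicInterval(chrom, s - 1, e, name=f"het_{chrom}")]
            for chrom, (s, e) in spans.items()
        }
    )


#: Pericentromeric heterochromatin of the dm6 assembly, defined by centromere
#: coordinates. Given here as 1-based inclusive spans (the convention of
#: genome-browser coordinate listings) and converted to 0-based half-open.
DM6_HETEROCHROMATIN_SPANS_1BASED: dict[str, tuple[int, int]] = {
    "2L": (22000975, 23513712),
    "2R": (1, 5398184),
    "3L": (22962476, 28110227),
    "3R": (1, 4174178),
    "X": (22628490, 23542271),
}

DM6_HETEROCHROMATIN = _het_map_from_1based(DM6_HETEROCHROMATIN_SPANS_1BASED)


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------

def promoter_window(g: GeneModel, halfwidth: int = 200) -> GenomicInterval:
    """The +/-halfwidth promoter window around a gene's TSS.

    Inclusive on both ends (tss-halfwidth .. tss+halfwidth, i.e. stored as
    ``[tss-halfwidth, tss+halfwidth+1)``), clipped at position 0, and
    identical for plus- and minus-strand genes.
    """
    start = max(0, g.tss - halfwidth)
    return GenomicInterval(g.chrom, start, g.tss + halfwidth + 1,
                           name=f"promoter_{g.gene_id}", strand=g.strand)


class _GeneIndex:
    """Per-chromosome gene lookup used by the annotation operations."""

    def __init__(self, genes: Sequence[GeneModel], halfwidth: int):
        self.halfwidth = halfwidth
        self.by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            self.by_chrom.setdefault(g.chrom, []).append(g)
        for glist in self.by_chrom.values():
            glist.sort(key=lambda g: (g.tss, g.gene_id))

    def promoter_hits(self, chrom: str, pos: int) -> list[GeneModel]:
        hw = self.halfwidth
        return [
            g for g in self.by_chrom.get(chrom, ())
            if g.tss - hw <= pos <= g.tss + hw
        ]

    def body_hits(self, chrom: str, pos: int) -> list[GeneModel]:
        return [
            g for g in self.by_chrom.get(chrom, ())
            if g.span_start <= pos < g.span_end
        ]


def _nearest_tss(genes: Sequence[GeneModel], pos: int) -> GeneModel:
    # nearest TSS wins; distance ties go to the lexicographically smaller id
    return min(genes, key=lambda g: (abs(g.tss - pos), g.gene_id))


def assign_feature(
    p: GenomicInterval,
    genes: Sequence[GeneModel] | _GeneIndex,
    params: AnnotationParams = AnnotationParams(),
) -> tuple[str, Optional[str]]:
    """Assign one feature label (and gene, where applicable) to a peak.

    The peak's anchor point (summit if available and requested, else
    midpoint) is tested against features in priority order: a promoter window
    always wins; otherwise a containing gene span yields ``gene_body``;
    otherwise ``intergenic``. Peaks on chromosomes with no annotated genes are
    intergenic (a warning is logged).
    """
    index = genes if isinstance(genes, _GeneIndex) else _GeneIndex(genes, params.promoter_halfwidth)
    pos = p.anchor(params.anchor)
    if p.chrom not in index.by_chrom:
        logger.warning("peak %s on chromosome %s with no annotated genes", p.name, p.chrom)
        return "intergenic", None
    hits = index.promoter_hits(p.chrom, pos)
    if hits:
        return "promoter", _nearest_tss(hits, pos).gene_id
    hits = index.body_hits(p.chrom, pos)
    if hits:
        return "gene_body", _nearest_tss(hits, pos).gene_id
    return "intergenic", None


def is_heterochromatic(
    p: GenomicInterval, het_map: HeterochromatinMap, anchor: str = "summit"
) -> bool:
    """True iff the peak's anchor point falls inside a heterochromatin block."""
    return het_map.contains(p.chrom, p.anchor(anchor))


def peaks_to_promoter_genes(
    ps: PeakSet,
    genes: Sequence[GeneModel],
    params: AnnotationParams = AnnotationParams(),
    housekeeping_only: bool = False,
) -> set[str]:
    """Gene ids whose promoter window contains at least one peak anchor.

    Set semantics: a gene appears once no matter how many peaks hit its
    promoter. A peak anchored inside several overlapping promoter windows is
    assigned to the gene with the nearest TSS (ties to the lexicographically
    smaller gene id). With ``housekeeping_only`` the result is restricted to
    housekeeping genes.
    """
    index = _GeneIndex(genes, params.promoter_halfwidth)
    out: set[str] = set()
    by_id = {g.gene_id: g for g in genes}
    for peak in ps:
        hits = index.promoter_hits(peak.chrom, peak.anchor(params.anchor))
        if not hits:
            continue
        g = _nearest_tss(hits, peak.anchor(params.anchor))
        if housekeeping_only and not by_id[g.gene_id].housekeeping:
            continue
        out.add(g.gene_id)
    return out


def summarize_distribution(
    ps: PeakSet,
    genes: Sequence[GeneModel],
    het_map: HeterochromatinMap,
    params: AnnotationParams = AnnotationParams(),
    motif_flags: Optional[Sequence[bool]] = None,
) -> pd.DataFrame:
    """Counts of peaks by feature x compartment x motif status.

    Returns a DataFrame indexed by (feature, compartment, motif) whose
    ``count`` column sums to the total number of peaks; ``fraction`` is
    count/total (all zeros yield an empty-total frame with fraction 0).
    """
    if motif_flags is None:
        motif_flags = [False] * len(ps)
    if len(motif_flags) != len(ps):
        raise ValidationError(
            f"motif_flags length {len(motif_flags)} != number of peaks {len(ps)}"
        )
    index = _GeneIndex(genes, params.promoter_halfwidth)
    rows = []
    for peak, flag in zip(ps, motif_flags):
        feature, _ = assign_feature(peak, index, params)
        compartment = (
            "heterochromatin" if is_heterochromatic(peak, het_map, params.anchor)
            else "euchromatin"
        )
        rows.append((feature, compartment, "with_motif" if flag else "without_motif"))
    features = list(params.feature_priority)
    idx = pd.MultiIndex.from_product(
        [features, ["euchromatin", "heterochromatin"], ["with_motif", "without_motif"]],
        names=["feature", "compartment", "motif"],
    )
    counts = pd.Series(0, index=idx, name="count")
    for key in rows:
        counts.loc[key] += 1
    df = counts.to_frame()
    total = len(ps)
    df["fraction"] = df["count"] / total if total else 0.0
    return df


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_GENE_ID_RE = re.compile(r'gene_id "([^"]+)"')

GTF_COLUMNS = [
    "seqname", "source", "feature", "start", "end",
    "score", "strand", "frame", "attribute",
]


def read_gtf(path: str | Path, feature: str = "gene") -> list[GeneModel]:
    """Read gene models from GTF (1-based inclusive, converted on read).

    Rows whose feature column matches ``feature`` (default ``gene``) are used;
    if none are present, spans are aggregated per gene_id over all rows. The
    TSS is the 5' end of the span given the strand. Housekeeping flags are
    left False; see :func:`mark_housekeeping`.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=GTF_COLUMNS,
        dtype={"seqname": str, "start": int, "end": int, "strand": str},
    )
    gene_rows = df[df["feature"] == feature]
    if gene_rows.empty:
        df = df.assign(gene_id=df["attribute"].str.extract(_GENE_ID_RE, expand=False))
        gene_rows = (
            df.groupby("gene_id")
            .agg(seqname=("seqname", "first"), start=("start", "min"),
                 end=("end", "max"), strand=("strand", "first"))
            .reset_index()
        )
    else:
        gene_rows = gene_rows.assign(
            gene_id=gene_rows["attribute"].str.extract(_GENE_ID_RE, expand=False)
        )
    genes = []
    for row in gene_rows.itertuples(index=False):
        if not isinstance(row.gene_id, str) or not row.gene_id:
            raise ValidationError(f"GTF row without gene_id attribute: {row}")
        start0, end0 = int(row.start) - 1, int(row.end)
        tss = start0 if row.strand == "+" else end0 - 1
        genes.append(GeneModel(row.gene_id, str(row.seqname), row.strand, tss, start0, end0))
    genes.sort(key=lambda g: (g.chrom, g.tss, g.gene_id))
    return genes


def read_housekeeping_list(path: str | Path) -> set[str]:
    """One gene id per line (first tab-separated field); '#' lines skipped."""
    out = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line.split("\t")[0])
    return out


def mark_housekeeping(genes: Sequence[GeneModel], housekeeping_ids: set[str]) -> None:
    """Set the housekeeping flag in place from a gene-id list."""
    for g in genes:
        g.housekeeping = g.gene_id in housekeeping_ids


def read_heterochromatin_bed(path: str | Path) -> HeterochromatinMap:
    """Heterochromatin map from a BED file (already 0-based half-open)."""
    from .interval_core import read_peaks

    ps = read_peaks(path, format="bed")
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in ps:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    return HeterochromatinMap(by_chrom)


def write_annotated_peaks(
    ps: PeakSet,
    genes: Sequence[GeneModel],
    het_map: HeterochromatinMap,
    path: str | Path,
    params: AnnotationParams = AnnotationParams(),
    motif_flags: Optional[Sequence[bool]] = None,
    header: Optional[str] = None,
) -> pd.DataFrame:
    """Write per-peak annotation (feature, gene, compartment, motif) as TSV."""
    if motif_flags is None:
        motif_flags = [False] * len(ps)
    index = _GeneIndex(genes, params.promoter_halfwidth)
    rows = []
    for peak, flag in zip(ps, motif_flags):
        feature, gene_id = assign_feature(peak, index, params)
        compartment = (
            "heterochromatin" if is_heterochromatic(peak, het_map, params.anchor)
            else "euchromatin"
        )
        rows.append(
            dict(peak=peak.name, chrom=peak.chrom, start=peak.start, end=peak.end,
                 feature=feature, gene_id=gene_id or "", compartment=compartment,
                 has_motif=flag)
        )
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", index=False)
    return df
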