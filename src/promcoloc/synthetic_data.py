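"""Synthetic genomes, gene models, correlated binding sets, and motif implants.

The generator emulates the statistical structure the colocalization analysis
assumes: each protein binds each housekeeping promoter independently across
genes with a controlled marginal probability, and pairwise dependence between
proteins is controlled by the odds ratio theta of a bivariate Bernoulli
(theta = 1 gives independence — the null of the Monte Carlo test). Gene
models are laid out in non-overlapping slots so that promoter windows of
adjacent genes never overlap and annotation can recover bound sets exactly.
Everything is deterministic given the config seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .annotation import GeneModel, HeterochromatinMap
from .colocalization import BoundSet
from .interval_core import GenomicInterval, PeakSet, ValidationError
from .motif_scan import ALPHABET, PWM

logger = logging.getLogger(__name__)

# substream tags so each generation stage has its own reproducible stream
_STREAM_GENES, _STREAM_BINDING, _STREAM_PEAKS, _STREAM_SEQ, _STREAM_DE = range(5)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class SynthConfig:
    """Simulation parameters; defaults give a compact two-chromosome genome
    with promoter-level binding rates in the range typical of architectural
    proteins on housekeeping promoters."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 1000
    housekeeping_fraction: float = 0.6
    het_fraction: float = 0.15          # pericentromeric block at each chrom start
    het_blocks: Optional[dict[str, list[tuple[int, int]]]] = None
    proteins: Sequence[tuple[str, float]] = (("P1", 0.1), ("P2", 0.1))
    pairwise_theta: dict[tuple[str, str], float] = field(default_factory=dict)
    peak_width: int = 200
    summit_jitter: int = 0
    promoter_halfwidth: int = 200
    motif: Optional[PWM] = None
    implant_probability: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.housekeeping_fraction <= 1):
            raise ValidationError("housekeeping_fraction must be in (0, 1]")
        for name, p in self.proteins:
            if not (0 <= p <= 1):
                raise ValidationError(f"protein {name}: marginal {p} outside [0, 1]")
        for pair, theta in self.pairwise_theta.items():
            if theta <= 0:
                raise ValidationError(f"pair {pair}: odds ratio must be > 0")
        if self.peak_width <= 0:
            raise ValidationError("peak_width must be positive")
        if not (0 <= self.implant_probability <= 1):
            raise ValidationError("implant_probability must be in [0, 1]")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


@dataclass
class GroundTruth:
    """Everything the recovery tests need to check a pipeline run exactly."""

    bound: dict[str, frozenset[str]] = field(default_factory=dict)
    realized_theta: dict[tuple[str, str], float] = field(default_factory=dict)
    housekeeping: frozenset[str] = frozenset()
    compartment: dict[str, str] = field(default_factory=dict)
    implants: dict[str, tuple[int, str, str]] = field(default_factory=dict)
    # implants: peak name -> (absolute start, strand, implanted word)


# ---------------------------------------------------------------------------
# Bivariate Bernoulli with a given odds ratio (Plackett construction)
# ---------------------------------------------------------------------------

def joint_success_probability(p1: float, p2: float, theta: float) -> float:
    """p11 of the bivariate Bernoulli with marginals p1, p2 and odds ratio
    theta = (p11*p00)/(p10*p01); theta = 1 yields independence p11 = p1*p2."""
    if theta <= 0:
        raise ValidationError("odds ratio must be > 0")
    if p1 in (0.0, 1.0) or p2 in (0.0, 1.0):
        return p1 * p2  # degenerate marginal: dependence unidentifiable
    if theta == 1.0:
        p11 = p1 * p2
    else:
        s = 1.0 + (p1 + p2) * (theta - 1.0)
        disc = s * s - 4.0 * theta * (theta - 1.0) * p1 * p2
        p11 = (s - math.sqrt(disc)) / (2.0 * (theta - 1.0))
    lo, hi = max(0.0, p1 + p2 - 1.0), min(p1, p2)
    if not (lo - 1e-12 <= p11 <= hi + 1e-12):
        raise ValidationError(
            f"infeasible (p1={p1}, p2={p2}, theta={theta}): p11={p11:.6g} "
            f"violates Frechet bounds [{lo:.6g}, {hi:.6g}]"
        )
    return min(max(p11, lo), hi)


def empirical_odds_ratio(x: np.ndarray, y: np.ndarray) -> float:
    """Sample odds ratio of two binary vectors (NaN when a margin is empty)."""
    x = np.asarray(x, bool)
    y = np.asarray(y, bool)
    n11 = int((x & y).sum())
    n10 = int((x & ~y).sum())
    n01 = int((~x & y).sum())
    n00 = int((~x & ~y).sum())
    if n10 == 0 or n01 == 0:
        return math.inf if n11 * n00 > 0 else math.nan
    return (n11 * n00) / (n10 * n01)


# ---------------------------------------------------------------------------
# Gene models and heterochromatin
# ---------------------------------------------------------------------------

def make_gene_models(cfg: SynthConfig) -> tuple[list[GeneModel], HeterochromatinMap]:
    """Place non-overlapping gene models and build the heterochromatin map.

    Each chromosome is divided into equal slots, one gene per slot; the TSS
    is drawn uniformly within the slot's interior and the gene span extends
    downstream of it, so adjacent promoter windows never overlap. Exactly
    round(housekeeping_fraction * n_genes) genes are flagged housekeeping.
    """
    rng = cfg._rng(_STREAM_GENES)
    chroms = cfg.chrom_names()
    per_chrom = [cfg.n_genes // cfg.n_chroms] * cfg.n_chroms
    for i in range(cfg.n_genes % cfg.n_chroms):
        per_chrom[i] += 1
    genes: list[GeneModel] = []
    gid = 0
    for chrom, n in zip(chroms, per_chrom):
        if n == 0:
            continue
        slot = cfg.chrom_length // n
        glen = slot // 3
        if glen < cfg.promoter_halfwidth + cfg.peak_width // 2 + cfg.summit_jitter + 1:
            raise ValidationError(
                f"genes cannot fit without overlap: slot {slot} bp on {chrom} "
                f"is too small for {n} genes at the configured widths"
            )
        for j in range(n):
            gid += 1
            lo = j * slot + glen
            hi = (j + 1) * slot - glen
            tss = int(rng.integers(lo, hi))
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                span = (tss, tss + glen)
            else:
                span = (tss - glen + 1, tss + 1)
            genes.append(GeneModel(f"g{gid:05d}", chrom, strand, tss, *span))
    n_hk = int(round(cfg.housekeeping_fraction * cfg.n_genes))
    hk_idx = rng.choice(len(genes), size=n_hk, replace=False)
    for i in hk_idx:
        genes[i].housekeeping = True

    if cfg.het_blocks is not None:
        blocks = cfg.het_blocks
    else:
        het_len = int(cfg.het_fraction * cfg.chrom_length)
        blocks = {c: [(0, het_len)] for c in chroms} if het_len > 0 else {}
    het_map = HeterochromatinMap(
        {
            c: [GenomicInterval(c, s, e, name=f"het_{c}_{i}")
                for i, (s, e) in enumerate(ivs)]
            for c, ivs in blocks.items()
        }
    )
    return genes, het_map


# ---------------------------------------------------------------------------
# Correlated binding indicators
# ---------------------------------------------------------------------------

def gene_compartments(
    genes: Sequence[GeneModel], het_map: HeterochromatinMap
) -> dict[str, str]:
    """Per-gene compartment label from the TSS position."""
    return {
        g.gene_id: "heterochromatin" if het_map.contains(g.chrom, g.tss)
        else "euchromatin"
        for g in genes
    }


def make_bound_sets(
    cfg: SynthConfig, genes: Sequence[GeneModel],
    het_map: Optional[HeterochromatinMap] = None,
) -> tuple[list[BoundSet], GroundTruth]:
    """Draw per-housekeeping-gene binding indicators for every protein.

    The first listed protein is the reference: every other protein's joint
    with the reference follows the bivariate Bernoulli with the configured
    odds ratio (theta keys are (reference, other) tuples; unspecified pairs
    default to theta = 1). Dependence between two non-reference proteins is
    whatever the sequential construction induces; the ground truth records
    the realized pairwise odds ratios for all pairs.
    """
    rng = cfg._rng(_STREAM_BINDING)
    hk = [g.gene_id for g in genes if g.housekeeping]
    if not hk:
        raise ValidationError("no housekeeping genes to bind")
    names = [name for name, _ in cfg.proteins]
    marginals = dict(cfg.proteins)
    ref = names[0]
    for pair in cfg.pairwise_theta:
        if pair[0] != ref or pair[1] not in names or pair[1] == ref:
            raise ValidationError(
                f"pairwise_theta keys must be (reference, other) = ({ref!r}, ...); "
                f"got {pair}"
            )
    n = len(hk)
    indicators: dict[str, np.ndarray] = {ref: rng.random(n) < marginals[ref]}
    p_ref = marginals[ref]
    for name in names[1:]:
        p = marginals[name]
        theta = cfg.pairwise_theta.get((ref, name), 1.0)
        p11 = joint_success_probability(p_ref, p, theta)
        if p_ref in (0.0, 1.0):
            cond1 = p
        else:
            cond1 = p11 / p_ref
        cond0 = (p - p11) / (1 - p_ref) if p_ref < 1 else p
        u = rng.random(n)
        x_ref = indicators[ref]
        indicators[name] = np.where(x_ref, u < cond1, u < cond0)
    truth = GroundTruth(housekeeping=frozenset(hk))
    hk_arr = np.array(hk)
    bound_sets = []
    for name in names:
        members = frozenset(hk_arr[indicators[name]])
        truth.bound[name] = members
        bound_sets.append(BoundSet(name, members))
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            truth.realized_theta[(a, b)] = empirical_odds_ratio(
                indicators[a], indicators[b]
            )
    if het_map is not None:
        truth.compartment = gene_compartments(genes, het_map)
    return bound_sets, truth


# ---------------------------------------------------------------------------
# Peaks and sequences
# ---------------------------------------------------------------------------

def bound_sets_to_peaks(
    bound: Sequence[BoundSet], genes: Sequence[GeneModel], cfg: SynthConfig
) -> list[PeakSet]:
    """One peak per bound gene, centered on its TSS with a jittered summit.

    With ``summit_jitter`` at most min(promoter_halfwidth, peak_width//2 - 1)
    the summit is guaranteed to fall inside the promoter window and
    annotation recovers every bound set exactly; a larger jitter only
    triggers a warning (recovery then holds in expectation, not exactly).
    """
    safe = min(cfg.promoter_halfwidth, cfg.peak_width // 2 - 1)
    if cfg.summit_jitter > safe:
        logger.warning(
            "summit_jitter %d exceeds %d; exact bound-set recovery not guaranteed",
            cfg.summit_jitter, safe,
        )
    rng = cfg._rng(_STREAM_PEAKS)
    by_id = {g.gene_id: g for g in genes}
    out = []
    for bs in bound:
        ivs = []
        for gene_id in sorted(bs.genes):
            g = by_id[gene_id]
            start = max(0, g.tss - cfg.peak_width // 2)
            end = start + cfg.peak_width
            jitter = int(rng.integers(-cfg.summit_jitter, cfg.summit_jitter + 1)) \
                if cfg.summit_jitter > 0 else 0
            summit = int(np.clip(g.tss + jitter, start, end - 1))
            ivs.append(
                GenomicInterval(g.chrom, start, end,
                                name=f"{bs.protein}_{gene_id}", summit=summit)
            )
        out.append(PeakSet(bs.protein, ivs, source_format="synthetic"))
    return out


def sample_word(pwm: PWM, rng: np.random.Generator) -> str:
    """One word drawn column-wise from the PWM's probability matrix."""
    return "".join(
        ALPHABET[rng.choice(4, p=pwm.probs[i])] for i in range(pwm.length)
    )


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def implant_motifs(
    cfg: SynthConfig, peaks: PeakSet | Sequence[PeakSet]
) -> tuple[dict[str, str], GroundTruth]:
    """Background genome sequences with motif words implanted into peaks.

    The genome is drawn i.i.d. from the PWM's background distribution. Each
    peak independently receives (with ``implant_probability``) one word
    sampled from the PWM, on a uniformly chosen strand, at a uniform offset
    within the peak; the returned truth records (start, strand, word) per
    peak name. Peaks shorter than the motif are skipped with a warning.
    """
    if cfg.motif is None:
        raise ValidationError("implant_motifs requires cfg.motif")
    pwm = cfg.motif
    rng = cfg._rng(_STREAM_SEQ)
    peak_sets = [peaks] if isinstance(peaks, PeakSet) else list(peaks)
    genome: dict[str, np.ndarray] = {}
    for chrom in cfg.chrom_names():
        codes = rng.choice(4, size=cfg.chrom_length, p=pwm.background)
        genome[chrom] = codes
    letters = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)
    truth = GroundTruth()
    for ps in peak_sets:
        for peak in ps:
            if peak.length < pwm.length:
                logger.warning("peak %s shorter than motif; skipped", peak.name)
                continue
            if rng.random() >= cfg.implant_probability:
                continue
            pos = int(rng.integers(peak.start, peak.end - pwm.length + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            word = sample_word(pwm, rng)
            inserted = word if strand == "+" else reverse_complement(word)
            enc = np.array([ALPHABET.index(c) for c in inserted], dtype=genome[peak.chrom].dtype)
            genome[peak.chrom][pos:pos + pwm.length] = enc
            truth.implants[peak.name] = (pos, strand, word)
    seqs = {
        chrom: letters[codes].tobytes().decode()
        for chrom, codes in genome.items()
    }
    return seqs, truth


# ---------------------------------------------------------------------------
# Synthetic differential expression (for end-to-end pipeline runs)
# ---------------------------------------------------------------------------

def make_de_table(
    cfg: SynthConfig,
    genes: Sequence[GeneModel],
    truth: GroundTruth,
    effect_log2fc: float = -1.0,
    effect_probability: float = 0.6,
) -> "pd.DataFrame":
    """A DE table where bound genes carry a planted expression effect.

    Genes bound by the reference protein are significant (FDR ~ U(0, 0.05))
    with ``effect_probability`` and get log2FC ~ N(effect_log2fc, 0.25);
    all other genes are null (FDR ~ U(0.05, 1), log2FC ~ N(0, 0.1)).
    """
    import pandas as pd

    rng = cfg._rng(_STREAM_DE)
    ref = cfg.proteins[0][0]
    bound = truth.bound.get(ref, frozenset())
    rows = []
    for g in genes:
        if g.gene_id in bound and rng.random() < effect_probability:
            lfc = rng.normal(effect_log2fc, 0.25)
            fdr = rng.uniform(0, 0.05)
        else:
            lfc = rng.normal(0.0, 0.1)
            fdr = rng.uniform(0.05, 1.0)
        rows.append(dict(gene_id=g.gene_id, log2fc=lfc, fdr=fdr))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_gtf(genes: Sequence[GeneModel], path: str | Path,
              source: str = "promcoloc_synth") -> None:
    """Write gene models as GTF (1-based inclusive on output)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; housekeeping "{int(g.housekeeping)}";'
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.span_start + 1}\t{g.span_end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in seqs.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_bound_sets_tsv(bound: Sequence[BoundSet], path: str | Path,
                         header: Optional[str] = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for bs in bound:
            for gene in sorted(bs.genes):
                fh.write(f"{bs.protein}\t{gene}\n")


def write_housekeeping_list(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            if g.housekeeping:
                fh.write(g.gene_id + "\n")
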