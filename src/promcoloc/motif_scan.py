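"""PWM construction, exact p-value score thresholds, and two-strand scanning.

Scores are log2 odds against a background nucleotide distribution. P-values
are computed exactly over a discretized score grid: per-position scores are
quantized to integer multiples of ``step`` and the distribution of the total
word score under the background model is obtained by dynamic-programming
convolution. Scanning quantizes window scores with the same step, so the set
of words passing a threshold is exactly the set the DP counted — refining the
step does not change which words pass except at genuine grid boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .interval_core import PeakSet, ValidationError

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
UNIFORM_BACKGROUND = np.full(4, 0.25)
#: Sentinel log-odds for zero-probability letters (pseudocount 0): large
#: enough in magnitude to sink any word containing the letter below any
#: realistic threshold, small enough to stay on the quantization grid.
NEG_SENTINEL = -100.0
DEFAULT_STEP = 1e-3

_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate(ALPHABET):
    _ENCODE[ord(_c)] = _i
    _ENCODE[ord(_c.lower())] = _i


@dataclass
class PWM:
    """Position weight matrix over ACGT with derived log2-odds scores."""

    probs: np.ndarray           # (L, 4), rows sum to 1
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())
    pseudocount: float = 0.0
    name: str = "pwm"

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or self.probs.shape[0] < 1:
            raise ValidationError(f"PWM probs must be (L, 4) with L >= 1, got {self.probs.shape}")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("PWM rows must each sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValidationError("background must sum to 1")
        with np.errstate(divide="ignore"):
            lo = np.log2(self.probs / self.background)
        self.log_odds = np.where(np.isneginf(lo), NEG_SENTINEL, lo)

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        """The PWM matching the reverse complement of this motif."""
        return PWM(self.probs[::-1, ::-1].copy(), self.background.copy(),
                   self.pseudocount, name=f"{self.name}_rc")

    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    def min_score(self) -> float:
        return float(self.log_odds.min(axis=1).sum())


@dataclass
class ScanParams:
    p_threshold: float = 1e-4
    both_strands: bool = True
    step: float = DEFAULT_STEP

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold <= 1):
            raise ValidationError(f"p_threshold must be in (0, 1], got {self.p_threshold}")
        if self.step <= 0:
            raise ValidationError("step must be positive")


def pwm_from_counts(
    counts: np.ndarray,
    pseudocount: float = 1.0,
    background: Optional[np.ndarray] = None,
    name: str = "pwm",
) -> PWM:
    """Build a PWM from an (L, 4) count matrix.

    probs[i, a] = (counts[i, a] + pseudocount) / (rowsum + 4 * pseudocount).
    With pseudocount 0, zero-count letters get the ``NEG_SENTINEL`` log-odds.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 4:
        raise ValidationError(f"counts must be (L, 4), got {counts.shape}")
    if (counts < 0).any():
        raise ValidationError("counts must be non-negative")
    rowsum = counts.sum(axis=1)
    if pseudocount == 0 and (rowsum == 0).any():
        raise ValidationError("all-zero count row with pseudocount=0")
    bg = UNIFORM_BACKGROUND.copy() if background is None else np.asarray(background, float)
    probs = (counts + pseudocount) / (rowsum + 4 * pseudocount)[:, None]
    return PWM(probs, bg, pseudocount, name=name)


# ---------------------------------------------------------------------------
# Exact background score distribution (quantized DP)
# ---------------------------------------------------------------------------

def _quantized_scores(pwm: PWM, step: float) -> np.ndarray:
    """Per-position integer scores: round(log_odds / step)."""
    return np.rint(pwm.log_odds / step).astype(np.int64)


@dataclass
class ScoreDistribution:
    """Exact pmf of the quantized total word score under the background model.

    ``pmf[i]`` is the probability that a random background word has quantized
    score ``offset + i``. Support bounds equal the column-wise min/max score
    sums by construction.
    """

    step: float
    offset: int                 # quantized score of pmf[0]
    pmf: np.ndarray

    def __post_init__(self) -> None:
        if not np.isclose(self.pmf.sum(), 1.0, atol=1e-9):
            raise ValidationError("score pmf must sum to 1")

    def tail(self, t_quantized: int) -> float:
        """P(quantized word score >= t_quantized)."""
        i = t_quantized - self.offset
        if i <= 0:
            return 1.0
        if i >= len(self.pmf):
            return 0.0
        return float(self.pmf[i:].sum())


def score_distribution(pwm: PWM, step: float = DEFAULT_STEP) -> ScoreDistribution:
    """DP convolution of per-position quantized score distributions."""
    q = _quantized_scores(pwm, step)
    lo, hi = int(q.min(axis=1).sum()), int(q.max(axis=1).sum())
    pmf = np.zeros(hi - lo + 1)
    # running pmf over a growing support; start with a point mass at score 0
    run = np.array([1.0])
    run_off = 0
    for i in range(pwm.length):
        qmin, qmax = int(q[i].min()), int(q[i].max())
        new = np.zeros(len(run) + (qmax - qmin))
        for a in range(4):
            b = pwm.background[a]
            if b == 0:
                continue
            sh = int(q[i, a]) - qmin
            new[sh:sh + len(run)] += b * run
        run = new
        run_off += qmin
    if run_off != lo or len(run) != hi - lo + 1:  # pragma: no cover - internal check
        raise AssertionError("score DP support mismatch")
    pmf[:] = run
    return ScoreDistribution(step=step, offset=lo, pmf=pmf)


def score_pvalue_threshold(
    pwm: PWM, p: float, step: float = DEFAULT_STEP
) -> float:
    """Minimal score t on the quantization grid with P_bg(score >= t) <= p.

    Words are called at a p-value threshold by comparing their quantized
    score against the quantized threshold (see :func:`scan_sequence`). For
    p = 1 every word passes (t is the minimum possible word score).
    """
    if not (0 < p <= 1):
        raise ValidationError(f"p must be in (0, 1], got {p}")
    dist = score_distribution(pwm, step)
    # tail(offset + i) is non-increasing in i; find smallest i with tail <= p
    tails = np.concatenate([dist.pmf[::-1].cumsum()[::-1], [0.0]])
    idx = int(np.searchsorted(-tails, -p, side="left"))
    if idx >= len(dist.pmf):
        # only the empty tail qualifies; threshold just above the max score
        return (dist.offset + len(dist.pmf)) * step
    return (dist.offset + idx) * step


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def encode_sequence(seq: str) -> np.ndarray:
    """ACGT -> 0..3 (case-insensitive); anything else (incl. N) -> -1."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_scores_quantized(pwm: PWM, enc: np.ndarray, step: float) -> np.ndarray:
    """Quantized scores of all length-L windows; windows with N get INT64_MIN."""
    L = pwm.length
    n = len(enc) - L + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64)
    q = _quantized_scores(pwm, step)
    windows = np.lib.stride_tricks.sliding_window_view(enc, L)
    valid = (windows >= 0).all(axis=1)
    safe = np.where(windows >= 0, windows, 0)
    scores = q[np.arange(L)[None, :], safe].sum(axis=1)
    scores[~valid] = np.iinfo(np.int64).min
    return scores


def scan_sequence(
    pwm: PWM,
    seq: str,
    threshold: float,
    both_strands: bool = True,
    step: float = DEFAULT_STEP,
) -> list[tuple[int, str, float]]:
    """All windows scoring >= threshold, as (start, strand, score) tuples.

    The comparison is on the quantization grid used by the threshold DP, so a
    word passes here iff the DP counted it. Windows containing N are skipped.
    Minus-strand hits (scored with the reverse-complement PWM) are reported at
    the plus-strand coordinate of the window start. Sequences shorter than
    the motif yield an empty list.
    """
    enc = encode_sequence(seq)
    tq = int(round(threshold / step))
    hits: list[tuple[int, str, float]] = []
    strands = [("+", pwm)]
    if both_strands:
        strands.append(("-", pwm.reverse_complement()))
    for strand, mat in strands:
        scores = _window_scores_quantized(mat, enc, step)
        for pos in np.flatnonzero(scores >= tq):
            hits.append((int(pos), strand, float(scores[pos] * step)))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def flag_motif_peaks(
    ps: PeakSet,
    genome: Mapping[str, str],
    pwms: Sequence[PWM],
    params: ScanParams = ScanParams(),
) -> list[bool]:
    """Per-peak flag: True iff any supplied PWM hits inside the peak span.

    Each PWM is used at its own score threshold for ``params.p_threshold``
    (logical OR across motifs). ``genome`` is any chrom -> sequence mapping
    (an indexed FASTA handle qualifies). A peak on a chromosome absent from
    the genome raises an error naming the peak.
    """
    thresholds = [score_pvalue_threshold(p, params.p_threshold, params.step) for p in pwms]
    flags: list[bool] = []
    for peak in ps:
        if peak.chrom not in genome:
            raise ValidationError(
                f"peak {peak.name!r}: chromosome {peak.chrom!r} not in genome"
            )
        seq = str(genome[peak.chrom][peak.start:peak.end])
        flag = False
        for pwm, t in zip(pwms, thresholds):
            if scan_sequence(pwm, seq, t, params.both_strands, params.step):
                flag = True
                break
        flags.append(flag)
    return flags


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_pwm_counts_tsv(path: str | Path, pseudocount: float = 1.0,
                        background: Optional[np.ndarray] = None) -> PWM:
    """Plain L x 4 count matrix (columns A C G T, optional header line)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0].upper() in ("A", "ACGT") or fields == list("ACGT"):
                continue
            rows.append([float(x) for x in fields[-4:]])
    return pwm_from_counts(np.array(rows), pseudocount, background,
                           name=Path(path).stem)


def read_meme_motifs(path: str | Path) -> list[PWM]:
    """Minimal MEME motif format reader (letter-probability matrices)."""
    pwms: list[PWM] = []
    background = UNIFORM_BACKGROUND.copy()
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            freqs = lines[i + 1].split()
            background = np.array([float(freqs[j]) for j in (1, 3, 5, 7)])
            i += 2
            continue
        if line.startswith("MOTIF"):
            name = line.split()[1]
            while i < len(lines) and "letter-probability" not in lines[i]:
                i += 1
            header = lines[i]
            L = int(header.split("w=")[1].split()[0])
            mat = np.array([[float(x) for x in lines[i + 1 + j].split()] for j in range(L)])
            mat = mat / mat.sum(axis=1, keepdims=True)
            pwms.append(PWM(mat, background.copy(), name=name))
            i += 1 + L
            continue
        i += 1
    return pwms


def write_hits_bed(hits: Sequence[tuple[str, int, str, float]], L: int,
                   path: str | Path) -> None:
    """Write (chrom, start, strand, score) motif hits as BED6."""
    with open(path, "w") as fh:
        for j, (chrom, start, strand, score) in enumerate(hits, 1):
            fh.write(f"{chrom}\t{start}\t{start + L}\tmotif_{j}\t{score:.4f}\t{strand}\n")
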