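"""Monte Carlo colocalization test over housekeeping-promoter universes.

For two proteins bound at N1 and N2 housekeeping promoters out of a universe
U, the observed sharing statistic is Fo = k / |A u B| (Jaccard fraction of
shared promoter ids, k = |A n B|). The null resamples pairs of uniform
random subsets of sizes N1 and N2 from U without replacement (default 5000
pairs), records their sharing fraction Fs, and the empirical p-value is the
proportion of Fs values strictly exceeding Fo. Because Fo is strictly
increasing in k at fixed N1, N2, the null law of k is hypergeometric, which
provides an exact closed-form cross-check (:func:`hypergeom_tail`).
P-values across protein pairs are Benjamini-Hochberg adjusted.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .interval_core import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class PromoterUniverse:
    """The ordered set of housekeeping promoter ids used as sampling frame."""

    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("universe gene ids must be unique")
        if len(self.gene_ids) < 2:
            raise ValidationError("universe must contain at least 2 promoters")
        self.gene_ids = tuple(self.gene_ids)

    def __len__(self) -> int:
        return len(self.gene_ids)

    @classmethod
    def from_ids(cls, ids: Sequence[str]) -> "PromoterUniverse":
        return cls(tuple(sorted(set(ids))))


@dataclass
class BoundSet:
    """One protein's bound housekeeping promoters (a subset of the universe)."""

    protein: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)

    @property
    def size(self) -> int:
        return len(self.genes)

    def validate_in(self, universe: PromoterUniverse) -> None:
        extra = self.genes - set(universe.gene_ids)
        if extra:
            raise ValidationError(
                f"bound set {self.protein!r} has genes outside the universe: "
                f"{sorted(extra)[:5]}"
            )


@dataclass
class MCParams:
    n_samples: int = 5000
    seed: int = 0
    tie_rule: str = "strict_greater"   # "exceeded" reading: p = #{Fs > Fo}/n
    smoothing: str = "none"            # or "add_one": (# + 1)/(n + 1)

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        if self.tie_rule not in ("strict_greater", "greater_equal"):
            raise ValidationError(f"unknown tie_rule {self.tie_rule!r}")
        if self.smoothing not in ("none", "add_one"):
            raise ValidationError(f"unknown smoothing {self.smoothing!r}")


@dataclass
class ColocResult:
    protein1: str
    protein2: str
    n1: int
    n2: int
    k: int
    fo: float
    p_emp: float
    p_adj: float
    n_samples: int
    seed: int
    fs: Optional[np.ndarray] = None  # full null vector, kept on request


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def sharing_fraction(k: int | np.ndarray, n1: int, n2: int) -> float | np.ndarray:
    """F = k / |A u B| = k / (n1 + n2 - k); strictly increasing in k."""
    return k / (n1 + n2 - k)


def observed_stat(A: BoundSet, B: BoundSet) -> tuple[int, float]:
    """(k, Fo) for two bound sets; undefined (error) when both are empty."""
    if A.size == 0 and B.size == 0:
        raise ValidationError(
            f"sharing fraction undefined: both {A.protein!r} and {B.protein!r} are empty"
        )
    k = len(A.genes & B.genes)
    return k, float(sharing_fraction(k, A.size, B.size))


def _random_subsets(rng: np.random.Generator, U: int, N: int, n: int) -> np.ndarray:
    """(n, N) matrix of uniform size-N subsets of range(U), each row without
    replacement, via a partial Fisher-Yates shuffle vectorized over rows."""
    idx = np.tile(np.arange(U, dtype=np.int32), (n, 1))
    rows = np.arange(n)
    R = rng.random((N, n))
    for j in range(N):
        r = j + (R[j] * (U - j)).astype(np.int64)
        tmp = idx[rows, j].copy()
        idx[rows, j] = idx[rows, r]
        idx[rows, r] = tmp
    return idx[:, :N]


def sample_null_counts(
    U: PromoterUniverse | int, N1: int, N2: int, params: MCParams
) -> np.ndarray:
    """Null intersection sizes k for ``n_samples`` independent subset pairs.

    Each sample draws two independent uniform subsets (sizes N1 and N2,
    each without replacement) from the universe and records |A n B|.
    Reproducible given ``params.seed``.
    """
    u = U if isinstance(U, int) else len(U)
    if N1 > u or N2 > u:
        raise ValidationError(f"set sizes ({N1}, {N2}) exceed universe size {u}")
    if N1 < 0 or N2 < 0:
        raise ValidationError("set sizes must be non-negative")
    n = params.n_samples
    if N1 == 0 or N2 == 0:
        return np.zeros(n, dtype=np.int64)
    rng = np.random.default_rng(params.seed)
    A = _random_subsets(rng, u, N1, n)
    B = _random_subsets(rng, u, N2, n)
    mark = np.zeros((n, u), dtype=bool)
    np.put_along_axis(mark, A, True, axis=1)
    return np.take_along_axis(mark, B, axis=1).sum(axis=1).astype(np.int64)


def sample_null(
    U: PromoterUniverse | int, N1: int, N2: int, params: MCParams
) -> np.ndarray:
    """Null sharing fractions Fs (length ``n_samples``); see sample_null_counts."""
    ks = sample_null_counts(U, N1, N2, params)
    if N1 == 0 and N2 == 0:
        raise ValidationError("sharing fraction undefined for two empty sets")
    return np.asarray(sharing_fraction(ks, N1, N2), dtype=float)


def empirical_p(observed: float, null: np.ndarray, params: MCParams = MCParams()) -> float:
    """Proportion of null statistic values exceeding the observed one.

    Defaults match the resampling definition literally: strict '>' and no
    smoothing, so an observed value above every null draw yields p = 0.
    ``greater_equal`` and ``add_one`` are available for users who want
    conservative ties or to avoid exact zeros.
    """
    null = np.asarray(null)
    if null.size == 0:
        raise ValidationError("null vector must be non-empty")
    if params.tie_rule == "strict_greater":
        count = int((null > observed).sum())
    else:
        count = int((null >= observed).sum())
    if params.smoothing == "add_one":
        return (count + 1) / (null.size + 1)
    return count / null.size


def hypergeom_tail(U_size: int, N1: int, N2: int, k: int) -> float:
    """Exact P(X > k) where X = |A n B| for uniform random subset pairs.

    X is hypergeometric: drawing N2 items from a universe of U_size of which
    N1 are 'marked'. Because the sharing fraction is strictly increasing in
    k, this equals the large-sample limit of the Monte Carlo p-value.
    """
    if not (0 <= k <= min(N1, N2) <= U_size) or max(N1, N2) > U_size:
        raise ValidationError(
            f"inconsistent sizes: U={U_size}, N1={N1}, N2={N2}, k={k}"
        )
    return float(hypergeom.sf(k, U_size, N1, N2))


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Pairwise table
# ---------------------------------------------------------------------------

def _pair_seed(master_seed: int, p1: str, p2: str) -> int:
    """Stable per-pair substream seed: adding pairs never perturbs others."""
    a, b = sorted((p1, p2))
    digest = hashlib.blake2b(
        f"{master_seed}|{a}|{b}".encode(), digest_size=4
    ).digest()
    return int.from_bytes(digest, "big") % (2**31)


def pairwise_table(
    sets: Sequence[BoundSet],
    U: PromoterUniverse,
    params: MCParams = MCParams(),
    keep_null: bool = False,
) -> list[ColocResult]:
    """One Monte Carlo colocalization result per unordered protein pair.

    Pairs are processed in lexicographic order of protein names, each with
    its own RNG substream derived from the master seed, and BH adjustment is
    applied across all pairs. Deterministic given the seed.
    """
    if len(sets) < 2:
        raise ValidationError("need at least 2 bound sets")
    names = [s.protein for s in sets]
    if len(set(names)) != len(names):
        raise ValidationError(f"protein names must be unique, got {names}")
    for s in sets:
        s.validate_in(U)
    by_name = {s.protein: s for s in sets}
    results: list[ColocResult] = []
    for p1, p2 in combinations(sorted(names), 2):
        A, B = by_name[p1], by_name[p2]
        k, fo = observed_stat(A, B)
        pair_params = MCParams(params.n_samples, _pair_seed(params.seed, p1, p2),
                               params.tie_rule, params.smoothing)
        fs = sample_null(U, A.size, B.size, pair_params)
        p_emp = empirical_p(fo, fs, pair_params)
        results.append(
            ColocResult(p1, p2, A.size, B.size, k, fo, p_emp, np.nan,
                        params.n_samples, pair_params.seed,
                        fs=fs if keep_null else None)
        )
    adj = bh_adjust([r.p_emp for r in results])
    for r, q in zip(results, adj):
        r.p_adj = float(q)
    return results


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_bound_sets_tsv(path: str | Path) -> list[BoundSet]:
    """TSV with columns (protein, gene_id); one row per bound promoter."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["protein", "gene_id"], header=None, dtype=str)
    if df.iloc[0].tolist() == ["protein", "gene_id"]:
        df = df.iloc[1:]
    return [
        BoundSet(protein, frozenset(sub["gene_id"]))
        for protein, sub in df.groupby("protein", sort=True)
    ]


def results_to_frame(results: Sequence[ColocResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(protein1=r.protein1, protein2=r.protein2, n1=r.n1, n2=r.n2,
                 k=r.k, fo=r.fo, p_emp=r.p_emp, p_adj=r.p_adj,
                 n_samples=r.n_samples, seed=r.seed)
            for r in results
        ]
    )


def write_results_tsv(results: Sequence[ColocResult], path: str | Path,
                      header: Optional[str] = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        results_to_frame(results).to_csv(fh, sep="\t", index=False)
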