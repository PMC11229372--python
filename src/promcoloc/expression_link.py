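"""Cross-tabulation of differential expression against binding categories,
plus qChIP percent-input normalization."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .interval_core import ValidationError

logger = logging.getLogger(__name__)

DEFAULT_FDR_THRESHOLD = 0.05


@dataclass(frozen=True)
class DERecord:
    """One gene's differential-expression call (log2 fold change + FDR)."""

    gene_id: str
    log2fc: float
    fdr: float
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD

    def __post_init__(self) -> None:
        if not (0 <= self.fdr <= 1):
            raise ValidationError(f"gene {self.gene_id}: FDR must be in [0, 1]")

    @property
    def significant(self) -> bool:
        return self.fdr < self.fdr_threshold


def read_de_table(path: str | Path,
                  fdr_threshold: float = DEFAULT_FDR_THRESHOLD) -> list[DERecord]:
    """TSV with columns gene_id, log2FC, FDR (header optional)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["gene_id", "log2fc", "fdr"], dtype=str)
    if df.iloc[0]["gene_id"].lower() in ("gene_id", "gene"):
        df = df.iloc[1:]
    return [
        DERecord(r.gene_id, float(r.log2fc), float(r.fdr), fdr_threshold)
        for r in df.itertuples(index=False)
    ]


def de_overlap_summary(
    de: Sequence[DERecord], categories: Mapping[str, str]
) -> pd.DataFrame:
    """Per-category DE summary (counts, DE proportion, mean log2FC by direction).

    ``categories`` maps gene ids to a stratum label (e.g. "promoter-bound,
    with motif, heterochromatin"). For each stratum the summary reports the
    number of genes, the number and proportion of significant genes, and the
    mean log2FC over down-regulated (log2fc < 0), up-regulated (log2fc > 0)
    and all significant genes. Empty strata get NaN means, not zeros; a
    significant gene with log2fc exactly 0 counts in "all DE" only.
    """
    ids = [r.gene_id for r in de]
    if len(set(ids)) != len(ids):
        dup = sorted({g for g in ids if ids.count(g) > 1})
        raise ValidationError(f"duplicate gene ids in DE table: {dup[:5]}")
    by_id = {r.gene_id: r for r in de}
    missing = sorted(set(categories) - set(by_id))
    if missing:
        raise ValidationError(
            f"categorized genes absent from the DE table: {missing[:5]}"
        )
    rows = []
    for cat in sorted(set(categories.values())):
        recs = [by_id[g] for g, c in categories.items() if c == cat]
        sig = [r for r in recs if r.significant]
        down = [r.log2fc for r in sig if r.log2fc < 0]
        up = [r.log2fc for r in sig if r.log2fc > 0]
        rows.append(
            dict(
                category=cat,
                n_genes=len(recs),
                n_de=len(sig),
                proportion_de=len(sig) / len(recs) if recs else np.nan,
                mean_lfc_down=float(np.mean(down)) if down else np.nan,
                mean_lfc_up=float(np.mean(up)) if up else np.nan,
                mean_lfc_de=float(np.mean([r.log2fc for r in sig])) if sig else np.nan,
            )
        )
    return pd.DataFrame(rows).set_index("category")


def normalize_qchip(pct_input_target: float, pct_input_reference: float) -> float:
    """ChIP enrichment as percent-input ratio to a positive control region."""
    if pct_input_target < 0 or pct_input_reference < 0:
        raise ValidationError("percent-input values must be non-negative")
    if pct_input_reference == 0:
        raise ZeroDivisionError(
            "reference percent-input is 0; cannot normalize against it"
        )
    return pct_input_target / pct_input_reference


def normalize_qchip_replicates(
    targets: Sequence[float], references: Sequence[float]
) -> tuple[float, float, np.ndarray]:
    """Per-replicate ratios with their mean and SD (ddof=1 when possible)."""
    if len(targets) != len(references):
        raise ValidationError("targets and references must align per replicate")
    ratios = np.array(
        [normalize_qchip(t, r) for t, r in zip(targets, references)]
    )
    sd = float(ratios.std(ddof=1)) if len(ratios) > 1 else np.nan
    return float(ratios.mean()), sd, ratios


def read_qchip_tsv(path: str | Path) -> pd.DataFrame:
    """TSV of (region, replicate, pct_input)."""
    return pd.read_csv(path, sep="\t", comment="#",
                       names=["region", "replicate", "pct_input"], header=0)


def write_summary_tsv(summary: pd.DataFrame, path: str | Path,
                      header: Optional[str] = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        summary.to_csv(fh, sep="\t")
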