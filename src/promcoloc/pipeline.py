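"""End-to-end orchestration: simulate -> annotate -> scan -> coloc -> de-link.

The pipeline is deterministic given a config and master seed; every output
table carries a header with the package version, a config hash, and the
seed. Individual stages are exposed as ``promcoloc`` subcommands; ``run-all``
executes the full chain.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import click
import numpy as np
import yaml

from . import __version__
from .annotation import (
    DM6_HETEROCHROMATIN,
    AnnotationParams,
    GeneModel,
    HeterochromatinMap,
    mark_housekeeping,
    peaks_to_promoter_genes,
    read_gtf,
    read_heterochromatin_bed,
    read_housekeeping_list,
    summarize_distribution,
    write_annotated_peaks,
    assign_feature,
    is_heterochromatic,
)
from .colocalization import (
    BoundSet,
    MCParams,
    PromoterUniverse,
    pairwise_table,
    read_bound_sets_tsv,
    write_results_tsv,
)
from .expression_link import de_overlap_summary, read_de_table, write_summary_tsv
from .interval_core import (
    PeakSet,
    ValidationError,
    combination_counts,
    merge_union,
    read_peaks,
    write_bed,
    write_combination_counts,
)
from .motif_scan import PWM, ScanParams, flag_motif_peaks, read_pwm_counts_tsv
from .synthetic_data import (
    SynthConfig,
    bound_sets_to_peaks,
    implant_motifs,
    make_bound_sets,
    make_de_table,
    make_gene_models,
    write_bound_sets_tsv,
    write_fasta,
    write_gtf,
    write_housekeeping_list,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Full pipeline configuration: either synthetic or file-based inputs."""

    outdir: Path
    seed: int = 0
    synth: Optional[SynthConfig] = None
    peak_paths: dict[str, str] = field(default_factory=dict)
    peak_format: str = "bed"
    gtf: Optional[str] = None
    housekeeping: Optional[str] = None
    fasta: Optional[str] = None
    pwm_paths: list[str] = field(default_factory=list)
    de_table: Optional[str] = None
    het_bed: Optional[str] = None
    use_dm6_het: bool = False
    annotation: AnnotationParams = field(default_factory=AnnotationParams)
    scan: ScanParams = field(default_factory=ScanParams)
    mc: MCParams = field(default_factory=MCParams)

    def validate(self) -> None:
        """Fail fast, before any stage runs."""
        synthetic = self.synth is not None
        real = bool(self.peak_paths)
        if synthetic == real:
            raise ValidationError(
                "exactly one of a synthetic config or real peak inputs is required"
            )
        if real:
            required = {"gtf": self.gtf, "housekeeping": self.housekeeping}
            for key, val in required.items():
                if not val:
                    raise ValidationError(f"real-input run requires --{key}")
            paths = [self.gtf, self.housekeeping, *self.peak_paths.values()]
            if self.pwm_paths:
                if not self.fasta:
                    raise ValidationError("motif scanning requires a FASTA genome")
                paths += [self.fasta, *self.pwm_paths]
            if self.de_table:
                paths.append(self.de_table)
            if self.het_bed:
                paths.append(self.het_bed)
            for p in paths:
                if p and not Path(p).exists():
                    raise ValidationError(f"input not found: {p}")

    def config_hash(self) -> str:
        payload = yaml.safe_dump(
            dict(
                seed=self.seed,
                synth=None if self.synth is None else _synth_to_dict(self.synth),
                peaks=self.peak_paths, gtf=self.gtf, housekeeping=self.housekeeping,
                fasta=self.fasta, pwms=self.pwm_paths, de_table=self.de_table,
                het_bed=self.het_bed, use_dm6_het=self.use_dm6_het,
                annotation=asdict(self.annotation),
                scan=asdict(self.scan),
                mc=dict(n_samples=self.mc.n_samples, tie_rule=self.mc.tie_rule,
                        smoothing=self.mc.smoothing),
            ),
            sort_keys=True,
        )
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    def header(self) -> str:
        return f"promcoloc v{__version__} | config={self.config_hash()} | seed={self.seed}"


def _synth_to_dict(s: SynthConfig) -> dict:
    d = dict(
        seed=s.seed, n_chroms=s.n_chroms, chrom_length=s.chrom_length,
        n_genes=s.n_genes, housekeeping_fraction=s.housekeeping_fraction,
        het_fraction=s.het_fraction,
        proteins=[list(p) for p in s.proteins],
        pairwise_theta={",".join(k): v for k, v in s.pairwise_theta.items()},
        peak_width=s.peak_width, summit_jitter=s.summit_jitter,
        implant_probability=s.implant_probability,
        motif="set" if s.motif is not None else None,
    )
    return d


def load_config(path: str | Path, seed: Optional[int] = None,
                outdir: Optional[str] = None) -> RunConfig:
    """Build a RunConfig from a YAML file, with optional CLI overrides."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg_seed = seed if seed is not None else int(raw.get("seed", 0))
    synth = None
    if "synthetic" in raw:
        s = dict(raw["synthetic"])
        motif_path = s.pop("motif_counts", None)
        proteins = s.pop("proteins", None)
        theta = s.pop("theta", {})
        synth = SynthConfig(
            seed=cfg_seed,
            proteins=tuple((k, float(v)) for k, v in proteins.items())
            if proteins else SynthConfig.proteins,
            pairwise_theta={tuple(k.split(",")): float(v) for k, v in theta.items()},
            **s,
        )
        if motif_path:
            synth.motif = read_pwm_counts_tsv(motif_path)
    inputs = raw.get("inputs", {})
    ann = AnnotationParams(**raw.get("annotation", {}))
    scan = ScanParams(**raw.get("scan", {}))
    mc_raw = dict(raw.get("mc", {}))
    mc_raw.pop("seed", None)
    mc = MCParams(seed=cfg_seed, **mc_raw)
    return RunConfig(
        outdir=Path(outdir or raw.get("outdir", "promcoloc_out")),
        seed=cfg_seed,
        synth=synth,
        peak_paths=dict(inputs.get("peaks", {})),
        peak_format=inputs.get("peak_format", "bed"),
        gtf=inputs.get("gtf"),
        housekeeping=inputs.get("housekeeping"),
        fasta=inputs.get("fasta"),
        pwm_paths=list(inputs.get("pwms", [])),
        de_table=inputs.get("de_table"),
        het_bed=inputs.get("het_bed"),
        use_dm6_het=bool(inputs.get("use_dm6_het", False)),
        annotation=ann, scan=scan, mc=mc,
    )


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _resolve_het_map(cfg: RunConfig,
                     synth_map: Optional[HeterochromatinMap]) -> HeterochromatinMap:
    if cfg.het_bed:
        return read_heterochromatin_bed(cfg.het_bed)
    if cfg.use_dm6_het:
        return DM6_HETEROCHROMATIN
    if synth_map is not None:
        return synth_map
    return HeterochromatinMap({})


def run_coloc_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages in order, persisting intermediate artifacts.

    Returns a dict of in-memory results (peak sets, annotation frames,
    colocalization results, DE summary). Identical config + seed produces a
    byte-identical output bundle.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = cfg.header()
    log_path = outdir / "run.log"
    log_lines = [header]

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    genome: Optional[dict[str, str]] = None
    pwms: list[PWM] = []
    synth_het = None

    if cfg.synth is not None:
        s = cfg.synth
        genes, synth_het = make_gene_models(s)
        bound_truth, truth = make_bound_sets(s, genes, synth_het)
        peak_sets = bound_sets_to_peaks(bound_truth, genes, s)
        log(f"simulated {len(genes)} genes, {len(truth.housekeeping)} housekeeping, "
            f"{len(peak_sets)} peak sets")
        if s.motif is not None:
            genome, seq_truth = implant_motifs(s, peak_sets)
            truth.implants = seq_truth.implants
            pwms = [s.motif]
            write_fasta(genome, outdir / "genome.fa")
        write_gtf(genes, outdir / "genes.gtf")
        write_housekeeping_list(genes, outdir / "housekeeping.tsv")
        for ps in peak_sets:
            write_bed(ps, outdir / f"peaks_{ps.label}.bed")
        write_bound_sets_tsv(bound_truth, outdir / "bound_truth.tsv", header=header)
        de_frame = make_de_table(s, genes, truth)
    else:
        genes = read_gtf(cfg.gtf)
        mark_housekeeping(genes, read_housekeeping_list(cfg.housekeeping))
        peak_sets = [
            read_peaks(path, cfg.peak_format, label=label)
            for label, path in sorted(cfg.peak_paths.items())
        ]
        log(f"loaded {len(genes)} genes and {len(peak_sets)} peak sets")
        if cfg.pwm_paths:
            from pyfaidx import Fasta

            genome = Fasta(cfg.fasta)
            pwms = [read_pwm_counts_tsv(p) for p in cfg.pwm_paths]
        de_frame = None
        truth = None

    het_map = _resolve_het_map(cfg, synth_het)
    log(f"annotation: anchor={cfg.annotation.anchor}, "
        f"halfwidth={cfg.annotation.promoter_halfwidth}; "
        f"mc: tie_rule={cfg.mc.tie_rule}, smoothing={cfg.mc.smoothing}, "
        f"n_samples={cfg.mc.n_samples}")

    # --- annotate + scan -------------------------------------------------
    flags_by_set: dict[str, list[bool]] = {}
    annotations = {}
    for ps in peak_sets:
        flags = (
            flag_motif_peaks(ps, genome, pwms, cfg.scan)
            if genome is not None and pwms else [False] * len(ps)
        )
        flags_by_set[ps.label] = flags
        annotations[ps.label] = write_annotated_peaks(
            ps, genes, het_map, outdir / f"annotated_{ps.label}.tsv",
            cfg.annotation, flags, header=header,
        )
    first = peak_sets[0]
    summary = summarize_distribution(first, genes, het_map, cfg.annotation,
                                     flags_by_set[first.label])
    write_summary_tsv(summary, outdir / "distribution_summary.tsv", header=header)

    # --- union / combination counts --------------------------------------
    merged = merge_union(peak_sets)
    write_combination_counts(combination_counts(merged),
                             outdir / "combination_counts.tsv", header=header)

    # --- colocalization ---------------------------------------------------
    hk_ids = sorted(g.gene_id for g in genes if g.housekeeping)
    universe = PromoterUniverse(tuple(hk_ids))
    bound_sets = [
        BoundSet(ps.label,
                 frozenset(peaks_to_promoter_genes(ps, genes, cfg.annotation,
                                                   housekeeping_only=True)))
        for ps in peak_sets
    ]
    coloc = (
        pairwise_table(bound_sets, universe, cfg.mc)
        if len(bound_sets) >= 2 else []
    )
    if coloc:
        write_results_tsv(coloc, outdir / "colocalization.tsv", header=header)
        log(f"colocalization: {len(coloc)} pairs over |U|={len(universe)}")

    # --- expression link --------------------------------------------------
    de_summary = None
    if cfg.de_table:
        de = read_de_table(cfg.de_table)
    elif de_frame is not None:
        de = [  # synthetic DE table generated above
            _de_record(r) for r in de_frame.itertuples(index=False)
        ]
        de_frame.to_csv(outdir / "de_table.tsv", sep="\t", index=False)
    else:
        de = None
    if de is not None:
        categories = _binding_categories(first, genes, het_map, cfg.annotation,
                                         flags_by_set[first.label])
        categories = {g: c for g, c in categories.items()
                      if g in {r.gene_id for r in de}}
        if categories:
            de_summary = de_overlap_summary(de, categories)
            write_summary_tsv(de_summary, outdir / "de_link_summary.tsv", header=header)

    log_path.write_text("\n".join(log_lines) + "\n")
    return dict(
        genes=genes, peak_sets=peak_sets, het_map=het_map, merged=merged,
        annotations=annotations, summary=summary, universe=universe,
        bound_sets=bound_sets, coloc=coloc, de_summary=de_summary,
        truth=truth,
    )


def _de_record(row):
    from .expression_link import DERecord

    return DERecord(row.gene_id, float(row.log2fc), float(row.fdr))


def _binding_categories(ps: PeakSet, genes: Sequence[GeneModel],
                        het_map: HeterochromatinMap, params: AnnotationParams,
                        flags: Sequence[bool]) -> dict[str, str]:
    """Map promoter-bound gene -> 'compartment,with/without_motif' stratum."""
    out: dict[str, str] = {}
    for peak, flag in zip(ps, flags):
        feature, gene_id = assign_feature(peak, genes, params)
        if feature != "promoter" or gene_id is None:
            continue
        compartment = ("heterochromatin"
                       if is_heterochromatic(peak, het_map, params.anchor)
                       else "euchromatin")
        motif = "with_motif" if flag else "without_motif"
        # a motif-bearing peak dominates if several peaks hit one promoter
        if gene_id not in out or "with_motif" in motif:
            out[gene_id] = f"{compartment},{motif}"
    return out


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

def _parse_peaks_opt(peaks: Sequence[str]) -> dict[str, str]:
    out = {}
    for item in peaks:
        if "=" not in item:
            raise click.BadParameter(f"--peaks expects label=path, got {item!r}")
        label, path = item.split("=", 1)
        out[label] = path
    return out


@click.group()
@click.version_option(__version__)
def main() -> None:
    """Promoter-centric peak annotation, motif scanning, and Monte Carlo
    colocalization testing."""
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")


@main.command("run-all")
@click.option("--config", "config_path", required=True, type=click.Path(exists=True))
@click.option("--seed", type=int, default=None, help="Master seed override.")
@click.option("--outdir", type=click.Path(), default=None)
def run_all_cmd(config_path: str, seed: Optional[int], outdir: Optional[str]) -> None:
    """Run the full pipeline from a YAML config."""
    cfg = load_config(config_path, seed=seed, outdir=outdir)
    try:
        run_coloc_pipeline(cfg)
    except ValidationError as exc:
        raise click.ClickException(str(exc))
    click.echo(f"done: {cfg.outdir}")


@main.command()
@click.option("--outdir", required=True, type=click.Path())
@click.option("--seed", type=int, default=0)
@click.option("--n-genes", type=int, default=1000)
@click.option("--n-chroms", type=int, default=2)
@click.option("--chrom-length", type=int, default=1_000_000)
@click.option("--hk-fraction", type=float, default=0.6)
@click.option("--protein", "proteins", multiple=True, default=("P1:0.1", "P2:0.1"),
              help="name:marginal, repeatable.")
@click.option("--theta", "thetas", multiple=True,
              help="ref,other:odds_ratio, repeatable.")
@click.option("--peak-width", type=int, default=200)
@click.option("--summit-jitter", type=int, default=0)
@click.option("--motif-counts", type=click.Path(exists=True), default=None,
              help="L x 4 count matrix TSV; enables sequence generation.")
def simulate(outdir, seed, n_genes, n_chroms, chrom_length, hk_fraction,
             proteins, thetas, peak_width, summit_jitter, motif_counts) -> None:
    """Generate a synthetic genome, gene models, and correlated peak sets."""
    prot = tuple((p.split(":")[0], float(p.split(":")[1])) for p in proteins)
    theta = {}
    for t in thetas:
        pair, val = t.split(":")
        theta[tuple(pair.split(","))] = float(val)
    synth = SynthConfig(seed=seed, n_chroms=n_chroms, chrom_length=chrom_length,
                        n_genes=n_genes, housekeeping_fraction=hk_fraction,
                        proteins=prot, pairwise_theta=theta,
                        peak_width=peak_width, summit_jitter=summit_jitter)
    if motif_counts:
        synth.motif = read_pwm_counts_tsv(motif_counts)
    cfg = RunConfig(outdir=Path(outdir), seed=seed, synth=synth,
                    mc=MCParams(seed=seed))
    run_coloc_pipeline(cfg)
    click.echo(f"done: {outdir}")


@main.command()
@click.option("--peaks", multiple=True, required=True, help="label=path, repeatable.")
@click.option("--format", "fmt", type=click.Choice(["bed", "narrowPeak"]), default="bed")
@click.option("--gtf", required=True, type=click.Path(exists=True))
@click.option("--housekeeping", required=True, type=click.Path(exists=True))
@click.option("--het-bed", type=click.Path(exists=True), default=None)
@click.option("--dm6-het", is_flag=True, help="Use the built-in dm6 map.")
@click.option("--promoter-halfwidth", type=int, default=200)
@click.option("--outdir", required=True, type=click.Path())
def annotate(peaks, fmt, gtf, housekeeping, het_bed, dm6_het,
             promoter_halfwidth, outdir) -> None:
    """Annotate peaks against TSS windows and the chromatin partition."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes = read_gtf(gtf)
    mark_housekeeping(genes, read_housekeeping_list(housekeeping))
    het = (read_heterochromatin_bed(het_bed) if het_bed
           else DM6_HETEROCHROMATIN if dm6_het else HeterochromatinMap({}))
    params = AnnotationParams(promoter_halfwidth=promoter_halfwidth)
    for label, path in sorted(_parse_peaks_opt(peaks).items()):
        ps = read_peaks(path, fmt, label=label)
        write_annotated_peaks(ps, genes, het, outdir / f"annotated_{label}.tsv", params)
    click.echo(f"done: {outdir}")


@main.command()
@click.option("--fasta", required=True, type=click.Path(exists=True))
@click.option("--pwm", "pwm_paths", multiple=True, required=True,
              type=click.Path(exists=True), help="L x 4 count TSV, repeatable.")
@click.option("--peaks", multiple=True, required=True, help="label=path, repeatable.")
@click.option("--format", "fmt", type=click.Choice(["bed", "narrowPeak"]), default="bed")
@click.option("--p-threshold", type=float, default=1e-4)
@click.option("--outdir", required=True, type=click.Path())
def scan(fasta, pwm_paths, peaks, fmt, p_threshold, outdir) -> None:
    """Flag peaks containing a motif site at the given p-value threshold."""
    from pyfaidx import Fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = Fasta(fasta)
    pwms = [read_pwm_counts_tsv(p) for p in pwm_paths]
    params = ScanParams(p_threshold=p_threshold)
    for label, path in sorted(_parse_peaks_opt(peaks).items()):
        ps = read_peaks(path, fmt, label=label)
        flags = flag_motif_peaks(ps, genome, pwms, params)
        with open(outdir / f"motif_flags_{label}.tsv", "w") as fh:
            fh.write("peak\thas_motif\n")
            for peak, flag in zip(ps, flags):
                fh.write(f"{peak.name}\t{flag}\n")
    click.echo(f"done: {outdir}")


@main.command()
@click.option("--bound-sets", required=True, type=click.Path(exists=True),
              help="TSV (protein, gene_id).")
@click.option("--universe", required=True, type=click.Path(exists=True),
              help="Housekeeping promoter ids, one per line.")
@click.option("--n-samples", type=int, default=5000)
@click.option("--seed", type=int, default=0)
@click.option("--out", required=True, type=click.Path())
def coloc(bound_sets, universe, n_samples, seed, out) -> None:
    """Monte Carlo colocalization test over all protein pairs."""
    sets = read_bound_sets_tsv(bound_sets)
    uni = PromoterUniverse.from_ids(sorted(read_housekeeping_list(universe)))
    results = pairwise_table(sets, uni, MCParams(n_samples=n_samples, seed=seed))
    write_results_tsv(results, out, header=f"promcoloc v{__version__} | seed={seed}")
    click.echo(f"done: {out}")


@main.command("de-link")
@click.option("--de-table", required=True, type=click.Path(exists=True))
@click.option("--categories", required=True, type=click.Path(exists=True),
              help="TSV (gene_id, category).")
@click.option("--out", required=True, type=click.Path())
def de_link(de_table, categories, out) -> None:
    """Cross-tabulate differential expression against binding categories."""
    import pandas as pd

    de = read_de_table(de_table)
    cat_df = pd.read_csv(categories, sep="\t", comment="#", header=None,
                         names=["gene_id", "category"], dtype=str)
    if cat_df.iloc[0]["gene_id"] == "gene_id":
        cat_df = cat_df.iloc[1:]
    summary = de_overlap_summary(de, dict(zip(cat_df.gene_id, cat_df.category)))
    write_summary_tsv(summary, out, header=f"promcoloc v{__version__}")
    click.echo(f"done: {out}")


if __name__ == "__main__":
    main()
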