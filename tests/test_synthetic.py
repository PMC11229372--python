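"""Synthetic-data generator: determinism, marginal/odds-ratio control, and
exact recovery of ground truth through the annotation stage."""

import numpy as np
import pytest

from promcoloc import (
    AnnotationParams,
    SynthConfig,
    ValidationError,
    bound_sets_to_peaks,
    empirical_odds_ratio,
    implant_motifs,
    is_heterochromatic,
    joint_success_probability,
    make_bound_sets,
    make_gene_models,
    peaks_to_promoter_genes,
    pwm_from_counts,
    scan_sequence,
    score_pvalue_threshold,
)
from promcoloc.interval_core import GenomicInterval
from promcoloc.motif_scan import ALPHABET
from promcoloc.synthetic_data import (
    gene_compartments,
    make_de_table,
    reverse_complement,
)


def small_cfg(**kw):
    defaults = dict(seed=11, n_chroms=2, chrom_length=200_000, n_genes=100,
                    housekeeping_fraction=0.5)
    defaults.update(kw)
    return SynthConfig(**defaults)


class TestJointSuccessProbability:
    def test_independence(self):
        assert joint_success_probability(0.5, 0.5, 1.0) == pytest.approx(0.25)

    def test_odds_ratio_nine_closed_form(self):
        # with p1=p2=0.5 symmetry forces p00=p11: p11^2 = 9 (0.5-p11)^2
        assert joint_success_probability(0.5, 0.5, 9.0) == pytest.approx(0.375)

    def test_recovers_requested_odds_ratio(self):
        for p1, p2, theta in [(0.1, 0.3, 4.0), (0.2, 0.2, 0.5), (0.4, 0.1, 8.0)]:
            p11 = joint_success_probability(p1, p2, theta)
            p10, p01 = p1 - p11, p2 - p11
            p00 = 1 - p1 - p2 + p11
            assert (p11 * p00) / (p10 * p01) == pytest.approx(theta)

    def test_frechet_bounds_respected(self):
        for theta in (0.1, 1.0, 50.0):
            p11 = joint_success_probability(0.7, 0.8, theta)
            assert max(0, 0.7 + 0.8 - 1) <= p11 <= 0.7

    def test_invalid_theta_rejected(self):
        with pytest.raises(ValidationError):
            joint_success_probability(0.5, 0.5, 0.0)


class TestMakeGeneModels:
    def test_exact_housekeeping_count(self):
        genes, _ = make_gene_models(small_cfg(housekeeping_fraction=0.5))
        assert sum(g.housekeeping for g in genes) == 50

    def test_deterministic_given_seed(self):
        a, _ = make_gene_models(small_cfg())
        b, _ = make_gene_models(small_cfg())
        assert [(g.gene_id, g.tss, g.strand, g.housekeeping) for g in a] == \
               [(g.gene_id, g.tss, g.strand, g.housekeeping) for g in b]

    def test_gene_spans_do_not_overlap(self):
        genes, _ = make_gene_models(small_cfg())
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append((g.span_start, g.span_end))
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2

    def test_infeasible_density_rejected(self):
        with pytest.raises(ValidationError):
            make_gene_models(small_cfg(n_genes=100_000))

    def test_compartments_match_heterochromatin_map(self):
        genes, het = make_gene_models(small_cfg())
        comp = gene_compartments(genes, het)
        for g in genes:
            tss_point = GenomicInterval(g.chrom, g.tss, g.tss + 1, name=g.gene_id)
            expected = ("heterochromatin"
                        if is_heterochromatic(tss_point, het, "midpoint")
                        else "euchromatin")
            assert comp[g.gene_id] == expected
        assert any(c == "heterochromatin" for c in comp.values())
        assert any(c == "euchromatin" for c in comp.values())


class TestMakeBoundSets:
    def test_marginals_within_binomial_interval(self):
        cfg = small_cfg(n_genes=6000, chrom_length=12_000_000,
                        housekeeping_fraction=1.0,
                        proteins=(("P1", 0.2), ("P2", 0.1)))
        genes, _ = make_gene_models(cfg)
        bound, _ = make_bound_sets(cfg, genes)
        for bs, p in zip(bound, (0.2, 0.1)):
            # 99% binomial interval around p at n=6000
            half = 2.576 * np.sqrt(p * (1 - p) / 6000)
            assert abs(bs.size / 6000 - p) <= half

    def test_independent_pair_has_odds_ratio_near_one(self):
        cfg = small_cfg(n_genes=10_000, chrom_length=20_000_000,
                        housekeeping_fraction=1.0,
                        proteins=(("P1", 0.3), ("P2", 0.3)))
        genes, _ = make_gene_models(cfg)
        _, truth = make_bound_sets(cfg, genes)
        # 99% CI for log OR: +/- 2.576 * sqrt(sum of 1/cell-counts) ~ 0.2
        assert abs(np.log(truth.realized_theta[("P1", "P2")])) < 0.25

    def test_theta_shifts_realized_odds_ratio(self):
        cfg = small_cfg(n_genes=10_000, chrom_length=20_000_000,
                        housekeeping_fraction=1.0,
                        proteins=(("P1", 0.2), ("P2", 0.2)),
                        pairwise_theta={("P1", "P2"): 4.0})
        genes, _ = make_gene_models(cfg)
        _, truth = make_bound_sets(cfg, genes)
        assert truth.realized_theta[("P1", "P2")] == pytest.approx(4.0, rel=0.25)

    def test_bound_sets_restricted_to_housekeeping(self):
        cfg = small_cfg(housekeeping_fraction=0.3)
        genes, _ = make_gene_models(cfg)
        bound, truth = make_bound_sets(cfg, genes)
        hk = {g.gene_id for g in genes if g.housekeeping}
        for bs in bound:
            assert bs.genes <= hk
            assert truth.bound[bs.protein] == bs.genes

    def test_non_reference_theta_key_rejected(self):
        cfg = small_cfg(proteins=(("P1", 0.1), ("P2", 0.1), ("P3", 0.1)),
                        pairwise_theta={("P2", "P3"): 2.0})
        genes, _ = make_gene_models(cfg)
        with pytest.raises(ValidationError):
            make_bound_sets(cfg, genes)


class TestPeaksAndRecovery:
    def test_round_trip_recovery_without_jitter(self):
        cfg = small_cfg(summit_jitter=0)
        genes, _ = make_gene_models(cfg)
        bound, truth = make_bound_sets(cfg, genes)
        peak_sets = bound_sets_to_peaks(bound, genes, cfg)
        for ps in peak_sets:
            recovered = peaks_to_promoter_genes(ps, genes, AnnotationParams(),
                                                housekeeping_only=True)
            assert recovered == set(truth.bound[ps.label])

    def test_round_trip_recovery_with_safe_jitter(self):
        cfg = small_cfg(summit_jitter=50, peak_width=200)
        genes, _ = make_gene_models(cfg)
        bound, truth = make_bound_sets(cfg, genes)
        for ps in bound_sets_to_peaks(bound, genes, cfg):
            recovered = peaks_to_promoter_genes(ps, genes, AnnotationParams(),
                                                housekeeping_only=True)
            assert recovered == set(truth.bound[ps.label])

    def test_empty_bound_set_gives_empty_peakset(self):
        cfg = small_cfg(proteins=(("P1", 0.0),))
        genes, _ = make_gene_models(cfg)
        bound, _ = make_bound_sets(cfg, genes)
        [ps] = bound_sets_to_peaks(bound, genes, cfg)
        assert len(ps) == 0

    def test_shared_gene_produces_one_region_with_both_labels(self):
        from promcoloc import merge_union

        cfg = small_cfg(proteins=(("P1", 1.0), ("P2", 1.0)))
        genes, _ = make_gene_models(cfg)
        bound, _ = make_bound_sets(cfg, genes)
        peak_sets = bound_sets_to_peaks(bound, genes, cfg)
        merged = merge_union(peak_sets)
        n_hk = sum(g.housekeeping for g in genes)
        assert len(merged) == n_hk
        assert all(mem == frozenset({"P1", "P2"}) for mem in merged.membership)


class TestImplantMotifs:
    def motif(self):
        counts = np.zeros((8, 4))
        for i, c in enumerate("ACGTACGT"):
            counts[i, ALPHABET.index(c)] = 30
        return pwm_from_counts(counts, pseudocount=1.0)

    def test_probability_one_implants_every_peak(self):
        cfg = small_cfg(motif=self.motif(), implant_probability=1.0)
        genes, _ = make_gene_models(cfg)
        bound, _ = make_bound_sets(cfg, genes)
        peak_sets = bound_sets_to_peaks(bound, genes, cfg)
        seqs, truth = implant_motifs(cfg, peak_sets)
        all_names = {p.name for ps in peak_sets for p in ps}
        assert set(truth.implants) == all_names

    def test_probability_zero_implants_nothing(self):
        cfg = small_cfg(motif=self.motif(), implant_probability=0.0)
        genes, _ = make_gene_models(cfg)
        bound, _ = make_bound_sets(cfg, genes)
        peak_sets = bound_sets_to_peaks(bound, genes, cfg)
        _, truth = implant_motifs(cfg, peak_sets)
        assert truth.implants == {}

    def test_scanning_recovers_passing_implants(self):
        """Every implant whose sampled word passes the threshold is found at
        its recorded position and strand."""
        cfg = small_cfg(motif=self.motif(), implant_probability=1.0,
                        proteins=(("P1", 0.5), ("P2", 0.5)))
        genes, _ = make_gene_models(cfg)
        bound, _ = make_bound_sets(cfg, genes)
        peak_sets = bound_sets_to_peaks(bound, genes, cfg)
        seqs, truth = implant_motifs(cfg, peak_sets)
        pwm = cfg.motif
        t = score_pvalue_threshold(pwm, 1e-4)
        checked = 0
        for ps in peak_sets:
            for peak in ps:
                if peak.name not in truth.implants:
                    continue
                pos, strand, word = truth.implants[peak.name]
                word_hits = scan_sequence(pwm, word, t, both_strands=False)
                if not word_hits:  # sampled word itself below threshold
                    continue
                inserted = word if strand == "+" else reverse_complement(word)
                if seqs[peak.chrom][pos:pos + pwm.length] != inserted:
                    continue  # overwritten by a later implant in an overlapping peak
                seq = seqs[peak.chrom][peak.start:peak.end]
                hits = {(peak.start + h[0], h[1])
                        for h in scan_sequence(pwm, seq, t)}
                assert (pos, strand) in hits
                checked += 1
        assert checked > 10

    def test_deterministic_sequences(self):
        cfg = small_cfg(motif=self.motif())
        genes, _ = make_gene_models(cfg)
        bound, _ = make_bound_sets(cfg, genes)
        peak_sets = bound_sets_to_peaks(bound, genes, cfg)
        s1, t1 = implant_motifs(cfg, peak_sets)
        s2, t2 = implant_motifs(cfg, peak_sets)
        assert s1 == s2 and t1.implants == t2.implants


def test_de_table_plants_effects_in_bound_genes():
    cfg = small_cfg()
    genes, _ = make_gene_models(cfg)
    bound, truth = make_bound_sets(cfg, genes)
    df = make_de_table(cfg, genes, truth, effect_probability=1.0)
    assert set(df.gene_id) == {g.gene_id for g in genes}
    ref_bound = truth.bound["P1"]
    sig = df[df.fdr < 0.05]
    assert set(sig.gene_id) == set(ref_bound)
    assert sig.log2fc.mean() < -0.5
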