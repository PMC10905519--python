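import numpy as np
import pytest

from lncguide.design_engine import (
    CRISPRI_LOCATION,
    DEFAULT_WEIGHTS,
    GENE_BODY_THIRD_FACTORS,
    GuidePair,
    composite_score,
    design_paired_crispko,
    design_single_crispri,
    location_score,
    write_design_bed,
    write_design_tsv,
)
from lncguide.genome_io import GeneModel, GenomeSequence
from lncguide.target_scan import CandidateGuide


def _cand(cut, context="gene_body", strand="+"):
    return CandidateGuide("A" * 20, "AGG", "chr1", max(cut - 17, 0), strand, cut,
                          context)


class TestLocationScore:
    def test_crispri_table_lookup(self):
        for ctx, expect in CRISPRI_LOCATION.items():
            assert location_score(_cand(10, ctx), "CRISPRi") == expect

    def test_crispko_thirds_plus_strand(self):
        gene = GeneModel("g", "chr1", 0, 3000, "+")
        assert location_score(_cand(100), "CRISPRko", gene) == GENE_BODY_THIRD_FACTORS[0]
        assert location_score(_cand(1500), "CRISPRko", gene) == GENE_BODY_THIRD_FACTORS[1]
        assert location_score(_cand(2900), "CRISPRko", gene) == GENE_BODY_THIRD_FACTORS[2]

    def test_crispko_thirds_mirror_on_minus_strand(self):
        plus = GeneModel("g", "chr1", 0, 3000, "+")
        minus = GeneModel("g", "chr1", 0, 3000, "-")
        # a cut near the genomic start is 5' on + but 3' on -
        assert location_score(_cand(100), "CRISPRko", plus) == GENE_BODY_THIRD_FACTORS[0]
        assert location_score(_cand(100), "CRISPRko", minus) == GENE_BODY_THIRD_FACTORS[2]

    def test_crispko_non_body_contexts(self):
        gene = GeneModel("g", "chr1", 0, 3000, "+")
        assert location_score(_cand(10, "promoter"), "CRISPRko", gene) == 0.3
        assert location_score(_cand(10, "intergenic"), "CRISPRko", gene) == 0.1

    def test_unknown_mechanism_rejected(self):
        with pytest.raises(ValueError):
            location_score(_cand(10), "CRISPRx")


class TestCompositeScore:
    def test_extremes(self):
        assert composite_score(1.0, 1.0, 1.0) == 1.0
        assert composite_score(0.0, 0.0, 0.0) == -1.0

    def test_hand_arithmetic_midpoint(self):
        # 2*(0.5*0.8 + 0.3*0.5 + 0.2*0.25) - 1 = 2*0.6 - 1 = 0.2
        assert composite_score(0.8, 0.5, 0.25) == pytest.approx(0.2)

    def test_range_fuzz(self, rng):
        for _ in range(500):
            s = composite_score(*rng.random(3))
            assert -1.0 <= s <= 1.0

    def test_monotone_in_each_argument(self, rng):
        for _ in range(100):
            a, b, c = rng.random(3) * 0.5
            base = composite_score(a, b, c)
            assert composite_score(a + 0.1, b, c) > base
            assert composite_score(a, b + 0.1, c) > base
            assert composite_score(a, b, c + 0.1) > base

    def test_inputs_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="p_on"):
            composite_score(1.2, 0.5, 0.5)
        with pytest.raises(ValueError, match="specificity"):
            composite_score(0.5, -0.1, 0.5)

    def test_bad_weights_rejected(self):
        with pytest.raises(ValueError, match="weights"):
            composite_score(0.5, 0.5, 0.5, weights=(0.5, 0.5, 0.5))

    def test_default_weights_sum_to_one(self):
        assert sum(DEFAULT_WEIGHTS) == pytest.approx(1.0)


class TestGuidePairValidation:
    def test_nonpositive_deletion_rejected(self):
        with pytest.raises(ValueError):
            GuidePair(None, None, 0, 0.0)


class TestCRISPRiDesign:
    def test_designs_in_promoter_and_sorted(self, toy_gene_setup, toy_models):
        genome, genes = toy_gene_setup
        model = toy_models["CRISPRi"]
        res = design_single_crispri(genes[0], genome, model, top_n=10,
                                    check_offtargets=False)
        assert res.mechanism == "CRISPRi"
        assert 0 < len(res.entries) <= 10
        comps = [sg.composite for sg in res.entries]
        assert comps == sorted(comps, reverse=True)
        for sg in res.entries:
            assert sg.candidate.context in CRISPRI_LOCATION
            assert -1 <= sg.composite <= 1
            assert sg.specificity == 1.0  # off-target check disabled

    def test_mechanism_mismatch_rejected(self, toy_gene_setup, toy_models):
        genome, genes = toy_gene_setup
        with pytest.raises(ValueError, match="CRISPRi"):
            design_single_crispri(genes[0], genome, toy_models["CRISPRko"])

    def test_empty_promoter_reports_diagnostic(self, toy_models):
        # PAM-free genome: scan finds nothing, design must not crash
        genome = GenomeSequence("c", "AT" * 3000)
        gene = GeneModel("g", "c", 2000, 4000, "+")
        res = design_single_crispri(gene, genome, toy_models["CRISPRi"],
                                    check_offtargets=False)
        assert res.entries == []
        assert any("no PAM candidates" in d for d in res.diagnostics)

    def test_composite_consistent_with_parts(self, toy_gene_setup, toy_models):
        genome, genes = toy_gene_setup
        res = design_single_crispri(genes[0], genome, toy_models["CRISPRi"],
                                    top_n=5, check_offtargets=False)
        for sg in res.entries:
            assert sg.composite == pytest.approx(
                composite_score(sg.p_on, sg.specificity, sg.location)
            )


class TestCRISPRkoDesign:
    def test_pairs_respect_deletion_window(self, toy_gene_setup, toy_models):
        genome, genes = toy_gene_setup
        res = design_paired_crispko(genes[0], genome, toy_models["CRISPRko"],
                                    top_n=15, check_offtargets=False)
        assert res.entries, res.diagnostics
        for p in res.entries:
            assert 50 <= p.deletion_size <= 2000
            assert p.left.candidate.cut_site < p.right.candidate.cut_site
            assert p.left.candidate.context == "gene_body"
            assert p.right.candidate.context == "gene_body"
        scores = [p.pair_composite for p in res.entries]
        assert scores == sorted(scores, reverse=True)

    def test_deletion_size_equals_cut_distance(self, toy_gene_setup, toy_models):
        genome, genes = toy_gene_setup
        res = design_paired_crispko(genes[1], genome, toy_models["CRISPRko"],
                                    top_n=5, check_offtargets=False)
        for p in res.entries:
            assert p.deletion_size == (
                p.right.candidate.cut_site - p.left.candidate.cut_site
            )

    def test_band_penalty_formula(self, toy_gene_setup, toy_models):
        genome, genes = toy_gene_setup
        res = design_paired_crispko(genes[0], genome, toy_models["CRISPRko"],
                                    top_n=50, check_offtargets=False)
        for p in res.entries:
            d = p.deletion_size
            penalty = 0.0
            if d < 200:
                penalty = 5e-4 * (200 - d)
            elif d > 1000:
                penalty = 5e-4 * (d - 1000)
            expect = (p.left.composite + p.right.composite) / 2 - penalty
            assert p.pair_composite == pytest.approx(expect)

    def test_in_band_pair_outranks_same_quality_out_of_band(self, toy_gene_setup,
                                                            toy_models):
        genome, genes = toy_gene_setup
        res = design_paired_crispko(genes[0], genome, toy_models["CRISPRko"],
                                    top_n=200, check_offtargets=False)
        in_band = [p for p in res.entries if 200 <= p.deletion_size <= 1000]
        out_band = [p for p in res.entries if not 200 <= p.deletion_size <= 1000]
        if in_band and out_band:
            # among pairs with equal mean composite, in-band scores higher
            for pi in in_band[:5]:
                mean_i = (pi.left.composite + pi.right.composite) / 2
                for po in out_band[:20]:
                    mean_o = (po.left.composite + po.right.composite) / 2
                    if abs(mean_i - mean_o) < 1e-12:
                        assert pi.pair_composite > po.pair_composite

    def test_impossible_window_gives_diagnostic_and_singletons(
        self, toy_gene_setup, toy_models
    ):
        genome, genes = toy_gene_setup
        res = design_paired_crispko(genes[0], genome, toy_models["CRISPRko"],
                                    min_del=1990, max_del=1991,
                                    check_offtargets=False)
        if not res.entries:
            assert any("no valid pair" in d for d in res.diagnostics)
            assert "singletons" in res.parameters

    def test_mechanism_mismatch_rejected(self, toy_gene_setup, toy_models):
        genome, genes = toy_gene_setup
        with pytest.raises(ValueError, match="CRISPRko"):
            design_paired_crispko(genes[0], genome, toy_models["CRISPRi"])

    def test_determinism(self, toy_gene_setup, toy_models):
        genome, genes = toy_gene_setup
        a = design_paired_crispko(genes[0], genome, toy_models["CRISPRko"],
                                  top_n=10, check_offtargets=False)
        b = design_paired_crispko(genes[0], genome, toy_models["CRISPRko"],
                                  top_n=10, check_offtargets=False)
        assert [(p.left.candidate.start, p.right.candidate.start, p.pair_composite)
                for p in a.entries] == \
               [(p.left.candidate.start, p.right.candidate.start, p.pair_composite)
                for p in b.entries]


class TestWriters:
    def test_tsv_and_bed_row_counts(self, toy_gene_setup, toy_models, tmp_path):
        genome, genes = toy_gene_setup
        res = design_paired_crispko(genes[0], genome, toy_models["CRISPRko"],
                                    top_n=7, check_offtargets=False)
        tsv, bed = tmp_path / "d.tsv", tmp_path / "d.bed"
        write_design_tsv(res, tsv)
        write_design_bed(res, bed)
        assert len(tsv.read_text().splitlines()) == len(res.entries) + 1
        bed_lines = bed.read_text().splitlines()
        assert len(bed_lines) == len(res.entries)
        for line, p in zip(bed_lines, res.entries):
            chrom, lo, hi = line.split("\t")[:3]
            assert int(hi) - int(lo) >= p.deletion_size
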