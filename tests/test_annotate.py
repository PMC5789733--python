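"""Genic context, protein-site flanks, regulatory flags and summary tiers."""

import numpy as np
import pytest

from regcircuits.annotate import (
    FunctionalAnnotation,
    annotate_protein_sites,
    annotate_regulatory,
    classify_genic_context,
    index_eqtls,
    index_protein_sites,
    summarize_annotations,
)
from regcircuits.intervals import GenomePosition, GenomicInterval, build_index
from regcircuits.io import CodingVariant, EqtlRecord, ProteinSite, SnpRecord


def snp(pos, snp_id="rs1", chrom="chr1", p=0.01):
    return SnpRecord(snp_id, GenomePosition(chrom, pos), "t", p)


def iv(start, end, fid, kind, chrom="chr1", attrs=None):
    return GenomicInterval(chrom, start, end, ".", fid, kind, attrs or {})


@pytest.fixture
def gene_model():
    genes = build_index([iv(1000, 3000, "G1", "gene")])
    exons = build_index([iv(1000, 1200, "G1.e1", "exon"), iv(2500, 2700, "G1.e2", "exon")])
    return genes, exons


class TestGenicContext:
    def test_exonic_intronic_intergenic(self, gene_model):
        genes, exons = gene_model
        assert classify_genic_context(snp(1100), genes, exons) == "exonic"
        assert classify_genic_context(snp(2000), genes, exons) == "intronic"
        assert classify_genic_context(snp(5000), genes, exons) == "intergenic"

    def test_empty_model_intergenic(self):
        empty = build_index([])
        assert classify_genic_context(snp(100, chrom="chr9"), empty, empty) == "intergenic"


class TestProteinSites:
    def test_phosphosite_exact_match(self):
        # a variant directly at a phosphosite residue (e.g. Q576R on a 576 site)
        sites = index_protein_sites([ProteinSite("IL4R", 576, "phosphorylation")])
        v = CodingVariant("rs1801275", "IL4R", 576, "Q576R")
        assert annotate_protein_sites(v, sites) == (False, True)

    @pytest.mark.parametrize(
        "residue,expect_ligand", [(141, True), (137, True), (142, False), (136, False)]
    )
    def test_ligand_two_residue_flank_boundary(self, residue, expect_ligand):
        sites = index_protein_sites([ProteinSite("P1", 139, "ligand_binding")])
        v = CodingVariant("rs1", "P1", residue)
        assert annotate_protein_sites(v, sites)[0] is expect_ligand

    @pytest.mark.parametrize("residue,expect", [(146, True), (147, False)])
    def test_phospho_seven_residue_flank_boundary(self, residue, expect):
        sites = index_protein_sites([ProteinSite("P1", 139, "phosphorylation")])
        assert annotate_protein_sites(CodingVariant("rs1", "P1", residue), sites)[1] is expect

    def test_absent_protein_both_false(self):
        assert annotate_protein_sites(CodingVariant("rs1", "PX", 5), {}) == (False, False)


class TestRegulatory:
    @pytest.fixture
    def toy(self):
        motifs = build_index([iv(100, 112, "A|1", "motif", attrs={"tf": "A"})])
        elements = build_index(
            [iv(90, 400, "E1", "enhancer"), iv(1000, 1300, "P1", "promoter")]
        )
        return motifs, elements

    def test_motif_and_enhancer_no_eqtl(self, toy):
        motifs, elements = toy
        a = annotate_regulatory(snp(105), motifs, elements, {})
        assert (a.motif, a.promoter_enhancer, a.eqtl) == (True, True, False)
        assert a.n_regulatory_categories == 2
        assert a.support["motif"] == ("A",)
        assert a.support["promoter_enhancer"] == ("E1",)

    def test_eqtl_fdr_boundary_inclusive(self, toy):
        motifs, elements = toy
        eq = index_eqtls([EqtlRecord("rs1", "G1", "lung", 0.05)])
        assert annotate_regulatory(snp(5000), motifs, elements, eq).eqtl is True
        eq2 = index_eqtls([EqtlRecord("rs1", "G1", "lung", 0.0500001)])
        assert annotate_regulatory(snp(5000), motifs, elements, eq2).eqtl is False

    def test_no_overlap_all_false(self, toy):
        motifs, elements = toy
        a = annotate_regulatory(snp(50_000), motifs, elements, {})
        assert a.n_regulatory_categories == 0 and a.support == {}

    def test_flag_requires_support(self):
        with pytest.raises(ValueError, match="without support"):
            FunctionalAnnotation("rs1", motif=True)


class TestSummary:
    def make(self, snp_id, flags, ctx="intergenic"):
        support = {f: (f"s_{f}",) for f in flags}
        return FunctionalAnnotation(
            snp_id, genic_context=ctx,
            motif="motif" in flags, promoter_enhancer="promoter_enhancer" in flags,
            eqtl="eqtl" in flags, support=support,
        )

    def test_tier_counts(self):
        anns = [
            self.make("a", ["motif", "eqtl"]),
            self.make("b", ["promoter_enhancer"]),
            self.make("c", []),
        ]
        s = summarize_annotations(anns)
        assert (s.at_least_1, s.more_than_1, s.all3) == (2, 1, 0)
        assert s.denominator == 3

    def test_all_three_everywhere(self):
        anns = [self.make(f"x{i}", ["motif", "promoter_enhancer", "eqtl"]) for i in range(4)]
        s = summarize_annotations(anns)
        assert s.all3 == 4 == s.denominator

    def test_noncoding_denominator_excludes_exonic(self):
        anns = [self.make("a", ["motif"], ctx="exonic"), self.make("b", ["motif"])]
        s = summarize_annotations(anns, "noncoding")
        assert s.denominator == 1 and s.totals["motif"] == 1

    def test_tier_ordering_invariant(self):
        rng = np.random.default_rng(0)
        anns = []
        for i in range(300):
            flags = [f for f in ("motif", "promoter_enhancer", "eqtl") if rng.random() < 0.4]
            anns.append(self.make(f"r{i}", flags))
        s = summarize_annotations(anns)
        assert s.all3 <= s.more_than_1 <= s.at_least_1 <= s.denominator

    def test_empty_input_all_zero(self):
        s = summarize_annotations([])
        assert s.denominator == 0 and s.at_least_1 == 0 and s.proportion("motif") == 0.0


class TestPlantedProportions:
    def test_observed_proportions_match_planted(self):
        """Category proportions on simulated data converge to the planted
        placement probabilities (99% binomial CI at n = 5,000)."""
        from regcircuits.annotate import annotate_catalog
        from regcircuits.simulate import (
            SimulationConfig, generate_catalogs, generate_genome_tracks,
        )
        from regcircuits.intervals import build_index
        from regcircuits.annotate import index_eqtls

        cfg = SimulationConfig(seed=11, n_catalog_snps=5000, n_background_snvs=0)
        tracks = generate_genome_tracks(cfg)
        sim = generate_catalogs(cfg, tracks)
        anns = annotate_catalog(
            sim.catalog,
            build_index(tracks.genes), build_index(tracks.exons),
            build_index(tracks.motifs),
            build_index(tracks.promoters + tracks.enhancers),
            index_eqtls(sim.eqtls),
        )
        n = len(anns)
        for cat, planted in cfg.catalog_probs.items():
            observed = sum(a.flag(cat) for a in anns.values()) / n
            half = 2.576 * np.sqrt(planted * (1 - planted) / n)
            assert abs(observed - planted) < half, (cat, observed, planted)
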