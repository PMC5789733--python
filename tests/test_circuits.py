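"""Promoter-flank hit rules, circuit construction, nearest-gene baseline,
disease-gene enrichment and BH thresholding."""

import numpy as np
import pytest

from regcircuits.circuits import (
    build_perturbed_circuit,
    disease_gene_enrichment,
    map_snps_to_elements,
    nearest_gene_set,
    threshold_novel_associations,
)
from regcircuits.intervals import GenomePosition, GenomicInterval, build_index
from regcircuits.io import NetworkEdgeRow, SnpRecord


def snp(pos, snp_id="rs1", chrom="chr1", p=0.01):
    return SnpRecord(snp_id, GenomePosition(chrom, pos), "t", p)


def promoter(start, end, strand="+", fid="P1"):
    return GenomicInterval("chr1", start, end, strand, fid, "promoter")


def enhancer(start, end, fid="E1"):
    return GenomicInterval("chr1", start, end, ".", fid, "enhancer")


def hits_for(pos1, prom=None, enh=None):
    pi = build_index([prom] if prom else [])
    ei = build_index([enh] if enh else [])
    return map_snps_to_elements([snp(pos1)], pi, ei)


class TestPromoterWindows:
    """Promoter [1000, 1500) 0-based: body plus a 400-bp upstream and a
    50-bp downstream window, closed on the outer boundary."""

    @pytest.mark.parametrize(
        "pos1,rule",
        [
            (601, "promoter_flank"),   # exactly 400 bp upstream of the 5' end
            (600, None),               # 401 bp upstream: outside
            (1001, "promoter_body"),   # first body base
            (1500, "promoter_body"),   # last body base
            (1550, "promoter_flank"),  # exactly 50 bp downstream of the 3' end
            (1551, None),              # 51 bp downstream: outside
        ],
    )
    def test_plus_strand_boundaries(self, pos1, rule):
        got = hits_for(pos1, prom=promoter(1000, 1500, "+"))
        if rule is None:
            assert got == []
        else:
            assert [h.hit_rule for h in got] == [rule]

    @pytest.mark.parametrize(
        "pos1,rule",
        [
            (1900, "promoter_flank"),  # upstream window sits right of the span
            (1901, None),
            (951, "promoter_flank"),   # downstream window sits left of the span
            (950, None),
        ],
    )
    def test_minus_strand_mirrored(self, pos1, rule):
        got = hits_for(pos1, prom=promoter(1000, 1500, "-"))
        if rule is None:
            assert got == []
        else:
            assert [h.hit_rule for h in got] == [rule]

    def test_unstranded_treated_as_plus(self):
        got = hits_for(601, prom=promoter(1000, 1500, "."))
        assert [h.hit_rule for h in got] == ["promoter_flank"]

    def test_enhancer_body_only_no_flank(self):
        assert [h.hit_rule for h in hits_for(2001, enh=enhancer(2000, 2300))] == ["enhancer_body"]
        assert hits_for(2000, enh=enhancer(2000, 2300)) == []  # 1 bp left of span
        assert hits_for(2301, enh=enhancer(2000, 2300)) == []  # 1 bp right of span


EDGES = [
    NetworkEdgeRow("TFa", "E1", "enhancer", "G1", "lung"),
    NetworkEdgeRow("TFa", "P1", "promoter", "G2", "lung"),
    NetworkEdgeRow("TFb", "P1", "promoter", "G2", "lung"),
    NetworkEdgeRow("TFa", "E1", "enhancer", "G1", "brain"),
]


class TestCircuitConstruction:
    def test_single_enhancer_hit_single_edge(self):
        hits = hits_for(2100, enh=enhancer(2000, 2300, "E1"))
        c = build_perturbed_circuit(hits, EDGES, "lung", "asthma")
        assert len(c.edges) == 1
        pe = c.edges[0]
        assert pe.perturbation_kind == "enhancer_perturbed"
        assert (pe.edge.tf, pe.edge.target) == ("TFa", "G1")
        assert pe.witness_snps == ("rs1",)

    def test_hit_without_network_element_empty_circuit(self):
        hits = hits_for(2100, enh=enhancer(2000, 2300, "E_unknown"))
        c = build_perturbed_circuit(hits, EDGES, "lung", "asthma")
        assert c.edges == [] and c.genes == set()

    def test_promoter_with_two_tfs_two_edges(self):
        hits = hits_for(1100, prom=promoter(1000, 1500, "+", "P1"))
        c = build_perturbed_circuit(hits, EDGES, "lung", "asthma")
        assert {(e.edge.tf, e.edge.target) for e in c.edges} == {("TFa", "G2"), ("TFb", "G2")}
        assert all(e.perturbation_kind == "promoter_perturbed" for e in c.edges)

    def test_unknown_tissue_lists_available(self):
        with pytest.raises(ValueError, match=r"brain.*lung|lung.*brain|available"):
            build_perturbed_circuit([], EDGES, "kidney", "asthma")

    def test_order_invariance_and_witness_removal(self):
        prom = promoter(1000, 1500, "+", "P1")
        enh = enhancer(2000, 2300, "E1")
        pi, ei = build_index([prom]), build_index([enh])
        s1, s2 = snp(1100, "rsA"), snp(2100, "rsB")
        h12 = map_snps_to_elements([s1, s2], pi, ei)
        h21 = map_snps_to_elements([s2, s1], pi, ei)
        c12 = build_perturbed_circuit(h12, EDGES, "lung", "x")
        c21 = build_perturbed_circuit(list(reversed(h21)), list(reversed(EDGES)), "lung", "x")
        assert c12.edge_keys == c21.edge_keys and len(c12.edges) == 3
        # dropping rsB removes exactly the enhancer edge it alone witnessed
        c_no_b = build_perturbed_circuit(
            map_snps_to_elements([s1], pi, ei), EDGES, "lung", "x"
        )
        assert c12.edge_keys - c_no_b.edge_keys == {("TFa", "E1", "G1")}


class TestNearestGeneSet:
    def test_aggregation_dedup_and_skip(self):
        genes = build_index(
            [
                GenomicInterval("chr1", 100, 200, "+", "G1", "gene"),
                GenomicInterval("chr1", 5000, 6000, "+", "G2", "gene"),
            ]
        )
        got, skipped = nearest_gene_set(
            [snp(150, "a"), snp(190, "b"), snp(5500, "c"), snp(7, "d", chrom="chrZ")], genes
        )
        assert got == {"G1", "G2"}
        assert skipped == ["d"]

    def test_empty_input(self):
        genes = build_index([GenomicInterval("chr1", 0, 10, "+", "G", "gene")])
        assert nearest_gene_set([], genes) == (set(), [])


class TestDiseaseGeneEnrichment:
    def test_perfect_overlap_is_minimal_p(self):
        universe = [f"g{i}" for i in range(20)]
        module = universe[:10]
        best = disease_gene_enrichment(module, module, universe).p_value
        # enumerate every other 10-gene disease set arrangement by overlap size
        for k in range(10):
            other = module[:k] + universe[10 : 20 - k]
            p = disease_gene_enrichment(module, other, universe).p_value
            assert best <= p + 1e-12

    def test_disjoint_module_fold_below_one(self):
        universe = [f"g{i}" for i in range(40)]
        res = disease_gene_enrichment(universe[:10], universe[20:30], universe)
        assert res.fold_change == 0.0

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            disease_gene_enrichment(["a"], ["a"], [])


class TestBhThresholding:
    def test_all_p_one_nothing_flagged(self):
        recs = [snp(1, f"rs{i}", p=1.0) for i in range(10)]
        assert not any(f for _, _, f in threshold_novel_associations(recs))

    def test_single_strong_signal_among_nulls(self):
        rng = np.random.default_rng(31)
        recs = [snp(1, f"rs{i}", p=float(p)) for i, p in enumerate(rng.uniform(0.2, 1.0, 999))]
        recs.append(snp(1, "rs_hit", p=1e-10))
        flagged = {r.snp_id for r, _, f in threshold_novel_associations(recs) if f}
        assert flagged == {"rs_hit"}

    def test_q_monotone_in_p(self):
        rng = np.random.default_rng(37)
        recs = [snp(1, f"rs{i}", p=float(p)) for i, p in enumerate(rng.uniform(0, 1, 200) + 1e-9)]
        res = threshold_novel_associations(recs)
        by_p = sorted(res, key=lambda t: t[0].p_value)
        qs = [q for _, q, _ in by_p]
        assert all(q1 <= q2 + 1e-12 for q1, q2 in zip(qs, qs[1:]))
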