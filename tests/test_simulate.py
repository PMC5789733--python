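"""Generator invariants: determinism, readable outputs, bounds, planted truth."""

import filecmp
import json

import pytest

from regcircuits import io as rio
from regcircuits.simulate import (
    SimulationConfig,
    generate_catalogs,
    generate_genome_tracks,
    generate_ld,
    generate_network_and_expression,
    simulate_all,
)

from conftest import small_config


class TestTracks:
    def test_minimal_config_valid_and_readable(self, tmp_path):
        cfg = small_config(seed=3, n_genes=2, n_enhancers=2, n_motifs=4,
                           n_catalog_snps=10, n_background_snvs=20,
                           n_perturbed_edges=1, n_disease_genes=2,
                           n_specific_genes=2, n_coding_variants=2, n_tfs=2)
        simulate_all(cfg, tmp_path)
        assert len(rio.read_bed_track(tmp_path / "genes.bed", "gene")) == 2
        assert len(rio.read_snp_catalog(tmp_path / "catalog.tsv", "phewas")) >= 10

    def test_intervals_within_chromosome_bounds(self):
        cfg = small_config(seed=5)
        tracks = generate_genome_tracks(cfg)
        for group in (tracks.genes, tracks.exons, tracks.promoters, tracks.enhancers, tracks.motifs):
            for iv in group:
                assert 0 <= iv.start < iv.end <= tracks.chrom_lengths[iv.chrom]

    def test_promoters_adjacent_to_gene_5prime(self):
        tracks = generate_genome_tracks(small_config(seed=5))
        genes = {g.feature_id: g for g in tracks.genes}
        for prom in tracks.promoters:
            g = genes["G" + prom.feature_id[1:]]
            assert prom.strand == g.strand
            if g.strand == "+":
                assert prom.end == g.start
            else:
                assert prom.start == g.end

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError, match="packing"):
            generate_genome_tracks(SimulationConfig(chrom_length=100_000, n_genes=200))


class TestDeterminism:
    def test_same_seed_byte_identical_files(self, tmp_path):
        cfg = small_config(seed=13)
        simulate_all(cfg, tmp_path / "a")
        simulate_all(cfg, tmp_path / "b")
        names = sorted(p.name for p in (tmp_path / "a").iterdir())
        assert names == sorted(p.name for p in (tmp_path / "b").iterdir())
        match, mismatch, errors = filecmp.cmpfiles(tmp_path / "a", tmp_path / "b", names, shallow=False)
        assert mismatch == [] and errors == []

    def test_different_seed_different_data(self, tmp_path):
        simulate_all(small_config(seed=1), tmp_path / "a")
        simulate_all(small_config(seed=2), tmp_path / "b")
        assert (tmp_path / "a" / "catalog.tsv").read_bytes() != (tmp_path / "b" / "catalog.tsv").read_bytes()


class TestCatalogs:
    def test_zero_snps_empty_catalog_valid_header(self, tmp_path):
        cfg = small_config(seed=3, n_catalog_snps=0, n_perturbed_edges=0, n_coding_variants=0)
        simulate_all(cfg, tmp_path)
        assert rio.read_snp_catalog(tmp_path / "catalog.tsv", "phewas") == []

    def test_planted_bits_match_annotation(self):
        """A planted category bit must be exactly realized by the overlap
        annotation of the emitted position."""
        from regcircuits.annotate import annotate_catalog, index_eqtls
        from regcircuits.intervals import build_index

        cfg = small_config(seed=9)
        tracks = generate_genome_tracks(cfg)
        sim = generate_catalogs(cfg, tracks)
        anns = annotate_catalog(
            sim.catalog,
            build_index(tracks.genes), build_index(tracks.exons),
            build_index(tracks.motifs),
            build_index(tracks.promoters + tracks.enhancers),
            index_eqtls(sim.eqtls),
        )
        for snp_id, (m, pe, eq) in sim.catalog_bits.items():
            a = anns[snp_id]
            assert (a.motif, a.promoter_enhancer, a.eqtl) == (m, pe, eq), snp_id

    def test_trend_zero_gives_flat_bins(self):
        from regcircuits.enrichment import power_stratified_enrichment

        cfg = small_config(seed=21, n_catalog_snps=4000, power_trend_slope=0.0)
        tracks = generate_genome_tracks(cfg)
        sim = generate_catalogs(cfg, tracks)
        p = [r.p_value for r in sim.catalog]
        flags = [any(sim.catalog_bits[r.snp_id]) for r in sim.catalog]
        strat = power_stratified_enrichment(p, flags, n_bins=8)
        assert abs(strat.pearson_r) < 0.7 and strat.pearson_p > 0.01


class TestLd:
    def test_tagging_probability_one_covers_every_unannotated_snp(self):
        cfg = small_config(seed=15, tagging_prob=1.0)
        tracks = generate_genome_tracks(cfg)
        sim = generate_catalogs(cfg, tracks)
        ldsim = generate_ld(cfg, sim, tracks)
        unannotated = {s.snp_id for s in sim.catalog if not any(sim.catalog_bits[s.snp_id])}
        tagged = {a for a, _ in ldsim.taggings}
        assert tagged == unannotated

    def test_tagging_probability_zero_plants_nothing(self):
        cfg = small_config(seed=15, tagging_prob=0.0)
        tracks = generate_genome_tracks(cfg)
        sim = generate_catalogs(cfg, tracks)
        assert generate_ld(cfg, sim, tracks).taggings == []

    def test_pair_bounds(self):
        cfg = small_config(seed=15)
        tracks = generate_genome_tracks(cfg)
        sim = generate_catalogs(cfg, tracks)
        ldsim = generate_ld(cfg, sim, tracks)
        qualifying = {(a, b) for a, b in ldsim.taggings}
        for pair in ldsim.pairs:
            assert 0.0 <= pair.r2 <= 1.0
            if (pair.snp_a, pair.snp_b) in qualifying:
                assert pair.r2 >= 0.8 and pair.distance_bp <= cfg.ld_window_bp


class TestNetworkExpression:
    def test_requested_edges_exceeding_available_rejected(self):
        cfg = small_config(seed=15, n_perturbed_edges=10**6)
        tracks = generate_genome_tracks(cfg)
        with pytest.raises(ValueError, match="perturbed edges"):
            generate_network_and_expression(cfg, tracks)

    def test_planted_edge_count_exact(self):
        cfg = small_config(seed=15)
        tracks = generate_genome_tracks(cfg)
        net = generate_network_and_expression(cfg, tracks)
        assert len(net.truth["planted_perturbed_edges"]) == cfg.n_perturbed_edges

    def test_zero_tissues_rejected(self):
        with pytest.raises(ValueError, match="n_tissues"):
            small_config(n_tissues=0)


class TestEmission:
    def test_every_file_readable_by_io(self, sim_dir):
        d, truth = sim_dir
        rio.read_bed_track(d / "promoters.bed", "promoter")
        rio.read_bed_track(d / "motifs.bed", "motif")
        rio.read_snp_catalog(d / "catalog.tsv", "phewas")
        rio.read_snp_catalog(d / "background.tsv", "background")
        rio.read_eqtl_table(d / "eqtl.tsv")
        rio.read_ld_table(d / "ld.tsv")
        rio.read_snp_positions(d / "proxies.tsv")
        rio.read_network(d / "network.tsv")
        rio.read_gene_disease_table(d / "disease_genes.tsv")
        rio.read_protein_sites(d / "protein_sites.tsv")
        rio.read_coding_variants(d / "coding_variants.tsv")
        mat, smap = rio.read_expression_matrix(d / "expression.tsv", d / "samples.tsv")
        assert mat.shape[0] == truth["config"]["n_genes"]

    def test_truth_consistent_with_files(self, sim_dir):
        d, truth = sim_dir
        truth_on_disk = json.loads((d / "truth.json").read_text())
        assert truth_on_disk["network"]["planted_perturbed_edges"] == [
            list(e) for e in truth["network"]["planted_perturbed_edges"]
        ]
        catalog = rio.read_snp_catalog(d / "catalog.tsv", "phewas")
        witness = {r.snp_id for r in catalog if r.trait == truth["network"]["circuit_trait"]}
        assert witness == set(truth["network"]["witness_snps"])
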