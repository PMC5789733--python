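"""Stage orchestration: plain-file handoff between pipeline stages.

Every stage reads the standard file names from ``input_dir`` (the layout
:func:`regcircuits.simulate.simulate_all` emits and real-data users
assemble by conversion), writes deterministic TSV/JSON outputs into
``out_dir``, and appends to a timestamp-free run log, so rerunning with the
same inputs and config reproduces every output byte for byte.  A manifest
records the config hash, input checksums and output row counts.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import annotate as ann
from . import circuits as circ
from . import enrichment as enr
from . import expression as expr
from . import io as rio
from . import ld as ldm
from .intervals import GenomePosition, IntervalIndex, build_index


@dataclass
class PipelineConfig:
    """Paths and every tunable threshold, defaulting to the study values."""

    input_dir: str = "."
    out_dir: str = "out"
    eqtl_fdr: float = 0.05
    r2_min: float = 0.8
    ld_window_bp: int = 500_000
    promoter_up_bp: int = 400
    promoter_down_bp: int = 50
    rpkm_min: float = 1.0
    sample_frac: float = 0.8
    novel_fdr: float = 0.1
    circuit_p: float = 0.05
    denominator_mode: str = "all"
    n_bins: int = 10
    seed: int = 0
    circuit_trait: str = "circuit_trait"
    circuit_tissue: Optional[str] = None  # None: first tissue in the network
    genome_build: str = "synthetic"
    chrom_style: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 < self.eqtl_fdr <= 1):
            raise ValueError("eqtl_fdr outside (0,1]")
        if not (0 <= self.r2_min <= 1):
            raise ValueError("r2_min outside [0,1]")
        if self.denominator_mode not in ("all", "noncoding"):
            raise ValueError(f"bad denominator_mode {self.denominator_mode!r}")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def config_hash(self) -> str:
        # paths are excluded so reruns into different directories compare equal
        payload = {k: v for k, v in asdict(self).items() if k not in ("input_dir", "out_dir")}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


STAGES = (
    "annotate",
    "extend_ld",
    "enrich",
    "stratify",
    "circuits",
    "expression",
    "compare",
    "recovery",
)


class _RunLog:
    """Timestamp-free structured log: stderr plus a file in the out dir."""

    def __init__(self, out_dir: Path):
        self.path = out_dir / "run_log.txt"
        self.lines: list[str] = []

    def info(self, msg: str) -> None:
        import sys

        self.lines.append(msg)
        print(f"[regcircuits] {msg}", file=sys.stderr)

    def flush(self) -> None:
        self.path.write_text("".join(line + "\n" for line in self.lines), encoding="utf-8")


class PipelineRun:
    """Holds shared state (indexes, annotations) across stages of one run."""

    def __init__(self, config: PipelineConfig):
        self.cfg = config
        self.inp = Path(config.input_dir)
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.log = _RunLog(self.out)
        self._cache: dict[str, object] = {}

    # ---- input access -----------------------------------------------------

    def _require(self, name: str, producer: str) -> Path:
        p = self.inp / name
        if not p.exists():
            raise FileNotFoundError(
                f"missing input {p}; produce it with the '{producer}' step first"
            )
        return p

    def load_tracks(self):
        if "tracks" in self._cache:
            return self._cache["tracks"]
        style = self.cfg.chrom_style
        tracks = {
            "genes": rio.read_bed_track(self._require("genes.bed", "simulate/convert"), "gene", style),
            "exons": rio.read_bed_track(self._require("exons.bed", "simulate/convert"), "exon", style),
            "promoters": rio.read_bed_track(self._require("promoters.bed", "simulate/convert"), "promoter", style),
            "enhancers": rio.read_bed_track(self._require("enhancers.bed", "simulate/convert"), "enhancer", style),
            "motifs": rio.read_bed_track(self._require("motifs.bed", "simulate/convert"), "motif", style),
        }
        idx = {
            "gene": build_index(tracks["genes"]),
            "exon": build_index(tracks["exons"]),
            "motif": build_index(tracks["motifs"]),
            "element": build_index(tracks["promoters"] + tracks["enhancers"]),
            "promoter": build_index(tracks["promoters"]),
            "enhancer": build_index(tracks["enhancers"]),
        }
        self._cache["tracks"] = (tracks, idx)
        return self._cache["tracks"]

    def load_catalogs(self):
        if "catalogs" not in self._cache:
            catalog = rio.read_snp_catalog(
                self._require("catalog.tsv", "simulate/convert"), "phewas", self.cfg.chrom_style
            )
            background = rio.read_snp_catalog(
                self._require("background.tsv", "simulate/convert"), "background", self.cfg.chrom_style
            )
            self._cache["catalogs"] = (catalog, background)
        return self._cache["catalogs"]

    def load_eqtls(self):
        if "eqtls" not in self._cache:
            self._cache["eqtls"] = ann.index_eqtls(
                rio.read_eqtl_table(self._require("eqtl.tsv", "simulate/convert"))
            )
        return self._cache["eqtls"]

    # ---- stages -----------------------------------------------------------

    def stage_annotate(self) -> dict:
        _, idx = self.load_tracks()
        catalog, background = self.load_catalogs()
        eqtl_by_snp = self.load_eqtls()
        cat_ann = ann.annotate_catalog(
            catalog, idx["gene"], idx["exon"], idx["motif"], idx["element"],
            eqtl_by_snp, self.cfg.eqtl_fdr,
        )
        bg_ann = ann.annotate_catalog(
            background, idx["gene"], idx["exon"], idx["motif"], idx["element"],
            eqtl_by_snp, self.cfg.eqtl_fdr,
        )
        # protein functional-site flags, when coding-variant tables are supplied
        var_path = self.inp / "coding_variants.tsv"
        site_path = self.inp / "protein_sites.tsv"
        if var_path.exists() and site_path.exists():
            sites_by_protein = ann.index_protein_sites(rio.read_protein_sites(site_path))
            for variant in rio.read_coding_variants(var_path):
                if variant.snp_id in cat_ann:
                    ligand, phospho = ann.annotate_protein_sites(variant, sites_by_protein)
                    cat_ann[variant.snp_id].ligand_site |= ligand
                    cat_ann[variant.snp_id].phospho_site |= phospho
        self._cache["annotations"] = (cat_ann, bg_ann)
        rio.write_tsv(
            self.out / "annotated_catalog.tsv", ann.ANNOTATION_HEADER,
            ann.annotation_rows(cat_ann.values()),
        )
        rio.write_tsv(
            self.out / "annotated_background.tsv", ann.ANNOTATION_HEADER,
            ann.annotation_rows(bg_ann.values()),
        )
        summaries = {}
        for mode in ("all", "noncoding"):
            s = ann.summarize_annotations(cat_ann.values(), mode)
            summaries[mode] = {
                "denominator": s.denominator,
                "totals": s.totals,
                "at_least_1": s.at_least_1,
                "more_than_1": s.more_than_1,
                "all3": s.all3,
                "proportions": {
                    k: s.proportion(k)
                    for k in ("motif", "promoter_enhancer", "eqtl", "at_least_1", "more_than_1", "all3")
                },
            }
        rio.write_json(self.out / "annotation_summary.json", summaries)
        self.log.info(
            f"annotate: catalog snps={len(cat_ann)} background snvs={len(bg_ann)}"
        )
        return {"catalog_rows": len(cat_ann), "background_rows": len(bg_ann)}

    def _annotations(self):
        if "annotations" not in self._cache:
            self.stage_annotate()
        return self._cache["annotations"]

    def stage_extend_ld(self) -> dict:
        _, idx = self.load_tracks()
        cat_ann, _ = self._annotations()
        eqtl_by_snp = self.load_eqtls()
        pairs = rio.read_ld_table(self._require("ld.tsv", "simulate/convert"))
        table = ldm.LdTable(pairs)
        proxies = rio.read_snp_positions(
            self._require("proxies.tsv", "simulate/convert"), self.cfg.chrom_style
        )
        proxy_ann: dict[str, ann.FunctionalAnnotation] = {}
        for p in proxies:
            rec = rio.SnpRecord(p.snp_id, p.position, "proxy", 1.0, None, "phewas")
            proxy_ann[p.snp_id] = ann.annotate_regulatory(
                rec, idx["motif"], idx["element"], eqtl_by_snp, self.cfg.eqtl_fdr
            )
        extended = ldm.extend_catalog(
            cat_ann, proxy_ann, table, self.cfg.r2_min, self.cfg.ld_window_bp
        )
        self._cache["extended"] = extended
        rio.write_tsv(
            self.out / "extended_catalog.tsv", ldm.EXTENDED_HEADER,
            ldm.extended_rows(extended.values()),
        )
        base_cov = sum(a.at_least_1 for a in cat_ann.values())
        ext_cov = sum(e.at_least_1 for e in extended.values())
        self.log.info(
            f"extend_ld: pairs={len(pairs)} proxies={len(proxies)} "
            f"coverage {base_cov}->{ext_cov} of {len(cat_ann)}"
        )
        return {
            "base_at_least_1": base_cov,
            "extended_at_least_1": ext_cov,
            "n_snps": len(cat_ann),
        }

    def _extended(self):
        if "extended" not in self._cache:
            self.stage_extend_ld()
        return self._cache["extended"]

    def stage_enrich(self) -> dict:
        cat_ann, bg_ann = self._annotations()
        results = enr.category_enrichment(cat_ann.values(), bg_ann.values())
        rio.write_tsv(
            self.out / "enrichment.tsv", enr.ENRICHMENT_HEADER, enr.enrichment_rows(results)
        )
        payload = {
            r.category: {
                "a": r.table.a, "b": r.table.b, "c": r.table.c, "d": r.table.d,
                "fold_change": r.fold_change, "p_value": r.p_value, "log10_p": r.log10_p,
            }
            for r in results
        }
        rio.write_json(self.out / "enrichment.json", payload)
        self._cache["enrichment"] = results
        self.log.info(f"enrich: categories={len(results)}")
        return payload

    def stage_stratify(self) -> dict:
        catalog, _ = self.load_catalogs()
        cat_ann, _ = self._annotations()
        extended = self._extended()
        # one record per snp_id: the smallest catalog P (strongest association)
        best_p: dict[str, float] = {}
        for r in catalog:
            if r.snp_id not in best_p or r.p_value < best_p[r.snp_id]:
                best_p[r.snp_id] = r.p_value
        snp_ids = sorted(best_p)
        out = {}
        for label, flags in (
            ("base", {s: cat_ann[s].at_least_1 for s in snp_ids}),
            ("extended", {s: extended[s].at_least_1 for s in snp_ids}),
        ):
            strat = enr.power_stratified_enrichment(
                [best_p[s] for s in snp_ids], [flags[s] for s in snp_ids], self.cfg.n_bins
            )
            suffix = "" if label == "base" else "_extended"
            rio.write_tsv(
                self.out / f"stratification{suffix}.tsv",
                enr.STRATIFICATION_HEADER,
                enr.stratification_rows(strat),
            )
            out[label] = {"pearson_r": strat.pearson_r, "pearson_p": strat.pearson_p}
        rio.write_json(self.out / "stratification.json", out)
        self.log.info(
            f"stratify: bins={self.cfg.n_bins} base r={out['base']['pearson_r']:.3f}"
        )
        return out

    def _circuit_inputs(self):
        _, idx = self.load_tracks()
        catalog, _ = self.load_catalogs()
        tissue = self.cfg.circuit_tissue
        edges = rio.read_network(self._require("network.tsv", "simulate/convert"))
        if tissue is None:
            tissue = sorted({e.tissue for e in edges})[0]
        snps = [
            r for r in catalog
            if r.trait == self.cfg.circuit_trait and r.p_value < self.cfg.circuit_p
        ]
        return idx, edges, tissue, snps

    def stage_circuits(self) -> dict:
        idx, edges, tissue, snps = self._circuit_inputs()
        hits = circ.map_snps_to_elements(
            snps, idx["promoter"], idx["enhancer"],
            self.cfg.promoter_up_bp, self.cfg.promoter_down_bp,
        )
        circuit = circ.build_perturbed_circuit(hits, edges, tissue, self.cfg.circuit_trait)
        self._cache["circuit"] = circuit
        rio.write_tsv(
            self.out / "circuit_edges.tsv", circ.CIRCUIT_HEADER, circ.circuit_rows(circuit)
        )
        rio.write_tsv(
            self.out / "circuit_genes.tsv", ["gene_id"], [[g] for g in sorted(circuit.genes)]
        )
        self.log.info(
            f"circuits: trait={circuit.trait} tissue={tissue} "
            f"snps={len(snps)} hits={len(hits)} edges={len(circuit.edges)}"
        )
        return {"n_edges": len(circuit.edges), "n_genes": len(circuit.genes), "tissue": tissue}

    def _circuit(self):
        if "circuit" not in self._cache:
            self.stage_circuits()
        return self._cache["circuit"]

    def stage_expression(self) -> dict:
        mat, sample_map = rio.read_expression_matrix(
            self._require("expression.tsv", "simulate/convert"),
            self._require("samples.tsv", "simulate/convert"),
        )
        tissues = sorted(set(sample_map.values()))
        summaries = expr.expression_summaries(mat, sample_map)
        self._cache["expression"] = (summaries, tissues, mat, sample_map)
        rio.write_tsv(
            self.out / "expression_summary.tsv",
            expr.summary_header(tissues),
            expr.summary_rows(summaries, tissues),
        )
        expressed = {
            t: sorted(
                expr.tissue_expressed_genes(
                    mat, sample_map, t, self.cfg.rpkm_min, self.cfg.sample_frac
                ).genes
            )
            for t in tissues
        }
        rio.write_json(
            self.out / "tissue_expressed.json", {t: len(g) for t, g in expressed.items()}
        )
        self.log.info(f"expression: genes={len(summaries)} tissues={len(tissues)}")
        return {"n_genes": len(summaries), "tissues": tissues}

    def stage_compare(self) -> dict:
        idx, _, _, snps = self._circuit_inputs()
        circuit = self._circuit()
        disease_rows = rio.read_gene_disease_table(
            self._require("disease_genes.tsv", "simulate/convert")
        )
        disease_genes = {r.gene_id for r in disease_rows}
        universe = {iv.feature_id for iv in self.load_tracks()[0]["genes"]}
        nearest, skipped = circ.nearest_gene_set(snps, idx["gene"])
        res_circ = circ.disease_gene_enrichment(
            circuit.genes, disease_genes, universe, "circuit_module"
        )
        res_near = circ.disease_gene_enrichment(
            nearest, disease_genes, universe, "nearest_gene_module"
        )
        rio.write_tsv(
            self.out / "module_comparison.tsv",
            enr.ENRICHMENT_HEADER,
            enr.enrichment_rows([res_circ, res_near]),
        )
        payload = {
            "circuit_module": {"p_value": res_circ.p_value, "log10_p": res_circ.log10_p,
                               "n_genes": len(circuit.genes & universe)},
            "nearest_gene_module": {"p_value": res_near.p_value, "log10_p": res_near.log10_p,
                                    "n_genes": len(nearest & universe)},
            "skipped_snps": sorted(skipped),
        }
        rio.write_json(self.out / "module_comparison.json", payload)
        self.log.info(
            f"compare: circuit log10P={res_circ.log10_p:.2f} "
            f"nearest log10P={res_near.log10_p:.2f}"
        )
        return payload

    def stage_recovery(self) -> dict:
        """Compare recovered structure with the generator's planted truth
        (no-op unless truth.json sits next to the inputs)."""
        truth_path = self.inp / "truth.json"
        if not truth_path.exists():
            self.log.info("recovery: no truth.json, skipped")
            return {"available": False}
        truth = json.loads(truth_path.read_text())
        report: dict = {"available": True}
        checks: list[bool] = []

        results = self._cache.get("enrichment") or self.stage_enrich()
        if isinstance(results, dict):
            results = self._cache["enrichment"]
        folds = {}
        for r in results:
            planted = truth["catalog"]["planted_folds"].get(r.category)
            if planted is None or r.fold_change is None:
                continue
            t = r.table
            p1 = t.a / (t.a + t.b)
            p2 = t.c / (t.c + t.d)
            se = math.sqrt(
                (1 - p1) / max(t.a, 1) + (1 - p2) / max(t.c, 1)
            )
            lo = r.fold_change * math.exp(-2.576 * se)
            hi = r.fold_change * math.exp(2.576 * se)
            ok = lo <= planted <= hi
            folds[r.category] = {
                "planted": planted, "estimated": r.fold_change,
                "ci99": [lo, hi], "recovered": ok,
            }
            checks.append(ok)
        report["folds"] = folds

        extended = self._extended()
        taggings = truth["ld"]["planted_taggings"]
        rec = sum(
            1 for snp_id, _ in taggings
            if snp_id in extended and extended[snp_id].at_least_1
        )
        report["taggings"] = {
            "planted": len(taggings), "recovered": rec,
            "fraction": rec / len(taggings) if taggings else 1.0,
        }
        checks.append(rec == len(taggings))

        circuit = self._circuit()
        planted_edges = {tuple(e) for e in truth["network"]["planted_perturbed_edges"]}
        got = circuit.edge_keys
        tp = len(got & planted_edges)
        precision = tp / len(got) if got else 1.0
        recall = tp / len(planted_edges) if planted_edges else 1.0
        report["perturbed_edges"] = {
            "planted": len(planted_edges), "recovered": len(got),
            "precision": precision, "recall": recall,
        }
        checks.append(precision == 1.0 and recall == 1.0)

        if "expression" not in self._cache:
            self.stage_expression()
        summaries = self._cache["expression"][0]
        spec = truth["network"]["specific_genes"]
        hits = sum(
            1 for gene, tissue in spec.items()
            if gene in summaries and summaries[gene].max_z_tissue == tissue
        )
        report["specific_genes"] = {
            "planted": len(spec), "max_z_in_planted_tissue": hits,
            "fraction": hits / len(spec) if spec else 1.0,
        }
        checks.append(hits == len(spec))

        report["all_green"] = all(checks)
        rio.write_json(self.out / "recovery.json", report)
        self.log.info(f"recovery: all_green={report['all_green']}")
        return report

    def stage_novel(self) -> dict:
        """Flag candidate novel associations by BH FDR on the catalog."""
        catalog, _ = self.load_catalogs()
        flagged = circ.threshold_novel_associations(catalog, self.cfg.novel_fdr)
        rio.write_tsv(
            self.out / "novel_candidates.tsv",
            ["snp_id", "trait", "p", "q", "candidate_novel"],
            [[r.snp_id, r.trait, r.p_value, q, flag] for r, q, flag in flagged],
        )
        n = sum(1 for _, _, f in flagged if f)
        self.log.info(f"novel: flagged={n} of {len(flagged)}")
        return {"n_flagged": n, "n_records": len(flagged)}

    # ---- orchestration ----------------------------------------------------

    def run_stage(self, stage: str) -> dict:
        fn = {
            "annotate": self.stage_annotate,
            "extend_ld": self.stage_extend_ld,
            "enrich": self.stage_enrich,
            "stratify": self.stage_stratify,
            "circuits": self.stage_circuits,
            "expression": self.stage_expression,
            "compare": self.stage_compare,
            "recovery": self.stage_recovery,
            "novel": self.stage_novel,
        }.get(stage)
        if fn is None:
            raise ValueError(f"unknown stage {stage!r}; stages: {STAGES}")
        return fn()

    def run_all(self) -> dict:
        summary: dict = {"config_hash": self.cfg.config_hash(), "genome_build": self.cfg.genome_build}
        summary["annotate"] = self.stage_annotate()
        summary["extend_ld"] = self.stage_extend_ld()
        summary["enrich"] = self.stage_enrich()
        summary["stratify"] = self.stage_stratify()
        summary["circuits"] = self.stage_circuits()
        summary["expression"] = {
            k: v for k, v in self.stage_expression().items() if k != "tissues"
        }
        summary["compare"] = {
            k: v for k, v in self.stage_compare().items() if k != "skipped_snps"
        }
        summary["novel"] = self.stage_novel()
        summary["recovery"] = self.stage_recovery()
        rio.write_json(self.out / "summary.json", summary)
        self._write_manifest()
        self.log.flush()
        return summary

    def _write_manifest(self) -> None:
        inputs = {}
        for p in sorted(self.inp.glob("*")):
            if p.is_file() and p.suffix in (".tsv", ".bed", ".json"):
                inputs[p.name] = rio.checksum(p)
        config = {k: v for k, v in asdict(self.cfg).items() if k not in ("input_dir", "out_dir")}
        manifest = {
            "config": config,
            "config_hash": self.cfg.config_hash(),
            "input_checksums": inputs,
        }
        rio.write_json(self.out / "manifest.json", manifest)


def run_stage(stage: str, config: PipelineConfig) -> dict:
    run = PipelineRun(config)
    result = run.run_stage(stage)
    run.log.flush()
    return result


def run_all(config: PipelineConfig) -> dict:
    return PipelineRun(config).run_all()
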