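"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the statistical structure the analysis assumes —
not human genome realism.  It emits a gene/exon model, promoter, enhancer
and motif tracks, a disease catalog and a background variant set with
planted per-category placement probabilities (hence planted enrichment
folds), a block-style LD table that tags unannotated catalog SNPs with
functional proxies, tissue-specific TF-element-target networks with
planted perturbed edges witnessed by boundary-exercising SNPs, a log-normal
expression matrix with planted tissue-specific genes, and a disease-gene
table optionally concentrated on circuit targets.  Everything it plants is
recorded in a ground-truth object so recovery can be asserted exactly.

Layout strategy: each chromosome is cut into equal slots, one feature
complex (gene+promoter, enhancer, or standalone motif) per slot with
generous margins, so functional spans and promoter flank windows never
collide across features.  Category placement then draws SNP positions from
four disjoint pools — motif-only, promoter/enhancer-only, motif-inside-
enhancer, neutral — which makes the planted category bits exact.

One pseudo-random stream per stage, derived from the master seed by stage
name, so changing one stage's parameters never perturbs another's draws.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .io import (
    EqtlRecord,
    GeneDiseaseRow,
    LdPair,
    NetworkEdgeRow,
    SnpPosition,
    SnpRecord,
)
from .intervals import GenomePosition

GENE_LEN_RANGE = (1500, 3000)
EXON_LEN = 150
PROMOTER_LEN = 300
ENHANCER_LEN = 300
MOTIF_LEN = 12
SLOT_MARGIN = 800
PROMOTER_UP_BP = 400
PROMOTER_DOWN_BP = 50


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent deterministic stream for one generator stage."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(stage.encode())])


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults are the study conditions.

    Catalog category probabilities default to the observed PheWAS-style
    proportions (motif 12.6%, promoter/enhancer 34.8%, eQTL 38.8%) and the
    background to the levels implied by the headline fold-changes
    (1.32 / 1.42 / 14.6), so a default run carries realistic enrichment.
    """

    seed: int = 0
    # genome
    n_chroms: int = 1
    chrom_length: int = 10_000_000
    n_genes: int = 200
    n_enhancers: int = 300
    n_motifs: int = 500
    n_tfs: int = 30
    # catalogs
    n_catalog_snps: int = 5_000
    n_background_snvs: int = 50_000
    catalog_probs: dict = field(
        default_factory=lambda: {"motif": 0.126, "promoter_enhancer": 0.348, "eqtl": 0.388}
    )
    background_probs: dict = field(
        default_factory=lambda: {"motif": 0.095, "promoter_enhancer": 0.245, "eqtl": 0.027}
    )
    power_trend_slope: float = 0.1
    n_traits: int = 20
    p_min_catalog: float = 1e-8
    p_max_catalog: float = 0.05
    # LD
    tagging_prob: float = 0.5
    ld_window_bp: int = 500_000
    ld_noise_frac: float = 0.1
    n_far_pairs: int = 20
    # network / circuit
    n_tissues: int = 4
    element_tissue_prob: float = 0.7
    n_perturbed_edges: int = 8
    circuit_trait: str = "circuit_trait"
    # expression
    n_samples_per_tissue: int = 50
    expr_log_mean: float = 0.7
    expr_log_sd: float = 0.6
    expr_tissue_log_sd: float = 0.15
    expr_sample_log_sd: float = 0.4
    n_specific_genes: int = 10
    specific_effect_sd: float = 4.0
    # disease genes
    n_disease_genes: int = 40
    disease_on_circuit_frac: float = 0.8
    # protein functional sites
    n_coding_variants: int = 50

    def __post_init__(self) -> None:
        for name, probs in (("catalog_probs", self.catalog_probs), ("background_probs", self.background_probs)):
            for k, v in probs.items():
                if not (0.0 <= v <= 1.0):
                    raise ValueError(f"{name}[{k}] = {v} outside [0,1]")
        for name in (
            "n_chroms", "chrom_length", "n_genes", "n_enhancers", "n_motifs", "n_tfs",
            "n_tissues", "n_samples_per_tissue",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_catalog_snps", "n_background_snvs", "n_perturbed_edges",
                     "n_specific_genes", "n_disease_genes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0.0 <= self.tagging_prob <= 1.0):
            raise ValueError("tagging_prob outside [0,1]")

    @property
    def tissues(self) -> list[str]:
        return [f"tissue_{i + 1:02d}" for i in range(self.n_tissues)]


@dataclass
class Tracks:
    """Generated genome tracks plus the disjoint placement pools."""

    chrom_lengths: dict[str, int]
    genes: list[GenomicInterval]
    exons: list[GenomicInterval]
    promoters: list[GenomicInterval]
    enhancers: list[GenomicInterval]
    motifs: list[GenomicInterval]
    pool_motif_only: list[GenomicInterval]
    pool_pe_only: list[GenomicInterval]
    pool_both: list[GenomicInterval]
    functional_spans: dict[str, np.ndarray]  # chrom -> (k,2) merged spans

    @property
    def gene_ids(self) -> list[str]:
        return [g.feature_id for g in self.genes]


def generate_genome_tracks(cfg: SimulationConfig) -> Tracks:
    """Lay out genes (with stranded promoters at their 5' ends), enhancers
    and motifs on a slot grid; raises when the genome cannot pack them."""
    rng = stage_rng(cfg.seed, "tracks")
    n_inside = min(cfg.n_motifs // 2, cfg.n_enhancers // 2)
    n_standalone = cfg.n_motifs - n_inside
    n_slots_total = cfg.n_genes + cfg.n_enhancers + n_standalone

    # distribute slots over chromosomes proportionally
    per_chrom = [n_slots_total // cfg.n_chroms] * cfg.n_chroms
    for i in range(n_slots_total % cfg.n_chroms):
        per_chrom[i] += 1
    min_slot = 2 * SLOT_MARGIN + GENE_LEN_RANGE[1] + PROMOTER_LEN
    for c, k in enumerate(per_chrom):
        if k and cfg.chrom_length // k < min_slot:
            raise ValueError(
                f"infeasible packing: chrom of {cfg.chrom_length} bp cannot hold "
                f"{k} features (needs >= {min_slot} bp per slot)"
            )

    # one global role assignment, dealt chromosome by chromosome
    roles = np.array(["G"] * cfg.n_genes + ["E"] * cfg.n_enhancers + ["M"] * n_standalone)
    rng.shuffle(roles)

    genes: list[GenomicInterval] = []
    exons: list[GenomicInterval] = []
    promoters: list[GenomicInterval] = []
    enhancers: list[GenomicInterval] = []
    motifs: list[GenomicInterval] = []
    chrom_lengths: dict[str, int] = {}
    tf_names = [f"G{i + 1:04d}" for i in range(cfg.n_genes)]  # overwritten below
    role_iter = iter(roles)
    gi = ei = mi = 0
    for c in range(cfg.n_chroms):
        chrom = f"chr{c + 1}"
        chrom_lengths[chrom] = cfg.chrom_length
        k = per_chrom[c]
        if k == 0:
            continue
        slot_w = cfg.chrom_length // k
        for s in range(k):
            role = next(role_iter)
            lo = s * slot_w + SLOT_MARGIN
            hi = (s + 1) * slot_w - SLOT_MARGIN
            if role == "G":
                gi += 1
                gene_id = f"G{gi:04d}"
                glen = int(rng.integers(GENE_LEN_RANGE[0], GENE_LEN_RANGE[1] + 1))
                strand = "+" if rng.random() < 0.5 else "-"
                g0 = int(rng.integers(lo + PROMOTER_LEN, hi - glen - PROMOTER_LEN + 1))
                genes.append(GenomicInterval(chrom, g0, g0 + glen, strand, gene_id, "gene"))
                if strand == "+":
                    promoters.append(
                        GenomicInterval(chrom, g0 - PROMOTER_LEN, g0, "+", f"P{gi:04d}", "promoter")
                    )
                else:
                    promoters.append(
                        GenomicInterval(chrom, g0 + glen, g0 + glen + PROMOTER_LEN, "-", f"P{gi:04d}", "promoter")
                    )
                n_ex = int(rng.integers(2, 5))
                chunk = glen // n_ex
                for x in range(n_ex):
                    off = int(rng.integers(0, chunk - EXON_LEN + 1))
                    e0 = g0 + x * chunk + off
                    exons.append(
                        GenomicInterval(chrom, e0, e0 + EXON_LEN, strand, f"{gene_id}.ex{x + 1}", "exon")
                    )
            elif role == "E":
                ei += 1
                e0 = int(rng.integers(lo, hi - ENHANCER_LEN + 1))
                enhancers.append(GenomicInterval(chrom, e0, e0 + ENHANCER_LEN, ".", f"E{ei:04d}", "enhancer"))
            else:
                mi += 1
                m0 = int(rng.integers(lo, hi - MOTIF_LEN + 1))
                motifs.append(GenomicInterval(chrom, m0, m0 + MOTIF_LEN, ".", f"TF|SA{mi:04d}", "motif"))

    # TFs are a subset of the generated genes; motif names use their ids
    tf_names = list(rng.choice([g.feature_id for g in genes], size=min(cfg.n_tfs, len(genes)), replace=False))
    tf_names.sort()
    pool_motif_only: list[GenomicInterval] = []
    for j, m in enumerate(motifs):
        tf = tf_names[int(rng.integers(len(tf_names)))]
        mm = GenomicInterval(m.chrom, m.start, m.end, m.strand, f"{tf}|SA{j + 1:04d}", "motif", {"tf": tf})
        pool_motif_only.append(mm)
    motifs = list(pool_motif_only)

    # plant motifs inside a random subset of enhancers (the "both" pool)
    pool_both: list[GenomicInterval] = []
    with_motif = set(rng.choice(len(enhancers), size=min(n_inside, len(enhancers)), replace=False).tolist())
    for j, enh in enumerate(enhancers):
        if j in with_motif:
            tf = tf_names[int(rng.integers(len(tf_names)))]
            off = int(rng.integers(0, enh.length - MOTIF_LEN + 1))
            iv = GenomicInterval(
                enh.chrom, enh.start + off, enh.start + off + MOTIF_LEN, ".",
                f"{tf}|IN{j + 1:04d}", "motif", {"tf": tf},
            )
            motifs.append(iv)
            pool_both.append(iv)
    pool_pe_only = [e for j, e in enumerate(enhancers) if j not in with_motif] + promoters

    functional = {}
    for chrom in chrom_lengths:
        spans = [
            (iv.start, iv.end)
            for group in (motifs, promoters, enhancers)
            for iv in group
            if iv.chrom == chrom
        ]
        spans.sort()
        merged: list[list[int]] = []
        for s0, e0 in spans:
            if merged and s0 <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e0)
            else:
                merged.append([s0, e0])
        functional[chrom] = np.array(merged, dtype=np.int64).reshape(-1, 2)

    return Tracks(
        chrom_lengths=chrom_lengths,
        genes=genes,
        exons=exons,
        promoters=promoters,
        enhancers=enhancers,
        motifs=motifs,
        pool_motif_only=pool_motif_only,
        pool_pe_only=pool_pe_only,
        pool_both=pool_both,
        functional_spans=functional,
    )


@dataclass
class CatalogSim:
    catalog: list[SnpRecord]
    background: list[SnpRecord]
    eqtls: list[EqtlRecord]
    catalog_bits: dict[str, tuple[bool, bool, bool]]  # snp_id -> (motif, pe, eqtl)
    background_bits: dict[str, tuple[bool, bool, bool]]
    truth: dict


def _neutral_positions(
    rng: np.random.Generator, tracks: Tracks, n: int
) -> list[tuple[str, int]]:
    """n uniform 1-based positions outside every functional span."""
    chroms = sorted(tracks.chrom_lengths)
    out: list[tuple[str, int]] = []
    while len(out) < n:
        need = n - len(out)
        picks = rng.integers(0, len(chroms), size=2 * need + 16)
        for ci in picks:
            chrom = chroms[int(ci)]
            pos0 = int(rng.integers(0, tracks.chrom_lengths[chrom]))
            spans = tracks.functional_spans[chrom]
            j = int(np.searchsorted(spans[:, 0], pos0, side="right")) - 1
            if j >= 0 and pos0 < spans[j, 1]:
                continue
            out.append((chrom, pos0 + 1))
            if len(out) == n:
                break
    return out


def _placed_position(rng: np.random.Generator, pool: list[GenomicInterval]) -> tuple[str, int]:
    iv = pool[int(rng.integers(len(pool)))]
    off = int(rng.integers(0, iv.length))
    return iv.chrom, iv.start + off + 1


def generate_catalogs(cfg: SimulationConfig, tracks: Tracks) -> CatalogSim:
    """Catalog and background SNVs with planted category probabilities.

    Catalog P values are uniform on the -log10 scale over
    (p_min_catalog, p_max_catalog]; ``power_trend_slope`` tilts each
    per-SNP category probability linearly in centred -log10(P), so the
    annotated fraction rises with association strength while the marginal
    probability stays at the planted value.
    """
    rng = stage_rng(cfg.seed, "catalog")
    gene_ids = tracks.gene_ids
    tissues = cfg.tissues
    traits = [f"trait_{i + 1:02d}" for i in range(cfg.n_traits)]

    def make_set(n: int, probs: dict, source: str, with_trend: bool, prefix: str):
        if n == 0:
            return [], {}, []
        if with_trend:
            x_lo = -np.log10(cfg.p_max_catalog)
            x_hi = -np.log10(cfg.p_min_catalog)
            x = rng.uniform(x_lo, x_hi, size=n)
            tilt = 1.0 + cfg.power_trend_slope * (x - (x_lo + x_hi) / 2.0)
            pvals = np.power(10.0, -x)
        else:
            tilt = np.ones(n)
            pvals = rng.uniform(1e-12, 1.0, size=n)
        bits = {}
        for cat in ("motif", "promoter_enhancer", "eqtl"):
            p = np.clip(probs[cat] * tilt, 0.0, 1.0)
            bits[cat] = rng.random(n) < p
        if bits["motif"].any() and np.logical_and(bits["motif"], bits["promoter_enhancer"]).any():
            if not tracks.pool_both:
                raise ValueError(
                    "planted joint motif+promoter/enhancer probability exceeds achievable "
                    "coverage: no motif-inside-enhancer regions exist"
                )
        if bits["motif"].any() and not tracks.pool_motif_only:
            raise ValueError("planted motif probability exceeds achievable coverage: no motifs")
        if bits["promoter_enhancer"].any() and not tracks.pool_pe_only:
            raise ValueError(
                "planted promoter/enhancer probability exceeds achievable coverage: no elements"
            )
        n_neutral = int(np.sum(~bits["motif"] & ~bits["promoter_enhancer"]))
        neutral = iter(_neutral_positions(rng, tracks, n_neutral))
        records: list[SnpRecord] = []
        bit_map: dict[str, tuple[bool, bool, bool]] = {}
        eqtl_rows: list[EqtlRecord] = []
        for i in range(n):
            m = bool(bits["motif"][i])
            pe = bool(bits["promoter_enhancer"][i])
            eq = bool(bits["eqtl"][i])
            if m and pe:
                chrom, pos = _placed_position(rng, tracks.pool_both)
            elif m:
                chrom, pos = _placed_position(rng, tracks.pool_motif_only)
            elif pe:
                chrom, pos = _placed_position(rng, tracks.pool_pe_only)
            else:
                chrom, pos = next(neutral)
            snp_id = f"{prefix}{i + 1:07d}"
            trait = traits[int(rng.integers(len(traits)))] if source != "background" else "background"
            records.append(
                SnpRecord(
                    snp_id=snp_id,
                    position=GenomePosition(chrom, pos),
                    trait=trait,
                    p_value=float(pvals[i]),
                    n_cases=int(rng.integers(20, 5000)) if source != "background" else None,
                    source=source,
                )
            )
            bit_map[snp_id] = (m, pe, eq)
            if eq:
                for _ in range(int(rng.integers(1, 3))):
                    eqtl_rows.append(
                        EqtlRecord(
                            snp_id=snp_id,
                            gene_id=gene_ids[int(rng.integers(len(gene_ids)))],
                            tissue=tissues[int(rng.integers(len(tissues)))],
                            fdr=float(rng.uniform(1e-6, 0.05)),
                        )
                    )
            elif rng.random() < 0.05:
                # a non-significant eQTL row: must NOT satisfy the category
                eqtl_rows.append(
                    EqtlRecord(
                        snp_id=snp_id,
                        gene_id=gene_ids[int(rng.integers(len(gene_ids)))],
                        tissue=tissues[int(rng.integers(len(tissues)))],
                        fdr=float(rng.uniform(0.051, 1.0)),
                    )
                )
        return records, bit_map, eqtl_rows

    catalog, catalog_bits, eq_cat = make_set(
        cfg.n_catalog_snps, cfg.catalog_probs, "phewas", True, "rs"
    )
    background, background_bits, eq_bg = make_set(
        cfg.n_background_snvs, cfg.background_probs, "background", False, "bg"
    )
    truth = {
        "planted_catalog_probs": dict(cfg.catalog_probs),
        "planted_background_probs": dict(cfg.background_probs),
        "planted_folds": {
            k: (cfg.catalog_probs[k] / cfg.background_probs[k]) if cfg.background_probs[k] > 0 else None
            for k in cfg.catalog_probs
        },
        "catalog_category_counts": {
            cat: int(sum(bits[i] for bits in catalog_bits.values()))
            for i, cat in enumerate(("motif", "promoter_enhancer", "eqtl"))
        },
        "background_category_counts": {
            cat: int(sum(bits[i] for bits in background_bits.values()))
            for i, cat in enumerate(("motif", "promoter_enhancer", "eqtl"))
        },
        "n_catalog": len(catalog),
        "n_background": len(background),
        "power_trend_slope": cfg.power_trend_slope,
    }
    return CatalogSim(
        catalog=catalog,
        background=background,
        eqtls=eq_cat + eq_bg,
        catalog_bits=catalog_bits,
        background_bits=background_bits,
        truth=truth,
    )


@dataclass
class LdSim:
    pairs: list[LdPair]
    proxy_positions: list[SnpPosition]
    taggings: list[tuple[str, str]]  # (index snp, functional proxy)
    truth: dict


def generate_ld(cfg: SimulationConfig, catalog_sim: CatalogSim, tracks: Tracks) -> LdSim:
    """Block-style LD pairs.  A ``tagging_prob`` fraction of unannotated
    catalog SNPs get a functional proxy at r² in [0.8, 1] within the
    window; noise pairs sit below r² 0.8 and a few functional pairs sit
    beyond the window so both filters are exercised."""
    rng = stage_rng(cfg.seed, "ld")
    elements = sorted(
        tracks.pool_pe_only + tracks.pool_both, key=lambda iv: (iv.chrom, iv.start, iv.feature_id)
    )
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in elements:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    starts = {c: np.array([iv.start for iv in ivs]) for c, ivs in by_chrom.items()}

    def element_near(chrom: str, pos1: int, lo_off: int, hi_off: int) -> Optional[GenomicInterval]:
        """Random element fully inside [pos-hi_off, pos-lo_off] U [pos+lo_off, pos+hi_off]."""
        ivs = by_chrom.get(chrom)
        if not ivs:
            return None
        pos0 = pos1 - 1
        arr = starts[chrom]
        span = max(iv.length for iv in ivs)
        cands = []
        for sign in (-1, 1):
            lo = pos0 + sign * hi_off if sign < 0 else pos0 + lo_off
            hi = pos0 - lo_off if sign < 0 else pos0 + hi_off
            i0 = int(np.searchsorted(arr, lo - span))
            i1 = int(np.searchsorted(arr, hi, side="right"))
            for iv in ivs[i0:i1]:
                d_lo = abs(iv.start - pos0)
                d_hi = abs(iv.end - 1 - pos0)
                if lo_off <= min(d_lo, d_hi) and max(d_lo, d_hi) <= hi_off:
                    cands.append(iv)
        if not cands:
            return None
        return cands[int(rng.integers(len(cands)))]

    pairs: list[LdPair] = []
    proxies: list[SnpPosition] = []
    taggings: list[tuple[str, str]] = []
    unannotated = [
        snp for snp in catalog_sim.catalog if not any(catalog_sim.catalog_bits[snp.snp_id])
    ]
    pi = 0
    for snp in unannotated:
        if rng.random() >= cfg.tagging_prob:
            continue
        iv = element_near(snp.position.chrom, snp.position.pos, 1, cfg.ld_window_bp - ENHANCER_LEN)
        if iv is None:
            continue
        off = int(rng.integers(0, iv.length))
        ppos = iv.start + off + 1
        dist = abs(ppos - snp.position.pos)
        if dist == 0 or dist > cfg.ld_window_bp:
            continue
        pi += 1
        pid = f"rsP{pi:06d}"
        proxies.append(SnpPosition(pid, GenomePosition(iv.chrom, ppos)))
        pairs.append(LdPair(snp.snp_id, pid, float(rng.uniform(0.8, 1.0)), dist))
        taggings.append((snp.snp_id, pid))

    # sub-threshold r2 noise pairs at neutral positions
    n_noise = int(cfg.ld_noise_frac * len(catalog_sim.catalog))
    noise_targets = _neutral_positions(rng, tracks, n_noise)
    ni = 0
    for snp, (chrom, pos) in zip(catalog_sim.catalog[:n_noise], noise_targets):
        if chrom != snp.position.chrom:
            continue
        dist = abs(pos - snp.position.pos)
        if dist == 0 or dist > cfg.ld_window_bp:
            continue
        ni += 1
        pid = f"rsN{ni:06d}"
        proxies.append(SnpPosition(pid, GenomePosition(chrom, pos)))
        pairs.append(LdPair(snp.snp_id, pid, float(rng.uniform(0.2, 0.79)), dist))

    # strong-LD pairs beyond the window: functional but must be excluded
    fi = 0
    for snp in catalog_sim.catalog[: cfg.n_far_pairs]:
        iv = element_near(
            snp.position.chrom, snp.position.pos, cfg.ld_window_bp + 1, cfg.ld_window_bp + 200_000
        )
        if iv is None:
            continue
        off = int(rng.integers(0, iv.length))
        ppos = iv.start + off + 1
        dist = abs(ppos - snp.position.pos)
        if dist <= cfg.ld_window_bp:
            continue
        fi += 1
        pid = f"rsF{fi:06d}"
        proxies.append(SnpPosition(pid, GenomePosition(iv.chrom, ppos)))
        pairs.append(LdPair(snp.snp_id, pid, float(rng.uniform(0.85, 1.0)), dist))

    truth = {
        "planted_taggings": sorted(taggings),
        "n_unannotated": len(unannotated),
        "tagging_prob": cfg.tagging_prob,
    }
    return LdSim(pairs=pairs, proxy_positions=proxies, taggings=taggings, truth=truth)


@dataclass
class NetworkSim:
    edges: list[NetworkEdgeRow]
    witness_snps: list[SnpRecord]
    expression: pd.DataFrame
    sample_map: dict[str, str]
    truth: dict


def generate_network_and_expression(cfg: SimulationConfig, tracks: Tracks) -> NetworkSim:
    """Tissue networks with planted perturbed edges, and an expression
    matrix with planted tissue-specific genes.

    Promoter edges target the promoter's own gene; enhancer edges target
    distal genes (never the enhancer's nearest gene), so circuit modules
    and nearest-gene modules genuinely differ.  Witness SNPs exercise the
    promoter body, the 400-bp upstream boundary and the 50-bp downstream
    boundary on both strands, plus enhancer bodies.
    """
    rng = stage_rng(cfg.seed, "network")
    tissues = cfg.tissues
    gene_ids = tracks.gene_ids
    tf_pool = sorted({iv.attrs["tf"] for iv in tracks.motifs})
    if not tf_pool:
        tf_pool = list(rng.choice(gene_ids, size=min(cfg.n_tfs, len(gene_ids)), replace=False))

    gene_by_chrom: dict[str, list[GenomicInterval]] = {}
    for g in tracks.genes:
        gene_by_chrom.setdefault(g.chrom, []).append(g)
    for ivs in gene_by_chrom.values():
        ivs.sort(key=lambda iv: iv.start)

    def nearest_gene_id(chrom: str, pos0: int) -> Optional[str]:
        ivs = gene_by_chrom.get(chrom)
        if not ivs:
            return None
        best, best_d = None, None
        for iv in ivs:  # small per-chrom lists; clarity over speed here
            d = 0 if iv.start <= pos0 < iv.end else (iv.start - pos0 if pos0 < iv.start else pos0 - iv.end + 1)
            if best_d is None or d < best_d or (d == best_d and iv.feature_id < best):
                best, best_d = iv.feature_id, d
        return best

    promoter_gene = {f"P{i + 1:04d}": f"G{i + 1:04d}" for i in range(len(tracks.promoters))}
    element_edges: dict[str, list[tuple[str, str, str]]] = {}  # element -> [(tf, kind, target)]
    for prom in tracks.promoters:
        tfs = rng.choice(tf_pool, size=min(int(rng.integers(1, 3)), len(tf_pool)), replace=False)
        element_edges[prom.feature_id] = [
            (str(tf), "promoter", promoter_gene[prom.feature_id]) for tf in sorted(tfs)
        ]
    for enh in tracks.enhancers:
        near = nearest_gene_id(enh.chrom, (enh.start + enh.end) // 2)
        distal = [g for g in gene_ids if g != near]
        targets = rng.choice(distal, size=min(int(rng.integers(1, 3)), len(distal)), replace=False)
        tfs = rng.choice(tf_pool, size=min(int(rng.integers(1, 3)), len(tf_pool)), replace=False)
        element_edges[enh.feature_id] = [
            (str(tf), "enhancer", str(t)) for tf in sorted(tfs) for t in sorted(targets)
        ]

    edges: list[NetworkEdgeRow] = []
    tissue_elements: dict[str, list[str]] = {t: [] for t in tissues}
    for element_id in sorted(element_edges):
        for t in tissues:
            if rng.random() < cfg.element_tissue_prob:
                tissue_elements[t].append(element_id)
                for tf, kind, target in element_edges[element_id]:
                    edges.append(NetworkEdgeRow(tf, element_id, kind, target, t))

    # ---- planted perturbation in the first tissue
    circuit_tissue = tissues[0]
    k = cfg.n_perturbed_edges
    avail = tissue_elements[circuit_tissue]
    total_edges = sum(len(element_edges[e]) for e in avail)
    if k > total_edges:
        raise ValueError(
            f"requested {k} perturbed edges but only {total_edges} exist in {circuit_tissue}"
        )
    order = list(rng.permutation(len(avail)))
    chosen: list[str] = []
    remaining = k
    for idx in order:
        e = avail[idx]
        c = len(element_edges[e])
        if c <= remaining:
            chosen.append(e)
            remaining -= c
        if remaining == 0:
            break
    if remaining != 0:
        raise ValueError(f"cannot realize exactly {k} perturbed edges from the available elements")
    chosen.sort()

    elements_by_id = {iv.feature_id: iv for iv in tracks.promoters + tracks.enhancers}
    witness: list[SnpRecord] = []
    planted_edges: list[tuple[str, str, str]] = []
    mode_cycle = 0
    wi = 0
    for e in chosen:
        iv = elements_by_id[e]
        planted_edges.extend((tf, e, target) for tf, _, target in element_edges[e])
        n_wit = 1 + (len(element_edges[e]) > 1)
        for _ in range(n_wit):
            if iv.feature_kind == "promoter":
                mode = ("body", "up_boundary", "down_boundary")[mode_cycle % 3]
                mode_cycle += 1
                if mode == "body":
                    pos0 = iv.start + int(rng.integers(0, iv.length))
                elif mode == "up_boundary":
                    pos0 = iv.end + PROMOTER_UP_BP - 1 if iv.strand == "-" else iv.start - PROMOTER_UP_BP
                else:
                    pos0 = iv.start - PROMOTER_DOWN_BP if iv.strand == "-" else iv.end + PROMOTER_DOWN_BP - 1
            else:
                pos0 = iv.start + int(rng.integers(0, iv.length))
            wi += 1
            witness.append(
                SnpRecord(
                    snp_id=f"rsW{wi:05d}",
                    position=GenomePosition(iv.chrom, pos0 + 1),
                    trait=cfg.circuit_trait,
                    p_value=float(rng.uniform(1e-6, 0.049)),
                    n_cases=int(rng.integers(50, 2000)),
                    source="phewas",
                )
            )

    # ---- expression matrix with planted tissue-specific genes
    erng = stage_rng(cfg.seed, "expression")
    n_genes = len(gene_ids)
    mu = erng.normal(cfg.expr_log_mean, cfg.expr_log_sd, size=n_genes)
    tau = erng.normal(0.0, cfg.expr_tissue_log_sd, size=(n_genes, cfg.n_tissues))
    cols: dict[str, np.ndarray] = {}
    sample_map: dict[str, str] = {}
    for ti, t in enumerate(tissues):
        loc = mu + tau[:, ti]
        draws = erng.normal(
            loc[:, None], cfg.expr_sample_log_sd, size=(n_genes, cfg.n_samples_per_tissue)
        )
        vals = np.exp(draws)
        for j in range(cfg.n_samples_per_tissue):
            name = f"{t}_s{j + 1:03d}"
            cols[name] = vals[:, j]
            sample_map[name] = t
    mat = pd.DataFrame(cols, index=gene_ids)

    n_spec = min(cfg.n_specific_genes, n_genes)
    spec_genes = sorted(erng.choice(gene_ids, size=n_spec, replace=False).tolist())
    specific: dict[str, str] = {}
    samples_of = {t: [s for s, tt in sample_map.items() if tt == t] for t in tissues}
    for j, gene in enumerate(spec_genes):
        t = tissues[j % len(tissues)]
        specific[gene] = t
        others = [tt for tt in tissues if tt != t]
        other_means = np.array([mat.loc[gene, samples_of[tt]].mean() for tt in others])
        target = other_means.mean() + cfg.specific_effect_sd * other_means.std(ddof=1)
        cur = mat.loc[gene, samples_of[t]].mean()
        if cur > 0 and target > 0:
            mat.loc[gene, samples_of[t]] *= target / cur

    truth = {
        "circuit_tissue": circuit_tissue,
        "circuit_trait": cfg.circuit_trait,
        "perturbed_elements": chosen,
        "planted_perturbed_edges": sorted(planted_edges),
        "witness_snps": [w.snp_id for w in witness],
        "specific_genes": specific,
        "specific_effect_sd": cfg.specific_effect_sd,
    }
    return NetworkSim(
        edges=edges, witness_snps=witness, expression=mat, sample_map=sample_map, truth=truth
    )


def generate_disease_genes(
    cfg: SimulationConfig, network_truth: dict, gene_ids: list[str]
) -> tuple[list[GeneDiseaseRow], dict]:
    """Disease-gene table with a configurable excess on circuit targets."""
    rng = stage_rng(cfg.seed, "disease")
    targets = sorted({t for _, _, t in network_truth["planted_perturbed_edges"]})
    n = min(cfg.n_disease_genes, len(gene_ids))
    n_on = min(int(round(cfg.disease_on_circuit_frac * n)), len(targets))
    on = sorted(rng.choice(targets, size=n_on, replace=False).tolist()) if n_on else []
    rest_pool = sorted(set(gene_ids) - set(on))
    n_rest = min(n - n_on, len(rest_pool))
    rest = sorted(rng.choice(rest_pool, size=n_rest, replace=False).tolist())
    genes = sorted(on + rest)
    rows = [GeneDiseaseRow(g, "disease_main") for g in genes]
    truth = {
        "disease_genes": genes,
        "disease_on_circuit": on,
        "disease_on_circuit_frac": cfg.disease_on_circuit_frac,
    }
    return rows, truth


def generate_protein_sites(
    cfg: SimulationConfig, catalog: list[SnpRecord]
) -> tuple[list, list, dict]:
    """Coding-variant and protein-site tables with planted flank hits.

    The first ``n_coding_variants`` catalog SNPs are mapped onto synthetic
    proteins; a rotating schedule plants a ligand-binding site inside the
    2-residue flank, a phosphorylation site inside the 7-residue flank, a
    site just outside each flank, or no site at all, so both inclusive
    boundaries are represented in the planted truth.
    """
    from .io import CodingVariant, ProteinSite

    rng = stage_rng(cfg.seed, "protein")
    variants: list[CodingVariant] = []
    sites: list[ProteinSite] = []
    planted: dict[str, dict] = {}
    n = min(cfg.n_coding_variants, len(catalog))
    for i in range(n):
        snp = catalog[i]
        protein = f"PR{i + 1:04d}"
        residue = int(rng.integers(20, 480))
        variants.append(CodingVariant(snp.snp_id, protein, residue, f"X{residue}Y"))
        mode = i % 5
        ligand = phospho = False
        if mode == 0:  # ligand site inside the 2-residue flank (boundary included)
            sites.append(ProteinSite(protein, residue + int(rng.integers(0, 3)), "ligand_binding"))
            ligand = True
        elif mode == 1:  # phosphosite inside the 7-residue flank
            sites.append(ProteinSite(protein, residue - int(rng.integers(0, 8)), "phosphorylation"))
            phospho = True
        elif mode == 2:  # sites just outside both flanks
            sites.append(ProteinSite(protein, residue + 3, "ligand_binding"))
            sites.append(ProteinSite(protein, residue + 8, "phosphorylation"))
        elif mode == 3:  # both flags
            sites.append(ProteinSite(protein, residue + 2, "ligand_binding"))
            sites.append(ProteinSite(protein, residue - 7, "phosphorylation"))
            ligand = phospho = True
        # mode 4: protein absent from the site table entirely
        planted[snp.snp_id] = {"protein": protein, "ligand": ligand, "phospho": phospho}
    return variants, sites, {"planted_site_flags": planted}


# ---------------------------------------------------------------------------
# one-shot emission


def simulate_all(cfg: SimulationConfig, out_dir) -> dict:
    """Generate every input file plus ``truth.json`` into ``out_dir``.

    Deterministic: a fixed seed reproduces every file byte for byte.
    Returns the ground-truth dictionary.
    """
    from pathlib import Path

    from . import io as rio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tracks = generate_genome_tracks(cfg)
    cat = generate_catalogs(cfg, tracks)
    net = generate_network_and_expression(cfg, tracks)
    ldsim = generate_ld(cfg, cat, tracks)
    disease_rows, disease_truth = generate_disease_genes(cfg, net.truth, tracks.gene_ids)
    variants, sites, protein_truth = generate_protein_sites(cfg, cat.catalog)

    rio.write_bed_track(tracks.genes, out / "genes.bed")
    rio.write_bed_track(tracks.exons, out / "exons.bed")
    rio.write_bed_track(tracks.promoters, out / "promoters.bed")
    rio.write_bed_track(tracks.enhancers, out / "enhancers.bed")
    rio.write_bed_track(tracks.motifs, out / "motifs.bed")
    rio.write_snp_catalog(cat.catalog + net.witness_snps, out / "catalog.tsv")
    rio.write_snp_catalog(cat.background, out / "background.tsv")
    rio.write_tsv(
        out / "eqtl.tsv",
        ["snp_id", "gene_id", "tissue", "fdr"],
        [[e.snp_id, e.gene_id, e.tissue, e.fdr] for e in cat.eqtls],
    )
    rio.write_tsv(
        out / "ld.tsv",
        ["snp_a", "snp_b", "r2", "distance_bp"],
        [[p.snp_a, p.snp_b, p.r2, p.distance_bp] for p in ldsim.pairs],
    )
    rio.write_tsv(
        out / "proxies.tsv",
        ["snp_id", "chrom", "pos"],
        [[p.snp_id, p.position.chrom, p.position.pos] for p in ldsim.proxy_positions],
    )
    rio.write_tsv(
        out / "network.tsv",
        ["tf", "element_id", "element_kind", "target", "tissue"],
        [[e.tf, e.element_id, e.element_kind, e.target, e.tissue] for e in net.edges],
    )
    expr = net.expression.sort_index()
    expr.to_csv(out / "expression.tsv", sep="\t", float_format="%.6g", index_label="gene_id")
    rio.write_tsv(
        out / "samples.tsv",
        ["sample", "tissue"],
        [[s, t] for s, t in net.sample_map.items()],
    )
    rio.write_tsv(
        out / "disease_genes.tsv",
        ["gene_id", "disease"],
        [[r.gene_id, r.disease] for r in disease_rows],
    )
    rio.write_tsv(
        out / "coding_variants.tsv",
        ["snp_id", "protein_id", "residue_index", "aa_change"],
        [[v.snp_id, v.protein_id, v.residue_index, v.aa_change] for v in variants],
    )
    rio.write_tsv(
        out / "protein_sites.tsv",
        ["protein_id", "residue_index", "site_kind"],
        [[s.protein_id, s.residue_index, s.site_kind] for s in sites],
    )

    truth = {
        "seed": cfg.seed,
        "config": asdict(cfg),
        "catalog": cat.truth,
        "ld": ldsim.truth,
        "network": {
            **net.truth,
            "planted_perturbed_edges": [list(e) for e in net.truth["planted_perturbed_edges"]],
        },
        "disease": disease_truth,
        "protein": protein_truth,
        "catalog_bits": {
            snp: list(bits) for snp, bits in sorted(cat.catalog_bits.items())
        },
    }
    rio.write_json(out / "truth.json", truth)
    return truth
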