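"""Per-SNP functional annotation.

Each catalog SNP receives (i) a genic context — exonic, intronic or
intergenic — from a user-supplied gene/exon model, (ii) protein
functional-site flags for coding variants (ligand-binding sites with a
2-residue flank, phosphorylation sites with a 7-residue flank), and
(iii) the three regulatory categories: TF-motif overlap, promoter/enhancer
overlap, and eQTL membership (FDR <= 0.05 in at least one tissue,
inclusive).

Promoters and enhancers are merged into one "promoter/enhancer" category
for the summary tiers (they stay distinct in the circuit analysis).
Coding SNPs still receive regulatory flags; summaries choose the
denominator (``all`` or ``noncoding``), and both modes are reported because
catalog denominators are ambiguous in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .intervals import IntervalIndex
from .io import CodingVariant, EqtlRecord, ProteinSite, SnpRecord

GENIC_CONTEXTS = ("exonic", "intronic", "intergenic")
REGULATORY_FLAGS = ("motif", "promoter_enhancer", "eqtl")

LIGAND_FLANK_RESIDUES = 2
PHOSPHO_FLANK_RESIDUES = 7
EQTL_FDR_MAX = 0.05


@dataclass
class FunctionalAnnotation:
    """Category flags for one SNP with supporting features per flag."""

    snp_id: str
    genic_context: str = "intergenic"
    ligand_site: bool = False
    phospho_site: bool = False
    motif: bool = False
    promoter_enhancer: bool = False
    eqtl: bool = False
    support: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.genic_context not in GENIC_CONTEXTS:
            raise ValueError(f"bad genic_context {self.genic_context!r}")
        for flag in REGULATORY_FLAGS:
            if getattr(self, flag) and not self.support.get(flag):
                raise ValueError(f"{self.snp_id}: flag {flag} set without support")

    def flag(self, name: str) -> bool:
        return bool(getattr(self, name))

    @property
    def n_regulatory_categories(self) -> int:
        return sum(self.flag(f) for f in REGULATORY_FLAGS)

    @property
    def at_least_1(self) -> bool:
        return self.n_regulatory_categories >= 1

    @property
    def more_than_1(self) -> bool:
        return self.n_regulatory_categories > 1

    @property
    def all3(self) -> bool:
        return self.n_regulatory_categories == 3


@dataclass
class AnnotationSummary:
    """Category totals and the >=1 / >1 / all-3 tiers over one catalog."""

    denominator: int
    denominator_mode: str
    totals: dict[str, int]
    at_least_1: int
    more_than_1: int
    all3: int

    def proportion(self, key: str) -> float:
        if self.denominator == 0:
            return 0.0
        if key in self.totals:
            return self.totals[key] / self.denominator
        return getattr(self, key) / self.denominator


def classify_genic_context(
    snp: SnpRecord, gene_index: IntervalIndex, exon_index: IntervalIndex
) -> str:
    """Exonic if inside any exon; else intronic if inside any gene body;
    else intergenic (an empty model classifies everything intergenic)."""
    if exon_index.overlaps(snp.position):
        return "exonic"
    if gene_index.overlaps(snp.position):
        return "intronic"
    return "intergenic"


def index_protein_sites(sites: Iterable[ProteinSite]) -> dict[str, list[ProteinSite]]:
    by_protein: dict[str, list[ProteinSite]] = {}
    for s in sites:
        by_protein.setdefault(s.protein_id, []).append(s)
    return by_protein


def annotate_protein_sites(
    variant: CodingVariant,
    sites_by_protein: Mapping[str, Sequence[ProteinSite]],
    ligand_flank: int = LIGAND_FLANK_RESIDUES,
    phospho_flank: int = PHOSPHO_FLANK_RESIDUES,
) -> tuple[bool, bool]:
    """(ligand_site, phospho_site) flags for a coding variant.

    A flag is true iff the variant residue lies within the site's flank on
    the same protein: |variant - site| <= 2 residues for ligand-binding
    sites, <= 7 for phosphorylation sites.  A protein absent from the site
    table yields (False, False).
    """
    ligand = phospho = False
    for site in sites_by_protein.get(variant.protein_id, ()):
        d = abs(variant.residue_index - site.residue_index)
        if site.site_kind == "ligand_binding" and d <= ligand_flank:
            ligand = True
        elif site.site_kind == "phosphorylation" and d <= phospho_flank:
            phospho = True
    return ligand, phospho


def index_eqtls(eqtls: Iterable[EqtlRecord]) -> dict[str, list[EqtlRecord]]:
    by_snp: dict[str, list[EqtlRecord]] = {}
    for e in eqtls:
        by_snp.setdefault(e.snp_id, []).append(e)
    return by_snp


def annotate_regulatory(
    snp: SnpRecord,
    motif_index: IntervalIndex,
    element_index: IntervalIndex,
    eqtl_by_snp: Mapping[str, Sequence[EqtlRecord]],
    eqtl_fdr_max: float = EQTL_FDR_MAX,
    genic_context: str = "intergenic",
) -> FunctionalAnnotation:
    """Regulatory category flags for one SNP.

    ``element_index`` holds both promoter and enhancer intervals; either
    kind satisfies the merged promoter/enhancer category.  An eQTL counts
    only when significant (FDR <= ``eqtl_fdr_max``, inclusive) in at least
    one tissue.  Support lists are deduplicated and sorted.
    """
    support: dict[str, tuple[str, ...]] = {}
    motif_hits = motif_index.query_point(snp.position)
    if motif_hits:
        support["motif"] = tuple(sorted({iv.attrs.get("tf", iv.feature_id) for iv in motif_hits}))
    element_hits = element_index.query_point(snp.position)
    if element_hits:
        support["promoter_enhancer"] = tuple(sorted({iv.feature_id for iv in element_hits}))
    qualifying = [
        e for e in eqtl_by_snp.get(snp.snp_id, ()) if e.fdr <= eqtl_fdr_max
    ]
    if qualifying:
        support["eqtl"] = tuple(sorted({f"{e.gene_id}@{e.tissue}" for e in qualifying}))
    return FunctionalAnnotation(
        snp_id=snp.snp_id,
        genic_context=genic_context,
        motif=bool(motif_hits),
        promoter_enhancer=bool(element_hits),
        eqtl=bool(qualifying),
        support=support,
    )


def annotate_catalog(
    snps: Iterable[SnpRecord],
    gene_index: IntervalIndex,
    exon_index: IntervalIndex,
    motif_index: IntervalIndex,
    element_index: IntervalIndex,
    eqtl_by_snp: Mapping[str, Sequence[EqtlRecord]],
    eqtl_fdr_max: float = EQTL_FDR_MAX,
) -> dict[str, FunctionalAnnotation]:
    """Annotate a whole catalog, one annotation per distinct snp_id.

    A SNP reported with several traits shares one genomic annotation; the
    first occurrence wins (annotation depends only on coordinates and id,
    so order cannot change the result).
    """
    out: dict[str, FunctionalAnnotation] = {}
    for snp in snps:
        if snp.snp_id in out:
            continue
        ctx = classify_genic_context(snp, gene_index, exon_index)
        out[snp.snp_id] = annotate_regulatory(
            snp, motif_index, element_index, eqtl_by_snp, eqtl_fdr_max, genic_context=ctx
        )
    return out


def summarize_annotations(
    annotations: Iterable[FunctionalAnnotation], denominator_mode: str = "all"
) -> AnnotationSummary:
    """Category totals plus the >=1 / >1 / all-3 regulatory tiers.

    ``denominator_mode="noncoding"`` excludes exonic SNPs from both the
    denominator and the counts; ``"all"`` keeps every SNP.  Empty input
    yields an all-zero summary.
    """
    if denominator_mode not in ("all", "noncoding"):
        raise ValueError(f"unknown denominator_mode {denominator_mode!r}")
    anns = list(annotations)
    if denominator_mode == "noncoding":
        anns = [a for a in anns if a.genic_context != "exonic"]
    totals = {f: sum(a.flag(f) for a in anns) for f in REGULATORY_FLAGS}
    totals["ligand_site"] = sum(a.ligand_site for a in anns)
    totals["phospho_site"] = sum(a.phospho_site for a in anns)
    return AnnotationSummary(
        denominator=len(anns),
        denominator_mode=denominator_mode,
        totals=totals,
        at_least_1=sum(a.at_least_1 for a in anns),
        more_than_1=sum(a.more_than_1 for a in anns),
        all3=sum(a.all3 for a in anns),
    )


def annotation_rows(annotations: Iterable[FunctionalAnnotation]) -> list[list]:
    """Rows for the annotated-catalog TSV (support lists semicolon-joined)."""
    rows = []
    for a in annotations:
        rows.append(
            [
                a.snp_id,
                a.genic_context,
                a.motif,
                a.promoter_enhancer,
                a.eqtl,
                a.n_regulatory_categories,
                ";".join(a.support.get("motif", ())),
                ";".join(a.support.get("promoter_enhancer", ())),
                ";".join(a.support.get("eqtl", ())),
            ]
        )
    return rows


ANNOTATION_HEADER = [
    "snp_id",
    "genic_context",
    "motif",
    "promoter_enhancer",
    "eqtl",
    "n_regulatory_categories",
    "motif_support",
    "promoter_enhancer_support",
    "eqtl_support",
]
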