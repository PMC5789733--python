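"""Tissue-specific perturbed regulatory circuits.

A tissue network is a list of TF -> element -> target-gene edges (elements
are promoters or enhancers).  A disease-associated SNP "perturbs" an edge
when it can plausibly alter TF binding at the linking element:

* promoter edges — the SNP lies in the promoter span, or in its 400-bp
  upstream window, or in its 50-bp downstream window (both windows
  strand-aware and closed on the outer boundary);
* enhancer edges — the SNP lies inside the enhancer span (no flank).

The perturbed circuit for a trait and tissue is the set of network edges
through hit elements, each edge recording its witnessing SNPs.  Circuit
gene modules are compared with a nearest-gene baseline by disease-gene
enrichment (Fisher exact test over a gene universe).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .enrichment import ContingencyTable, EnrichmentResult, _fisher_with_log
from .intervals import GenomicInterval, IntervalIndex
from .io import NetworkEdgeRow, SnpRecord

PROMOTER_UP_BP = 400
PROMOTER_DOWN_BP = 50
HIT_RULES = ("promoter_body", "promoter_flank", "enhancer_body")


@dataclass(frozen=True)
class RegulatoryEdge:
    tf: str
    element_id: str
    element_kind: str  # promoter | enhancer
    target: str
    tissue: str

    @classmethod
    def from_row(cls, row: NetworkEdgeRow) -> "RegulatoryEdge":
        return cls(row.tf, row.element_id, row.element_kind, row.target, row.tissue)


@dataclass(frozen=True)
class ElementHit:
    snp_id: str
    element_id: str
    element_kind: str
    hit_rule: str

    def __post_init__(self) -> None:
        if self.hit_rule not in HIT_RULES:
            raise ValueError(f"unknown hit_rule {self.hit_rule!r}")
        if not self.hit_rule.startswith(self.element_kind):
            raise ValueError(
                f"hit_rule {self.hit_rule} inconsistent with element_kind {self.element_kind}"
            )


@dataclass(frozen=True)
class PerturbedEdge:
    edge: RegulatoryEdge
    perturbation_kind: str  # promoter_perturbed | enhancer_perturbed
    witness_snps: tuple[str, ...]


@dataclass
class PerturbedCircuit:
    trait: str
    tissue: str
    edges: list[PerturbedEdge] = field(default_factory=list)

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for pe in self.edges:
            out.add(pe.edge.tf)
            out.add(pe.edge.target)
        return out

    @property
    def edge_keys(self) -> set[tuple[str, str, str]]:
        return {(pe.edge.tf, pe.edge.element_id, pe.edge.target) for pe in self.edges}


def _promoter_hit_rule(
    iv: GenomicInterval, pos0: int, up_bp: int, down_bp: int
) -> Optional[str]:
    """Classify a point against a promoter span and its strand-aware flanks.

    Unstranded promoters default to the + orientation.  Windows are closed
    on the outer boundary: the 400th upstream and 50th downstream bp hit.
    """
    if iv.start <= pos0 < iv.end:
        return "promoter_body"
    if iv.strand == "-":
        upstream = iv.end <= pos0 < iv.end + up_bp
        downstream = iv.start - down_bp <= pos0 < iv.start
    else:
        upstream = iv.start - up_bp <= pos0 < iv.start
        downstream = iv.end <= pos0 < iv.end + down_bp
    if upstream or downstream:
        return "promoter_flank"
    return None


def map_snps_to_elements(
    snps: Iterable[SnpRecord],
    promoter_index: IntervalIndex,
    enhancer_index: IntervalIndex,
    up_bp: int = PROMOTER_UP_BP,
    down_bp: int = PROMOTER_DOWN_BP,
) -> list[ElementHit]:
    """All (SNP, element) hits under the promoter-flank and enhancer-body
    rules.  SNPs hitting nothing are simply absent from the result."""
    # query promoters through an index of spans expanded by the larger flank,
    # then classify against the true span — keeps lookups O(log n)
    pad = max(up_bp, down_bp)
    expanded = [
        GenomicInterval(
            iv.chrom,
            max(0, iv.start - pad),
            iv.end + pad,
            iv.strand,
            iv.feature_id,
            "promoter",
            {"s": str(iv.start), "e": str(iv.end)},
        )
        for iv in promoter_index.intervals()
    ]
    padded_index = IntervalIndex(expanded)
    hits: list[ElementHit] = []
    seen: set[tuple[str, str]] = set()
    for snp in snps:
        pos0 = snp.position.pos0
        for iv in padded_index.query_point(snp.position):
            true_iv = GenomicInterval(
                iv.chrom, int(iv.attrs["s"]), int(iv.attrs["e"]), iv.strand, iv.feature_id, "promoter"
            )
            rule = _promoter_hit_rule(true_iv, pos0, up_bp, down_bp)
            if rule and (snp.snp_id, iv.feature_id) not in seen:
                seen.add((snp.snp_id, iv.feature_id))
                hits.append(ElementHit(snp.snp_id, iv.feature_id, "promoter", rule))
        for iv in enhancer_index.query_point(snp.position):
            if (snp.snp_id, iv.feature_id) not in seen:
                seen.add((snp.snp_id, iv.feature_id))
                hits.append(ElementHit(snp.snp_id, iv.feature_id, "enhancer", "enhancer_body"))
    hits.sort(key=lambda h: (h.snp_id, h.element_id))
    return hits


def build_perturbed_circuit(
    hits: Iterable[ElementHit],
    network_edges: Iterable[NetworkEdgeRow],
    tissue: str,
    trait: str,
) -> PerturbedCircuit:
    """Emit every network edge of ``tissue`` through a hit element.

    Each edge appears once, labelled promoter_perturbed or
    enhancer_perturbed from its element kind and listing all witnessing
    SNPs (sorted).  An unknown tissue raises, listing the available ones.
    Output order is deterministic: (tf, element_id, target).
    """
    edges = [RegulatoryEdge.from_row(r) if isinstance(r, NetworkEdgeRow) else r for r in network_edges]
    tissues = sorted({e.tissue for e in edges})
    if tissue not in tissues:
        raise ValueError(f"tissue {tissue!r} absent from network; available: {tissues}")
    by_element: dict[str, list[RegulatoryEdge]] = {}
    for e in edges:
        if e.tissue == tissue:
            by_element.setdefault(e.element_id, []).append(e)
    witnesses: dict[RegulatoryEdge, set[str]] = {}
    for hit in hits:
        for edge in by_element.get(hit.element_id, ()):
            if edge.element_kind != hit.element_kind:
                raise ValueError(
                    f"element {hit.element_id}: hit kind {hit.element_kind} but network says {edge.element_kind}"
                )
            witnesses.setdefault(edge, set()).add(hit.snp_id)
    perturbed = [
        PerturbedEdge(
            edge=e,
            perturbation_kind=f"{e.element_kind}_perturbed",
            witness_snps=tuple(sorted(snps)),
        )
        for e, snps in witnesses.items()
    ]
    perturbed.sort(key=lambda pe: (pe.edge.tf, pe.edge.element_id, pe.edge.target))
    return PerturbedCircuit(trait=trait, tissue=tissue, edges=perturbed)


def nearest_gene_set(
    snps: Iterable[SnpRecord], gene_index: IntervalIndex
) -> tuple[set[str], list[str]]:
    """Nearest gene of each SNP (gene-body distance, lexicographic ties),
    deduplicated.  Returns ``(genes, skipped_snp_ids)``; a SNP on a
    chromosome without genes is skipped and reported."""
    genes: set[str] = set()
    skipped: list[str] = []
    for snp in snps:
        res = gene_index.nearest_feature(snp.position, "gene")
        if res is None:
            skipped.append(snp.snp_id)
        else:
            genes.add(res[0])
    return genes, skipped


def disease_gene_enrichment(
    module_genes: Iterable[str],
    disease_genes: Iterable[str],
    universe: Iterable[str],
    category: str = "module",
) -> EnrichmentResult:
    """Fisher exact test for disease genes inside a gene module.

    Table: (module & disease, module - disease, disease - module, rest)
    over ``universe``; genes outside the universe are ignored.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty gene universe")
    module = set(module_genes) & uni
    disease = set(disease_genes) & uni
    a = len(module & disease)
    b = len(module - disease)
    c = len(disease - module)
    d = len(uni) - a - b - c
    t = ContingencyTable(a=a, b=b, c=c, d=d)
    p, log10p = _fisher_with_log(t)
    # fold here is module disease-fraction over the universe disease-fraction
    fold = None
    if module and disease:
        fold = (a / len(module)) / (len(disease) / len(uni))
    return EnrichmentResult(
        category=category, table=t, fold_change=fold, p_value=p, log10_p=log10p
    )


def threshold_novel_associations(
    records: Sequence[SnpRecord], fdr_q: float = 0.1
) -> list[tuple[SnpRecord, float, bool]]:
    """Benjamini-Hochberg q-values over the catalog's raw P values;
    records with q < ``fdr_q`` are flagged as candidate novel associations."""
    from statsmodels.stats.multitest import multipletests

    if not records:
        return []
    pvals = [r.p_value for r in records]
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    return [(r, float(q), bool(q < fdr_q)) for r, q in zip(records, qvals)]


CIRCUIT_HEADER = [
    "tf",
    "element_id",
    "element_kind",
    "target",
    "tissue",
    "perturbation_kind",
    "witness_snps",
]


def circuit_rows(circuit: PerturbedCircuit) -> list[list]:
    return [
        [
            pe.edge.tf,
            pe.edge.element_id,
            pe.edge.element_kind,
            pe.edge.target,
            pe.edge.tissue,
            pe.perturbation_kind,
            ";".join(pe.witness_snps),
        ]
        for pe in circuit.edges
    ]
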