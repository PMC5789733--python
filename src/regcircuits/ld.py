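"""LD proxy lookup and annotation extension.

A reported SNP inherits a functional category if any of its strong-LD
proxies (r² >= 0.8, within 500 kb on either side, both thresholds
inclusive) carries that category — even when the reported SNP itself lies
outside every functional region.  Extension is a single hop: proxies of
proxies are never chased, matching the way proxy searches are used with
SNP-pair tables such as SNAP output.

The LD table is the only LD source (no genotype-based r²); duplicate pairs
keep the larger r².
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .annotate import REGULATORY_FLAGS, FunctionalAnnotation
from .io import LdPair

R2_MIN_DEFAULT = 0.8
WINDOW_BP_DEFAULT = 500_000


class LdTable:
    """Symmetrized pair lookup: neighbors(b) returns a whenever (a, b) was read."""

    def __init__(self, pairs: Iterable[LdPair] = ()):
        self._adj: dict[str, dict[str, tuple[float, int]]] = {}
        for p in pairs:
            self.add(p)

    def add(self, pair: LdPair) -> None:
        for a, b in ((pair.snp_a, pair.snp_b), (pair.snp_b, pair.snp_a)):
            slot = self._adj.setdefault(a, {})
            prev = slot.get(b)
            if prev is None or pair.r2 > prev[0]:
                slot[b] = (pair.r2, pair.distance_bp)

    def neighbors(self, snp_id: str) -> list[tuple[str, float, int]]:
        return [(b, r2, d) for b, (r2, d) in self._adj.get(snp_id, {}).items()]

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._adj

    def __len__(self) -> int:
        return len(self._adj)


@dataclass
class ProxySet:
    """Qualifying proxies of one index SNP, sorted by descending r² then id."""

    index_snp_id: str
    proxies: list[tuple[str, float, int]] = field(default_factory=list)

    @property
    def proxy_ids(self) -> list[str]:
        return [p[0] for p in self.proxies]


@dataclass
class ExtendedAnnotation:
    """Base annotation plus the proxy-union flags (monotone over the base)."""

    base: FunctionalAnnotation
    extended_flags: dict[str, bool]
    contributing_proxies: dict[str, tuple[str, ...]]

    def flag(self, name: str) -> bool:
        return self.extended_flags[name]

    @property
    def n_regulatory_categories(self) -> int:
        return sum(self.extended_flags[f] for f in REGULATORY_FLAGS)

    @property
    def at_least_1(self) -> bool:
        return self.n_regulatory_categories >= 1

    @property
    def more_than_1(self) -> bool:
        return self.n_regulatory_categories > 1

    @property
    def all3(self) -> bool:
        return self.n_regulatory_categories == 3


def find_proxies(
    snp_id: str,
    ld_table: LdTable,
    r2_min: float = R2_MIN_DEFAULT,
    window_bp: int = WINDOW_BP_DEFAULT,
) -> ProxySet:
    """Proxies of ``snp_id`` with r² >= ``r2_min`` and distance <=
    ``window_bp`` (both inclusive).  The index SNP itself is excluded; a SNP
    absent from the table yields an empty set."""
    kept = [
        (other, r2, d)
        for other, r2, d in ld_table.neighbors(snp_id)
        if r2 >= r2_min and d <= window_bp and other != snp_id
    ]
    kept.sort(key=lambda t: (-t[1], t[0]))
    return ProxySet(index_snp_id=snp_id, proxies=kept)


def extend_annotation(
    base: FunctionalAnnotation,
    proxy_annotations: Iterable[FunctionalAnnotation],
) -> ExtendedAnnotation:
    """OR each regulatory flag of the base with all proxy flags, recording
    which proxies contributed each flag."""
    flags = {f: base.flag(f) for f in REGULATORY_FLAGS}
    contributors: dict[str, list[str]] = {f: [] for f in REGULATORY_FLAGS}
    for pa in proxy_annotations:
        for f in REGULATORY_FLAGS:
            if pa.flag(f):
                flags[f] = True
                contributors[f].append(pa.snp_id)
    return ExtendedAnnotation(
        base=base,
        extended_flags=flags,
        contributing_proxies={f: tuple(sorted(set(v))) for f, v in contributors.items()},
    )


def extend_catalog(
    annotations: Mapping[str, FunctionalAnnotation],
    proxy_annotations: Mapping[str, FunctionalAnnotation],
    ld_table: LdTable,
    r2_min: float = R2_MIN_DEFAULT,
    window_bp: int = WINDOW_BP_DEFAULT,
) -> dict[str, ExtendedAnnotation]:
    """Extend every catalog annotation through its qualifying proxies.

    ``proxy_annotations`` maps proxy snp_id -> annotation; proxies without
    an annotation contribute nothing (they are treated as unannotated).
    """
    out: dict[str, ExtendedAnnotation] = {}
    for snp_id, base in annotations.items():
        proxies = find_proxies(snp_id, ld_table, r2_min, window_bp)
        pas = [
            proxy_annotations[pid]
            for pid in proxies.proxy_ids
            if pid in proxy_annotations
        ]
        out[snp_id] = extend_annotation(base, pas)
    return out


EXTENDED_HEADER = [
    "snp_id",
    "genic_context",
    "motif",
    "promoter_enhancer",
    "eqtl",
    "extended_motif",
    "extended_promoter_enhancer",
    "extended_eqtl",
    "extended_n_regulatory_categories",
    "motif_proxies",
    "promoter_enhancer_proxies",
    "eqtl_proxies",
]


def extended_rows(extended: Iterable[ExtendedAnnotation]) -> list[list]:
    rows = []
    for e in extended:
        rows.append(
            [
                e.base.snp_id,
                e.base.genic_context,
                e.base.motif,
                e.base.promoter_enhancer,
                e.base.eqtl,
                e.extended_flags["motif"],
                e.extended_flags["promoter_enhancer"],
                e.extended_flags["eqtl"],
                e.n_regulatory_categories,
                ";".join(e.contributing_proxies["motif"]),
                ";".join(e.contributing_proxies["promoter_enhancer"]),
                ";".join(e.contributing_proxies["eqtl"]),
            ]
        )
    return rows
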