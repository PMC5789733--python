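"""Genome coordinate primitives and a searchable interval index.

All internal coordinates are 0-based, half-open ``[start, end)``.  Catalog
and eQTL tables carry 1-based positions and are converted on read; BED is
native 0-based half-open.  Chromosome names are matched as exact strings
("chr1" is not "1"); :mod:`regcircuits.io` offers an optional normalization
pass for the "chr" prefix.

The index supports the two queries every annotation stage needs:

* point overlap — all intervals whose span contains a SNP position;
* nearest feature of a kind — for the nearest-gene baseline.

Point queries use a per-chromosome array sorted by start augmented with a
prefix running maximum of interval ends, so a query is a binary search plus
a bounded walk-back.  Nearest queries use per-(chromosome, kind) arrays
sorted by start and by end.  Results are defined to be identical to a
brute-force linear scan; the test suite enforces this equivalence.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

STRANDS = ("+", "-", ".")
FEATURE_KINDS = ("gene", "exon", "promoter", "enhancer", "motif")


@dataclass(frozen=True)
class GenomePosition:
    """A 1-based genomic point (the convention of SNP catalogs)."""

    chrom: str
    pos: int  # 1-based

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1 (got {self.pos})")

    @property
    def pos0(self) -> int:
        """0-based coordinate of this position."""
        return self.pos - 1


@dataclass
class GenomicInterval:
    """A genomic feature span, 0-based half-open."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str = "."
    feature_id: str = ""
    feature_kind: str = "gene"
    attrs: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        validate_interval(self)

    def contains(self, p: GenomePosition) -> bool:
        return self.chrom == p.chrom and self.start <= p.pos0 < self.end

    @property
    def length(self) -> int:
        return self.end - self.start


def validate_interval(iv: GenomicInterval) -> None:
    if not iv.chrom:
        raise ValueError(f"interval {iv.feature_id!r}: chrom must be non-empty")
    if iv.start < 0:
        raise ValueError(f"interval {iv.feature_id!r}: negative start {iv.start}")
    if iv.start >= iv.end:
        raise ValueError(
            f"interval {iv.feature_id!r}: start >= end ({iv.start} >= {iv.end})"
        )
    if iv.strand not in STRANDS:
        raise ValueError(f"interval {iv.feature_id!r}: bad strand {iv.strand!r}")
    if iv.feature_kind not in FEATURE_KINDS:
        raise ValueError(
            f"interval {iv.feature_id!r}: bad feature_kind {iv.feature_kind!r}"
        )


class _ChromIndex:
    """Intervals of one chromosome, sorted by start with a prefix max-end."""

    __slots__ = ("ivs", "starts", "prefix_maxend", "by_kind")

    def __init__(self, intervals: list[GenomicInterval]):
        self.ivs = sorted(intervals, key=lambda iv: (iv.start, iv.feature_id, iv.end))
        self.starts = [iv.start for iv in self.ivs]
        self.prefix_maxend: list[int] = []
        m = -1
        for iv in self.ivs:
            m = iv.end if iv.end > m else m
            self.prefix_maxend.append(m)
        self.by_kind: dict[str, _KindIndex] = {}
        for kind in FEATURE_KINDS:
            sub = [iv for iv in self.ivs if iv.feature_kind == kind]
            if sub:
                self.by_kind[kind] = _KindIndex(sub)

    def query_point(self, pos0: int) -> list[GenomicInterval]:
        hits = []
        i = bisect_right(self.starts, pos0) - 1
        while i >= 0 and self.prefix_maxend[i] > pos0:
            if self.ivs[i].end > pos0:
                hits.append(self.ivs[i])
            i -= 1
        hits.reverse()  # already (start, feature_id)-sorted in forward order
        return hits


class _KindIndex:
    """One feature kind on one chromosome; supports nearest queries."""

    __slots__ = ("ivs", "starts", "prefix_maxend", "ends_sorted", "by_end")

    def __init__(self, intervals: list[GenomicInterval]):
        self.ivs = sorted(intervals, key=lambda iv: (iv.start, iv.feature_id, iv.end))
        self.starts = [iv.start for iv in self.ivs]
        self.prefix_maxend: list[int] = []
        m = -1
        for iv in self.ivs:
            m = iv.end if iv.end > m else m
            self.prefix_maxend.append(m)
        self.by_end = sorted(self.ivs, key=lambda iv: iv.end)
        self.ends_sorted = [iv.end for iv in self.by_end]

    def containing(self, pos0: int) -> list[GenomicInterval]:
        hits = []
        i = bisect_right(self.starts, pos0) - 1
        while i >= 0 and self.prefix_maxend[i] > pos0:
            if self.ivs[i].end > pos0:
                hits.append(self.ivs[i])
            i -= 1
        return hits

    def nearest(self, pos0: int) -> tuple[str, int]:
        inside = self.containing(pos0)
        if inside:
            return (min(iv.feature_id for iv in inside), 0)
        candidates: list[str] = []
        best = None
        # nearest interval entirely to the right: minimal start > pos0
        i = bisect_right(self.starts, pos0)
        if i < len(self.starts):
            d_right = self.starts[i] - pos0
            best = d_right
            j = bisect_right(self.starts, self.starts[i])
            candidates = [iv.feature_id for iv in self.ivs[i:j]]
        # nearest interval entirely to the left: maximal end <= pos0
        j = bisect_right(self.ends_sorted, pos0) - 1
        if j >= 0:
            d_left = pos0 - self.ends_sorted[j] + 1
            if best is None or d_left < best:
                best = d_left
                i0 = bisect_left(self.ends_sorted, self.ends_sorted[j])
                candidates = [iv.feature_id for iv in self.by_end[i0 : j + 1]]
            elif d_left == best:
                i0 = bisect_left(self.ends_sorted, self.ends_sorted[j])
                candidates.extend(iv.feature_id for iv in self.by_end[i0 : j + 1])
        assert best is not None  # class invariant: ivs non-empty
        return (min(candidates), best)


class IntervalIndex:
    """Per-chromosome searchable collection of :class:`GenomicInterval`."""

    def __init__(self, intervals: Iterable[GenomicInterval] = ()):
        ivs = list(intervals)
        for iv in ivs:
            validate_interval(iv)
        self._n = len(ivs)
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in ivs:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        self._chroms = {c: _ChromIndex(sub) for c, sub in by_chrom.items()}

    def __len__(self) -> int:
        return self._n

    def intervals(self) -> list[GenomicInterval]:
        """All indexed intervals, sorted by (chrom, start, feature_id)."""
        out: list[GenomicInterval] = []
        for c in sorted(self._chroms):
            out.extend(self._chroms[c].ivs)
        return out

    def query_point(self, p: GenomePosition) -> list[GenomicInterval]:
        """Intervals whose half-open span contains ``p`` (0-based ``p.pos - 1``).

        Unknown chromosomes yield an empty list.  Order is deterministic:
        by start, then feature_id.
        """
        ci = self._chroms.get(p.chrom)
        if ci is None:
            return []
        return ci.query_point(p.pos0)

    def overlaps(self, p: GenomePosition) -> bool:
        return bool(self.query_point(p))

    def nearest_feature(
        self, p: GenomePosition, kind: str
    ) -> Optional[tuple[str, int]]:
        """Nearest feature of ``kind`` to ``p`` as ``(feature_id, distance_bp)``.

        Distance is 0 when the point lies inside the feature, else the
        minimal gap in bp to the feature span.  Ties break by smaller
        distance then lexicographic feature_id.  Returns ``None`` when the
        chromosome carries no feature of the kind — the caller decides.
        """
        if kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {kind!r}")
        ci = self._chroms.get(p.chrom)
        if ci is None:
            return None
        ki = ci.by_kind.get(kind)
        if ki is None:
            return None
        return ki.nearest(p.pos0)


def build_index(intervals: Iterable[GenomicInterval]) -> IntervalIndex:
    """Build an :class:`IntervalIndex`; invalid intervals are rejected with
    the offending record identified in the error message."""
    return IntervalIndex(intervals)


def point_distance(iv: GenomicInterval, pos0: int) -> int:
    """Gap in bp between a 0-based point and a half-open span (0 if inside)."""
    if pos0 < iv.start:
        return iv.start - pos0
    if pos0 >= iv.end:
        return pos0 - iv.end + 1
    return 0
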