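"""Enrichment of functional categories against a background variant set.

The core statistic is the two-sided Fisher exact test on the 2x2 table

    a = catalog & annotated      b = catalog & not annotated
    c = background & annotated   d = background & not annotated

with fold-change (a/(a+b)) / (c/(c+d)).  Two-sidedness follows the
hypergeometric-summation definition (the convention of R's ``fisher.test``
and SciPy): the P value is the total probability of all tables with the
observed margins whose probability does not exceed that of the observed
table, the comparison made with a relative slack of 1e-7 to absorb
floating-point ties.  For vanishingly small P the log10 P value is also
reported, so extreme significances never collapse onto an arbitrary
underflow bound.

The module also provides the power stratification: catalog records are cut
into equal-occupancy -log10(P) bins and the per-bin annotated fraction is
correlated (Pearson) with the bin midpoint, probing whether stronger
associations are more often functional.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats as _sps

REL_TIE_TOLERANCE = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """Counts a, b, c, d; rows are catalog/background, columns annotated/not."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def row_margins(self) -> tuple[int, int]:
        return (self.a + self.b, self.c + self.d)

    @property
    def col_margins(self) -> tuple[int, int]:
        return (self.a + self.c, self.b + self.d)

    @property
    def fold_change(self) -> Optional[float]:
        """(a/(a+b)) / (c/(c+d)); None (reported NA) when c == 0."""
        if self.a + self.b == 0 or self.c + self.d == 0 or self.c == 0:
            return None
        return (self.a / (self.a + self.b)) / (self.c / (self.c + self.d))


def _logfact(n: int) -> np.ndarray:
    return np.concatenate(([0.0], np.cumsum(np.log(np.arange(1, n + 1)))))


def fisher_pvalues_for_margins(n: int, r: int, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Fisher P for every table with total ``n``, first-row margin
    ``r`` and first-column margin ``k``.

    Returns ``(support, pvalues)`` where ``support`` holds the feasible
    values of cell ``a``.  Sharing the per-margin probability grid makes
    sweeps over many tables (and the exhaustive oracle comparison) cheap.
    """
    if not (0 < r < n and 0 < k < n):
        raise ValueError("margins must be strictly inside (0, n)")
    lf = _logfact(n)
    lo = max(0, r + k - n)
    hi = min(r, k)
    support = np.arange(lo, hi + 1)
    # log P(a) = log C(r, a) + log C(n-r, k-a) - log C(n, k)
    logpmf = (
        lf[r]
        - lf[support]
        - lf[r - support]
        + lf[n - r]
        - lf[k - support]
        - lf[n - r - k + support]
        - (lf[n] - lf[k] - lf[n - k])
    )
    pmf = np.exp(logpmf - logpmf.max())
    order = np.argsort(pmf, kind="stable")
    csum = np.cumsum(pmf[order])
    # for each observed table: sum of pmf over tables with pmf <= obs*(1+tol)
    idx = np.searchsorted(pmf[order], pmf * (1.0 + REL_TIE_TOLERANCE), side="right")
    total = csum[-1]
    pvals = np.minimum(csum[idx - 1] / total, 1.0)
    return support, pvals


def fisher_exact_2x2(t: ContingencyTable) -> float:
    """Two-sided exact P for a 2x2 table; every margin must be positive."""
    r, s = t.row_margins
    k, m = t.col_margins
    if r == 0 or s == 0 or k == 0 or m == 0:
        raise ValueError(f"zero margin in table {t}")
    support, pvals = fisher_pvalues_for_margins(t.n, r, k)
    return float(pvals[int(t.a) - int(support[0])])


def fisher_log10_p(t: ContingencyTable) -> float:
    """log10 of the two-sided exact P, stable far below float underflow."""
    return _fisher_with_log(t)[1]


@dataclass
class EnrichmentResult:
    category: str
    table: ContingencyTable
    fold_change: Optional[float]
    p_value: float
    log10_p: float
    q_value: Optional[float] = None


@dataclass
class PowerBin:
    """One equal-occupancy stratum of the catalog, on the -log10(P) scale."""

    neglog10p_lo: float
    neglog10p_hi: float
    n: int
    annotated_fraction: float

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.neglog10p_lo + self.neglog10p_hi)


@dataclass
class PowerStratification:
    bins: list[PowerBin]
    pearson_r: float
    pearson_p: float


TIER_FLAGS = ("at_least_1", "more_than_1", "all3")


def category_enrichment(
    catalog_annotations: Iterable,
    background_annotations: Iterable,
    categories: Sequence[str] = ("motif", "promoter_enhancer", "eqtl", "at_least_1"),
) -> list[EnrichmentResult]:
    """One :class:`EnrichmentResult` per category, catalog vs background.

    Both inputs are collections of annotations exposing ``flag(name)`` plus
    the tier properties; the background is used as-is (catalog SNPs are not
    removed from it — the standard whole-genome background convention).
    """
    cat = list(catalog_annotations)
    bg = list(background_annotations)
    if not bg:
        raise ValueError("empty background annotation set")
    if not cat:
        raise ValueError("empty catalog annotation set")

    def flag_of(ann, category: str) -> bool:
        if category in TIER_FLAGS:
            return bool(getattr(ann, category))
        return bool(ann.flag(category))

    results = []
    for category in categories:
        a = sum(flag_of(x, category) for x in cat)
        c = sum(flag_of(x, category) for x in bg)
        t = ContingencyTable(a=a, b=len(cat) - a, c=c, d=len(bg) - c)
        p, log10p = _fisher_with_log(t)
        results.append(
            EnrichmentResult(
                category=category,
                table=t,
                fold_change=t.fold_change,
                p_value=p,
                log10_p=log10p,
            )
        )
    return results


def _fisher_with_log(t: ContingencyTable) -> tuple[float, float]:
    """(p, log10 p); p underflows to 0.0 gracefully while log10 p stays exact."""
    r, s = t.row_margins
    k, m = t.col_margins
    if r == 0 or s == 0 or k == 0 or m == 0:
        raise ValueError(f"zero margin in table {t}")
    n = t.n
    lf = _logfact(n)
    lo = max(0, r + k - n)
    hi = min(r, k)
    support = np.arange(lo, hi + 1)
    logpmf = (
        lf[r] - lf[support] - lf[r - support]
        + lf[n - r] - lf[k - support] - lf[n - r - k + support]
        - (lf[n] - lf[k] - lf[n - k])
    )
    obs = logpmf[int(t.a) - lo]
    mask = logpmf <= obs + math.log1p(REL_TIE_TOLERANCE)
    log_p = float(_logsumexp(logpmf[mask]))
    log_p = min(log_p, 0.0)
    return math.exp(log_p), log_p / math.log(10.0)


def _logsumexp(x: np.ndarray) -> float:
    m = float(np.max(x))
    return m + math.log(float(np.sum(np.exp(x - m))))


def adjust_bh(results: Sequence[EnrichmentResult]) -> None:
    """Benjamini-Hochberg q-values across categories, stored in-place.
    Off by default in reports; enrichment figures conventionally show raw P."""
    from statsmodels.stats.multitest import multipletests

    if not results:
        return
    _, q, _, _ = multipletests([r.p_value for r in results], method="fdr_bh")
    for r, qv in zip(results, q):
        r.q_value = float(qv)


def power_stratified_enrichment(
    p_values: Sequence[float],
    annotated: Sequence[bool],
    n_bins: int = 10,
    min_bin_size: int = 5,
) -> PowerStratification:
    """Bin records by -log10(P) into equal-occupancy strata and correlate
    the per-bin annotated fraction with the bin midpoint (Pearson).

    Raises when ``n_bins < 2`` or any bin would hold fewer than
    ``min_bin_size`` records — use fewer bins.
    """
    p = np.asarray(p_values, dtype=float)
    flags = np.asarray(annotated, dtype=bool)
    if p.shape != flags.shape or p.ndim != 1:
        raise ValueError("p_values and annotated must be equal-length 1-D sequences")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p values must lie in (0, 1]")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if len(p) < n_bins * min_bin_size:
        raise ValueError(
            f"{len(p)} records cannot fill {n_bins} bins of >= {min_bin_size}; use fewer bins"
        )
    x = -np.log10(p)
    order = np.argsort(x, kind="stable")
    chunks = np.array_split(order, n_bins)
    bins = []
    for chunk in chunks:
        if len(chunk) < min_bin_size:
            raise ValueError(f"a stratum holds {len(chunk)} < {min_bin_size} records; use fewer bins")
        xs = x[chunk]
        bins.append(
            PowerBin(
                neglog10p_lo=float(xs.min()),
                neglog10p_hi=float(xs.max()),
                n=len(chunk),
                annotated_fraction=float(flags[chunk].mean()),
            )
        )
    mids = np.array([b.midpoint for b in bins])
    fracs = np.array([b.annotated_fraction for b in bins])
    if np.allclose(fracs, fracs[0]) or np.allclose(mids, mids[0]):
        r_val, p_val = 0.0, 1.0
    else:
        r_val, p_val = _sps.pearsonr(mids, fracs)
    return PowerStratification(bins=bins, pearson_r=float(r_val), pearson_p=float(p_val))


ENRICHMENT_HEADER = ["category", "a", "b", "c", "d", "fold_change", "p_value", "log10_p"]


def enrichment_rows(results: Iterable[EnrichmentResult]) -> list[list]:
    return [
        [r.category, r.table.a, r.table.b, r.table.c, r.table.d, r.fold_change, r.p_value, r.log10_p]
        for r in results
    ]


STRATIFICATION_HEADER = ["bin", "neglog10p_lo", "neglog10p_hi", "n", "annotated_fraction"]


def stratification_rows(strat: PowerStratification) -> list[list]:
    return [
        [f"{i:02d}", b.neglog10p_lo, b.neglog10p_hi, b.n, b.annotated_fraction]
        for i, b in enumerate(strat.bins)
    ]
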