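"""Fisher exact test vs exact-integer enumeration, fold-change semantics,
and the power stratification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from regcircuits.enrichment import (
    ContingencyTable,
    category_enrichment,
    fisher_exact_2x2,
    fisher_log10_p,
    power_stratified_enrichment,
)

_TIE = 10**7  # integer mirror of the 1e-7 relative tie tolerance


def oracle_fisher(a, b, c, d):
    """Exact-rational two-sided Fisher P by full hypergeometric enumeration."""
    n, r, k = a + b + c + d, a + b, a + c
    lo, hi = max(0, r + k - n), min(r, k)
    nums = {x: math.comb(r, x) * math.comb(n - r, k - x) for x in range(lo, hi + 1)}
    obs = nums[a]
    total = math.comb(n, k)
    acc = sum(v for v in nums.values() if v * _TIE <= obs * (_TIE + 1))
    return acc / total


class TestFisher:
    def test_balanced_table_p_one(self):
        assert fisher_exact_2x2(ContingencyTable(5, 5, 5, 5)) == 1.0

    def test_extreme_table_two_tables_qualify(self):
        # only the two diagonal extremes are as improbable as the observed
        p = fisher_exact_2x2(ContingencyTable(10, 0, 0, 10))
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_exact_2x2(ContingencyTable(0, 5, 0, 5))
        with pytest.raises(ValueError, match="margin"):
            fisher_exact_2x2(ContingencyTable(0, 0, 3, 5))

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 2, 3, 4)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.tuples(*(st.integers(0, 15) for _ in range(4))))
    def test_matches_enumeration_oracle(self, cells):
        a, b, c, d = cells
        t = ContingencyTable(a, b, c, d)
        if 0 in (*t.row_margins, *t.col_margins):
            return
        assert fisher_exact_2x2(t) == pytest.approx(oracle_fisher(a, b, c, d), rel=1e-9)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.tuples(*(st.integers(1, 20) for _ in range(4))))
    def test_transpose_invariance(self, cells):
        a, b, c, d = cells
        assert fisher_exact_2x2(ContingencyTable(a, b, c, d)) == pytest.approx(
            fisher_exact_2x2(ContingencyTable(a, c, b, d)), rel=1e-9
        )

    def test_cross_check_against_scipy(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(1, 200, size=4))
            ours = fisher_exact_2x2(ContingencyTable(a, b, c, d))
            ref = sps.fisher_exact([[a, b], [c, d]])[1]
            assert ours == pytest.approx(ref, rel=1e-6)

    def test_log10_p_tracks_p_and_survives_underflow(self):
        t = ContingencyTable(30, 70, 10, 90)
        assert fisher_log10_p(t) == pytest.approx(math.log10(fisher_exact_2x2(t)), rel=1e-9)
        # a table whose P underflows double precision still yields finite log10
        extreme = ContingencyTable(4000, 1000, 100, 50_000)
        lg = fisher_log10_p(extreme)
        assert lg < -320 and math.isfinite(lg)


class _FlagSet:
    def __init__(self, flags):
        self._f = set(flags)

    def flag(self, name):
        return name in self._f

    @property
    def at_least_1(self):
        return bool(self._f)

    @property
    def more_than_1(self):
        return len(self._f) > 1

    @property
    def all3(self):
        return len(self._f) == 3


class TestCategoryEnrichment:
    def test_equal_fractions_fold_exactly_one(self):
        cat = [_FlagSet(["motif"])] * 30 + [_FlagSet([])] * 70
        bg = [_FlagSet(["motif"])] * 60 + [_FlagSet([])] * 140
        (res,) = category_enrichment(cat, bg, ["motif"])
        assert res.fold_change == 1.0

    def test_category_absent_from_catalog(self):
        cat = [_FlagSet([])] * 50
        bg = [_FlagSet(["eqtl"])] * 10 + [_FlagSet([])] * 90
        (res,) = category_enrichment(cat, bg, ["eqtl"])
        assert res.fold_change == 0.0 and 0 < res.p_value <= 1

    def test_fold_sign_tracks_fraction_difference(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            pa, pb = rng.uniform(0.05, 0.95, size=2)
            cat = [_FlagSet(["motif"] if rng.random() < pa else []) for _ in range(300)]
            bg = [_FlagSet(["motif"] if rng.random() < pb else []) for _ in range(300)]
            a = sum(x.flag("motif") for x in cat)
            c = sum(x.flag("motif") for x in bg)
            if a == 0 or c == 0 or a == 300 or c == 300:
                continue
            (res,) = category_enrichment(cat, bg, ["motif"])
            assert (res.fold_change > 1) == (a / 300 > c / 300)

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            category_enrichment([_FlagSet([])], [])

    def test_planted_fold_recovered_within_ci(self):
        """Catalog planted at 30% vs background 10%: estimated fold stays
        inside the 99% CI of the planted 3.0 ratio at n = 2,000 each."""
        rng = np.random.default_rng(17)
        cat = [_FlagSet(["promoter_enhancer"] if rng.random() < 0.30 else []) for _ in range(2000)]
        bg = [_FlagSet(["promoter_enhancer"] if rng.random() < 0.10 else []) for _ in range(2000)]
        (res,) = category_enrichment(cat, bg, ["promoter_enhancer"])
        t = res.table
        se = math.sqrt((1 - t.a / 2000) / t.a + (1 - t.c / 2000) / t.c)
        assert res.fold_change * math.exp(-2.576 * se) <= 3.0 <= res.fold_change * math.exp(2.576 * se)


class TestPowerStratification:
    def test_null_flat_annotation_low_correlation(self):
        rng = np.random.default_rng(19)
        p = rng.uniform(1e-8, 0.05, size=5000)
        flags = rng.random(5000) < 0.4
        strat = power_stratified_enrichment(p, flags, n_bins=10)
        assert abs(strat.pearson_r) < 0.2

    def test_planted_trend_detected(self):
        rng = np.random.default_rng(23)
        x = rng.uniform(1.3, 8.0, size=5000)
        prob = 0.2 + 0.05 * (x - x.mean())
        flags = rng.random(5000) < prob
        strat = power_stratified_enrichment(10.0 ** -x, flags, n_bins=10)
        assert strat.pearson_r > 0 and strat.pearson_p < 0.05

    def test_two_bins_perfect_step_r_one(self):
        p = [0.5] * 10 + [1e-6] * 10
        flags = [False] * 10 + [True] * 10
        strat = power_stratified_enrichment(p, flags, n_bins=2)
        assert strat.pearson_r == pytest.approx(1.0)

    def test_bins_partition_catalog(self):
        rng = np.random.default_rng(29)
        p = rng.uniform(1e-6, 1.0, size=500)
        strat = power_stratified_enrichment(p, rng.random(500) < 0.5, n_bins=7)
        assert sum(b.n for b in strat.bins) == 500
        assert all(0 <= b.annotated_fraction <= 1 for b in strat.bins)

    def test_too_few_records_advises_fewer_bins(self):
        with pytest.raises(ValueError, match="fewer bins"):
            power_stratified_enrichment([0.1] * 12, [True] * 12, n_bins=10)
        with pytest.raises(ValueError, match="n_bins"):
            power_stratified_enrichment([0.1] * 100, [True] * 100, n_bins=1)
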