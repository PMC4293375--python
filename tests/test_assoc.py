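"""The OLS engine, p-value lookup tables, filters and the streaming scan."""

import math

import numpy as np
import pytest
from scipy import stats

from conftest import naive_ols
from ratioscan import (
    FilterSpec,
    PhenotypeMatrix,
    batch_associate,
    build_pvalue_table,
    fit_simple_ols,
    passes_filters,
    pvalue_exact,
    pvalue_interpolated,
)
from ratioscan.assoc import AssociationResult, PValueTableCache
from ratioscan.gen_io import MarkerRecord, allele_stats


def make_pm(values, names=None):
    values = np.asarray(values, float)
    if values.ndim == 1:
        values = values[:, None]
    names = names or [f"t{j}" for j in range(values.shape[1])]
    return PhenotypeMatrix([f"id{i}" for i in range(values.shape[0])],
                           names, values)


def make_marker(dosages, snp_id="snp1"):
    return MarkerRecord(snp_id, "rs_" + snp_id, 1000, "A", "G",
                        np.asarray(dosages, float))


class TestFitSimpleOLS:
    def test_textbook_example(self):
        x = [0, 1, 2, 0, 1, 2]
        y = [0.1, 0.9, 2.2, -0.1, 1.1, 1.8]
        fit = fit_simple_ols(x, y)
        b, se, p, n = naive_ols(x, y)
        assert fit.beta == pytest.approx(b, rel=1e-10)
        assert fit.se == pytest.approx(se, rel=1e-10)
        assert fit.p == pytest.approx(p, rel=1e-10)
        assert fit.n_used == n and fit.df == 4

    def test_perfect_fit_is_degenerate(self):
        fit = fit_simple_ols([0, 1, 2], [0, 1, 2])
        assert fit.beta == pytest.approx(1.0)
        assert fit.se == 0.0
        assert fit.status == "degenerate"
        assert math.isnan(fit.p)

    def test_constant_trait_degenerate_zero_slope(self):
        fit = fit_simple_ols([0, 1, 2, 1], [3.0, 3.0, 3.0, 3.0])
        assert fit.beta == 0.0
        assert fit.status == "degenerate"

    def test_monomorphic_marker_untestable(self):
        fit = fit_simple_ols([1, 1, 1, 1], [0.1, 0.5, 0.2, 0.9])
        assert fit.status == "untestable"

    def test_too_few_pairs_untestable(self):
        fit = fit_simple_ols([0.0, 1.0, np.nan], [1.0, 2.0, 3.0])
        assert fit.status == "untestable"
        assert fit.n_used == 2

    @pytest.mark.parametrize("n", [10, 100, 1000])
    def test_matches_oracle_with_missingness(self, rng, n):
        for _ in range(30):
            x = rng.binomial(2, 0.3, size=n).astype(float)
            y = 0.2 * x + rng.normal(size=n)
            drop = rng.random(n) < 0.15
            y[drop] = np.nan
            if (~np.isnan(y)).sum() < 5 or np.nanstd(x[~np.isnan(y)]) == 0:
                continue
            fit = fit_simple_ols(x, y)
            b, se, p, nn = naive_ols(x, y)
            assert fit.beta == pytest.approx(b, rel=1e-10)
            assert fit.se == pytest.approx(se, rel=1e-10)
            assert fit.p == pytest.approx(p, rel=1e-10)
            assert fit.n_used == nn

    def test_missing_equals_deletion(self, rng):
        x = rng.binomial(2, 0.4, 60).astype(float)
        y = 0.5 * x + rng.normal(size=60)
        y_miss = y.copy()
        y_miss[10] = np.nan
        a = fit_simple_ols(x, y_miss)
        b = fit_simple_ols(np.delete(x, 10), np.delete(y, 10))
        assert a.beta == b.beta and a.se == b.se and a.p == b.p

    def test_permutation_invariance(self, rng):
        x = rng.binomial(2, 0.4, 80).astype(float)
        y = 0.3 * x + rng.normal(size=80)
        perm = rng.permutation(80)
        a, b = fit_simple_ols(x, y), fit_simple_ols(x[perm], y[perm])
        assert a.beta == pytest.approx(b.beta, rel=1e-12)
        assert a.p == pytest.approx(b.p, rel=1e-12)


class TestPValues:
    def test_t_zero_gives_one(self):
        assert pvalue_exact(0.0, 10) == 1.0

    def test_normal_limit(self):
        assert pvalue_exact(1.959964, 10**6) == pytest.approx(0.05, rel=1e-4)

    def test_quantile_oracle(self):
        # t_{0.975, 2} = 4.302653
        assert pvalue_exact(4.302653, 2) == pytest.approx(0.05, rel=1e-5)
        q = stats.t.ppf(0.995, 7)
        assert pvalue_exact(q, 7) == pytest.approx(0.01, rel=1e-10)

    def test_extreme_tail_representable(self):
        p = pvalue_exact(40.0, 998)
        assert 0.0 < p < 1e-200

    def test_df_below_one_errors(self):
        with pytest.raises(ValueError):
            pvalue_exact(1.0, 0)

    def test_symmetric_in_t_sign(self):
        assert pvalue_exact(-3.2, 9) == pvalue_exact(3.2, 9)

    def test_monotone_decreasing_in_abs_t(self):
        ts = np.linspace(0, 20, 200)
        ps = [pvalue_exact(t, 30) for t in ts]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestPValueTable:
    def test_grid_point_matches_exact(self):
        table = build_pvalue_table(df=10, t_max=10, step=0.5)
        assert pvalue_interpolated(2.5, table) == pytest.approx(
            pvalue_exact(2.5, 10), rel=1e-12)

    def test_t_zero(self):
        table = build_pvalue_table(df=10)
        assert pvalue_interpolated(0.0, table) == 1.0

    def test_beyond_grid_falls_back_to_exact(self):
        table = build_pvalue_table(df=10, t_max=5, step=0.1)
        assert pvalue_interpolated(7.3, table) == pvalue_exact(7.3, 10)

    @pytest.mark.parametrize("df", [8, 98, 998])
    def test_interpolation_within_one_percent(self, rng, df):
        table = build_pvalue_table(df)
        ts = rng.uniform(0, 40, size=2000)
        for t in ts:
            approx = pvalue_interpolated(t, table)
            exact = pvalue_exact(t, df)
            assert approx == pytest.approx(exact, rel=0.01)

    def test_cache_reuses_tables(self):
        cache = PValueTableCache()
        cache(1.0, 50)
        table = cache._tables[50]
        cache(2.0, 50)
        assert cache._tables[50] is table

    def test_invalid_build_params(self):
        with pytest.raises(ValueError):
            build_pvalue_table(10, step=0.0)
        with pytest.raises(ValueError):
            build_pvalue_table(10, t_max=-1.0)


class TestFilters:
    def make_row(self, p=0.5, mac=10.0, se=0.1, beta=1.0, status="ok"):
        from ratioscan.assoc import RegressionFit

        fit = RegressionFit(beta, se, beta / se if se else math.nan,
                            10, p, 12, status=status)
        return AssociationResult("s", "r", 1, "A", "G", "t", fit,
                                 allele_stats(np.full(6, mac / 6)))

    def test_defaults_pass_everything_testable(self):
        assert passes_filters(self.make_row(), FilterSpec())

    def test_untestable_never_passes(self):
        assert not passes_filters(self.make_row(status="untestable"),
                                  FilterSpec())

    def test_mac_threshold(self):
        row = self.make_row(mac=5.0)
        assert not passes_filters(row, FilterSpec(mac_min=6))
        assert passes_filters(row, FilterSpec(mac_min=5))

    def test_p_max_inclusive(self):
        assert passes_filters(self.make_row(p=0.05),
                              FilterSpec(p_max=0.05))
        assert not passes_filters(self.make_row(p=0.050001),
                                  FilterSpec(p_max=0.05))

    def test_se_and_beta_thresholds(self):
        row = self.make_row(se=0.2, beta=0.3)
        assert not passes_filters(row, FilterSpec(se_max=0.1))
        assert not passes_filters(row, FilterSpec(abs_beta_min=0.5))
        assert passes_filters(row, FilterSpec(se_max=0.2, abs_beta_min=0.3))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            FilterSpec(p_max=0.0)
        with pytest.raises(ValueError):
            FilterSpec(mac_min=-1)


class TestBatchAssociate:
    def test_full_cartesian_product_without_filters(self, rng):
        markers = [make_marker(rng.binomial(2, 0.4, 30), f"snp{i}")
                   for i in range(5)]
        pm = make_pm(rng.normal(size=(30, 4)))
        rows = list(batch_associate(iter(markers), pm))
        assert len(rows) == 5 * 4
        assert {(r.snp_id, r.trait_name) for r in rows} == {
            (f"snp{i}", f"t{j}") for i in range(5) for j in range(4)}

    def test_matches_single_trait_runs(self, rng):
        x = rng.binomial(2, 0.3, 50).astype(float)
        values = rng.normal(size=(50, 3))
        values[rng.random((50, 3)) < 0.2] = np.nan
        pm = make_pm(values)
        rows = {r.trait_name: r.fit
                for r in batch_associate(iter([make_marker(x)]), pm)}
        for j, name in enumerate(pm.trait_names):
            solo = fit_simple_ols(x, values[:, j])
            if not solo.testable:
                assert name not in rows
                continue
            assert rows[name].beta == pytest.approx(solo.beta, rel=1e-12)
            assert rows[name].se == pytest.approx(solo.se, rel=1e-12)
            assert rows[name].p == pytest.approx(solo.p, rel=1e-12)
            assert rows[name].n_used == solo.n_used

    def test_planted_effect_has_smallest_p(self, rng):
        n = 500
        markers = [make_marker(rng.binomial(2, 0.3, n), f"snp{i}")
                   for i in range(20)]
        y = 0.5 * markers[7].dosages + rng.normal(size=n)
        pm = make_pm(y, ["trait"])
        rows = list(batch_associate(iter(markers), pm))
        best = min(rows, key=lambda r: r.fit.p)
        assert best.snp_id == "snp7"
        assert best.fit.p < 1e-8

    def test_mac_short_circuit(self, rng):
        rare = make_marker([0.0] * 29 + [1.0])  # mac = 1
        common = make_marker(rng.binomial(2, 0.4, 30), "snp2")
        pm = make_pm(rng.normal(size=(30, 2)))
        rows = list(batch_associate(iter([rare, common]), pm,
                                    FilterSpec(mac_min=5)))
        assert {r.snp_id for r in rows} == {"snp2"}

    def test_untestable_to_side_channel(self, rng):
        mono = make_marker(np.ones(30), "mono")
        pm = make_pm(rng.normal(size=(30, 2)))
        sink = []
        rows = list(batch_associate(iter([mono]), pm,
                                    untestable_sink=sink))
        assert rows == []
        assert len(sink) == 2
        assert all(not r.fit.testable for r in sink)

    def test_sample_count_mismatch_is_hard_error(self, rng):
        marker = make_marker(rng.binomial(2, 0.4, 10))
        pm = make_pm(rng.normal(size=(12, 1)))
        with pytest.raises(ValueError, match="snp1"):
            list(batch_associate(iter([marker]), pm))

    def test_interp_mode_close_to_exact(self, rng):
        markers = [make_marker(rng.binomial(2, 0.3, 100), f"snp{i}")
                   for i in range(10)]
        pm = make_pm(rng.normal(size=(100, 2)))
        exact = list(batch_associate(iter(markers), pm, pvalue_mode="exact"))
        interp = list(batch_associate(iter(markers), pm,
                                      pvalue_mode="interp"))
        for a, b in zip(exact, interp):
            assert b.fit.p == pytest.approx(a.fit.p, rel=0.01)
            assert b.fit.beta == a.fit.beta
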