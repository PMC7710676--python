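from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from enhburden.assoc import (
    SkatOConfig,
    beta_weight,
    cohort_maf,
    fit_null,
    select_a2,
    skat_p,
    skat_q,
    skato_p,
    tune_a2,
)
from enhburden.assoc.skat import impute_missing
from enhburden.errors import ConfigError, DegenerateSetError
from enhburden.io_formats import SampleTable


@pytest.fixture
def small_cohort():
    rng = np.random.default_rng(42)
    n = 300
    y = np.r_[np.ones(150), np.zeros(150)]
    st = SampleTable(sample_ids=[f"s{i}" for i in range(n)], status=y)
    null = fit_null(st)
    G = rng.binomial(2, rng.uniform(0.01, 0.1, size=10)[None, :], size=(n, 10))
    G = G.astype(float)
    w = beta_weight(cohort_maf(G), 1, 25)
    return G, w, null


class TestSkatQ:
    def test_four_sample_arithmetic_oracle(self):
        st = SampleTable(sample_ids=list("abcd"), status=np.array([1, 1, 0, 0]))
        null = fit_null(st)
        spec = skat_q(np.array([[1], [0], [0], [0]], float), np.ones(1), null)
        # r = (.5,.5,-.5,-.5); Q = (g'r)^2 = 0.25
        assert spec.q == pytest.approx(0.25)

    def test_duplicate_column_matches_dense_oracle(self, small_cohort):
        G, w, null = small_cohort
        g = G[:, :1]
        Gdup = np.hstack([g, g])
        spec = skat_q(Gdup, np.ones(2), null)
        r = null.residuals
        K_full = Gdup @ Gdup.T  # W = I
        q_oracle = float(r @ K_full @ r)
        assert spec.q == pytest.approx(q_oracle, rel=1e-10)
        # eigenvalue oracle: dense projected kernel
        d = null.variance_weights
        X = null.X
        P0 = np.diag(d) - (X * d[:, None]) @ np.linalg.solve(
            X.T @ (X * d[:, None]), (X * d[:, None]).T
        )
        lam_oracle = np.linalg.eigvalsh(Gdup.T @ P0 @ Gdup)
        lam_oracle = np.sort(lam_oracle[lam_oracle > 1e-10])[::-1]
        assert spec.lambdas == pytest.approx(lam_oracle, rel=1e-8)

    def test_zero_weights_give_zero_q(self, small_cohort):
        G, _, null = small_cohort
        spec = skat_q(G, np.zeros(G.shape[1]), null)
        assert spec.q == 0.0

    def test_degenerate_all_zero_dosages(self, small_cohort):
        _, _, null = small_cohort
        with pytest.raises(DegenerateSetError):
            skat_q(np.zeros((300, 3)), np.ones(3), null)

    def test_missing_dosages_mean_imputed(self, small_cohort):
        G, w, null = small_cohort
        Gm = G.copy()
        Gm[0, 0] = np.nan
        expected = G.copy()
        expected[0, 0] = np.nanmean(Gm[:, 0])
        spec_a = skat_q(Gm, w, null)
        spec_b = skat_q(expected, w, null)
        assert spec_a.q == pytest.approx(spec_b.q)

    def test_impute_missing_no_nan(self):
        G = np.array([[1.0, np.nan], [np.nan, 0.0], [0.0, 2.0]])
        out = impute_missing(G)
        assert not np.isnan(out).any()
        assert out[0, 1] == pytest.approx(1.0)


class TestSkatO:
    def test_grid_zero_equals_skat(self, small_cohort):
        G, w, null = small_cohort
        p_skat, _ = skat_p(G, w, null)
        res = skato_p(G, w, null, SkatOConfig(rho_grid=(0.0,)))
        assert res.p == pytest.approx(p_skat, rel=1e-12)

    def test_grid_one_equals_burden_score_test(self, small_cohort):
        G, w, null = small_cohort
        b = (G * w).sum(axis=1)
        s = float(b @ null.residuals)
        d = null.variance_weights
        X = null.X
        proj = b - X @ np.linalg.solve(X.T @ (X * d[:, None]), X.T @ (d * b))
        var = float(np.sum(d * proj * b))
        p_burden = stats.chi2.sf(s * s / var, 1)
        res = skato_p(G, w, null, SkatOConfig(rho_grid=(1.0,)))
        assert res.p == pytest.approx(p_burden, rel=1e-8)

    def test_full_grid_bounded_by_per_rho(self, small_cohort):
        G, w, null = small_cohort
        res = skato_p(G, w, null)
        pmin = min(res.p_per_rho.values())
        assert pmin <= res.p <= min(1.0, pmin * len(res.p_per_rho))

    def test_rho_min_is_argmin(self, small_cohort):
        G, w, null = small_cohort
        res = skato_p(G, w, null)
        assert res.p_per_rho[res.rho_min] == min(res.p_per_rho.values())

    def test_single_variant_set(self, small_cohort):
        G, _, null = small_cohort
        res = skato_p(G[:, :1], np.ones(1), null)
        assert 0 < res.p <= 1

    def test_degenerate_set_raises(self, small_cohort):
        _, _, null = small_cohort
        with pytest.raises(DegenerateSetError):
            skato_p(np.zeros((300, 2)), np.ones(2), null)

    def test_config_requires_bracketing_grid(self):
        with pytest.raises(ConfigError):
            SkatOConfig(rho_grid=(0.0, 0.5))

    def test_config_rejects_out_of_range(self):
        with pytest.raises(ConfigError):
            SkatOConfig(rho_grid=(0.0, 1.5, 1.0))


class TestNullUniformity:
    def test_ks_uniform_over_replicates(self, null_skato_battery):
        # 2,000 null replicates; K-S must not reject at alpha = 0.01
        ks = stats.kstest(null_skato_battery.pvalues, "uniform")
        assert ks.pvalue > 0.01

    def test_type_i_error_at_both_levels(self, null_skato_battery):
        p = null_skato_battery.pvalues
        n = p.size
        for alpha in (0.05, 0.01):
            k = int((p <= alpha).sum())
            lo = stats.binom.ppf(0.005, n, alpha) / n
            hi = stats.binom.ppf(0.995, n, alpha) / n
            assert lo <= k / n <= hi


class TestPower:
    def test_planted_signal_beats_null_rate(
        self, planted_skato_battery, null_skato_battery
    ):
        null_rate = float((null_skato_battery.pvalues <= 1e-3).mean())
        power = float(planted_skato_battery.table["rejection_fraction"].iloc[0])
        assert power > null_rate


class TestTuneA2:
    def test_printed_triples_select_250(self):
        assert select_a2({25.0: 0.2, 250.0: 0.003, 2500.0: 0.01}) == 250.0

    def test_tie_selects_smallest(self):
        assert select_a2({25.0: 0.05, 250.0: 0.05, 2500.0: 0.05}) == 25.0

    def test_single_element_grid(self, small_cohort):
        G, _, null = small_cohort
        best, table = tune_a2(G, null, cohort_maf(G), grid=(250.0,))
        assert best == 250.0 and set(table) == {250.0}

    def test_selected_minimises_table(self, small_cohort):
        G, _, null = small_cohort
        best, table = tune_a2(G, null, cohort_maf(G))
        assert table[best] == min(table.values())

    def test_empty_grid_raises(self, small_cohort):
        G, _, null = small_cohort
        with pytest.raises(ConfigError):
            tune_a2(G, null, cohort_maf(G), grid=())

    def test_degenerate_set_raises(self, small_cohort):
        _, _, null = small_cohort
        with pytest.raises(DegenerateSetError):
            tune_a2(np.empty((300, 0)), null, np.array([]))
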