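from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from enhburden.errors import DataError, EmptyCohortError
from enhburden.qc import (
    QcThresholds,
    differential_missingness_p,
    hwe_exact_p,
    qc_samples,
    qc_variants,
)
from .conftest import make_matrix


def hwe_enumeration_oracle(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Independent full enumeration of the exact conditional HWE test.

    Conditions on the allele counts and sums P(n_het) over all heterozygote
    counts whose probability does not exceed the observed one.
    """
    n = n_AA + n_Aa + n_aa
    n_rare = 2 * min(n_AA, n_aa) + n_Aa
    if n_rare == 0:
        return 1.0
    probs = {}
    for het in range(n_rare % 2, n_rare + 1, 2):
        rare_hom = (n_rare - het) // 2
        common_hom = n - het - rare_hom
        if common_hom < 0:
            continue
        probs[het] = (
            2**het
            * math.factorial(n)
            / (
                math.factorial(het)
                * math.factorial(rare_hom)
                * math.factorial(common_hom)
            )
        )
    total = sum(probs.values())
    obs = probs[n_Aa]
    return min(sum(v for v in probs.values() if v <= obs * (1 + 1e-12)) / total, 1.0)


class TestHweExact:
    def test_equilibrium_counts(self):
        assert hwe_exact_p(25, 50, 25) == pytest.approx(1.0)

    def test_monomorphic_alt(self):
        assert hwe_exact_p(0, 0, 10) == 1.0

    def test_extreme_het_deficit(self):
        assert hwe_exact_p(50, 0, 50) < 1e-25

    def test_all_zero_raises(self):
        with pytest.raises(DataError):
            hwe_exact_p(0, 0, 0)

    def test_negative_raises(self):
        with pytest.raises(DataError):
            hwe_exact_p(-1, 2, 3)

    @settings(max_examples=150, deadline=None)
    @given(
        st.integers(0, 60), st.integers(0, 60), st.integers(0, 60)
    )
    def test_agrees_with_enumeration_oracle(self, n_aa, n_ab, n_bb):
        # tables with up to 200 alleles (<= 120 here)
        if n_aa + n_ab + n_bb == 0:
            return
        assert hwe_exact_p(n_aa, n_ab, n_bb) == pytest.approx(
            hwe_enumeration_oracle(n_aa, n_ab, n_bb), rel=1e-9
        )


def fisher_tail_oracle(miss_case, n_case, miss_ctrl, n_ctrl) -> float:
    """Two-sided Fisher p by hypergeometric enumeration."""
    total_miss = miss_case + miss_ctrl
    n = n_case + n_ctrl
    def table_prob(k):
        return (
            math.comb(n_case, k)
            * math.comb(n_ctrl, total_miss - k)
            / math.comb(n, total_miss)
        )
    lo = max(0, total_miss - n_ctrl)
    hi = min(n_case, total_miss)
    obs = table_prob(miss_case)
    return min(
        sum(table_prob(k) for k in range(lo, hi + 1) if table_prob(k) <= obs * (1 + 1e-9)),
        1.0,
    )


class TestDifferentialMissingness:
    def test_identical_rates(self):
        assert differential_missingness_p(5, 100, 5, 100) == pytest.approx(1.0)

    def test_strong_differential(self):
        p = differential_missingness_p(10, 100, 0, 100)
        assert p < 0.01
        assert p == pytest.approx(fisher_tail_oracle(10, 100, 0, 100), rel=1e-6)

    def test_degenerate_table(self):
        assert differential_missingness_p(0, 10, 0, 10) == 1.0

    def test_zero_group_raises(self):
        with pytest.raises(DataError):
            differential_missingness_p(0, 0, 1, 10)


class TestQcSamples:
    def test_high_missingness_excluded(self):
        dos = np.zeros((3, 20))
        dos[0, :3] = np.nan  # 15% missing
        gm, st_tab = make_matrix(dos, status=[1, 1, 0])
        out, st2, report = qc_samples(gm, st_tab)
        assert out.sample_ids == ["S1", "S2"]
        assert report.excluded_samples == [("S0", "missingness")]

    def test_boundary_exactly_10pct_retained(self):
        dos = np.zeros((2, 20))
        dos[0, :2] = np.nan  # exactly 10%
        gm, st_tab = make_matrix(dos, status=[1, 0])
        out, _, report = qc_samples(gm, st_tab)
        assert out.n_samples == 2 and report.n_excluded == 0

    def test_clean_sample_retained(self):
        gm, st_tab = make_matrix(np.zeros((2, 5)), status=[1, 0])
        out, _, report = qc_samples(gm, st_tab)
        assert out.n_samples == 2

    def test_all_removed_raises(self):
        dos = np.full((2, 4), np.nan)
        gm, st_tab = make_matrix(dos, status=[1, 0])
        with pytest.raises(EmptyCohortError):
            qc_samples(gm, st_tab)


class TestQcVariants:
    def _cohort(self, cols, status):
        return make_matrix(np.array(cols, dtype=float).T, status=status)

    def test_hwe_equilibrium_retained(self):
        # controls with perfect HW proportions 25/50/25; plus het cases
        ctrl = [0] * 25 + [1] * 50 + [2] * 25
        case = [0, 1]
        gm, st_tab = self._cohort([case + ctrl], [1] * 2 + [0] * 100)
        out, report = qc_variants(gm, st_tab)
        assert out.n_variants == 1 and report.n_excluded == 0

    def test_hwe_violation_removed(self):
        ctrl = [0] * 50 + [2] * 50
        gm, st_tab = self._cohort([[1, 1] + ctrl], [1] * 2 + [0] * 100)
        out, report = qc_variants(gm, st_tab)
        assert out.n_variants == 0
        assert report.excluded_variants[0][1] == "hwe"

    def test_missingness_above_5pct_removed(self):
        col = [np.nan] * 6 + [0, 1] * 47  # 6% missing of 100
        gm, st_tab = self._cohort([col], [1] * 50 + [0] * 50)
        out, report = qc_variants(gm, st_tab)
        assert report.excluded_variants[0][1] == "missingness"

    def test_monomorphic_removed(self):
        gm, st_tab = self._cohort([[0, 0, 0, 0]], [1, 1, 0, 0])
        out, report = qc_variants(gm, st_tab)
        assert out.n_variants == 0
        assert report.excluded_variants[0][1] == "monomorphic"

    def test_no_controls_skips_hwe_with_warning(self):
        gm, st_tab = self._cohort([[0, 1, 1, 0]], [1, 1, 1, 1])
        out, report = qc_variants(gm, st_tab)
        assert any("HWE" in w for w in report.warnings)

    def test_counts_sum_to_total(self):
        cols = [
            [0, 1, 0, 1] * 25,          # fine
            [0] * 100,                  # monomorphic
            [np.nan] * 10 + [0, 1] * 45,  # missingness
        ]
        gm, st_tab = self._cohort(cols, [1] * 50 + [0] * 50)
        out, report = qc_variants(gm, st_tab)
        assert sum(report.counts.values()) == len(report.excluded_variants) == 2

    def test_rerun_is_stable(self):
        cols = [[0, 1, 0, 1] * 25, [np.nan] * 10 + [0, 1] * 45]
        gm, st_tab = self._cohort(cols, [1] * 50 + [0] * 50)
        once, _ = qc_variants(gm, st_tab)
        twice, report = qc_variants(once, st_tab)
        assert twice.n_variants == once.n_variants and report.n_excluded == 0

    def test_depth_outlier_removed(self):
        import dataclasses

        # a single 6-sd outlier needs sqrt(n_variants-1) > 6, so use 101 variants
        rng = np.random.default_rng(0)
        cols = rng.binomial(2, 0.5, size=(101, 100)).tolist()
        gm, st_tab = self._cohort(cols, [1] * 50 + [0] * 50)
        depths = [40.0] * 100 + [400.0]
        gm.variants = [
            dataclasses.replace(v, mean_depth=d) for v, d in zip(gm.variants, depths)
        ]
        out, report = qc_variants(gm, st_tab)
        assert ("depth" in dict(report.counts)) and report.counts["depth"] == 1
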