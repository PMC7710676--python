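"""Carrier counts, risk ratios, inflation diagnostics and multiple testing."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ..errors import DataError
from ..io_formats import GenotypeMatrix, SampleTable

__all__ = [
    "BurdenTestResult",
    "CarrierStats",
    "InflationStats",
    "carrier_stats",
    "risk_ratio",
    "inflation",
    "qq_points",
    "adjust_multiple",
    "CHI2_1DF_MEDIAN",
]

#: Median of the 1-df chi-square distribution, the lambda-GC denominator.
CHI2_1DF_MEDIAN = 0.4549364


@dataclass
class BurdenTestResult:
    """One result row: a set's statistic, p, carrier summary and flags."""

    set_id: str
    test: str  # skat | skato | firth
    statistic: float
    p: float
    n_variants: int
    carriers_case: int
    carriers_ctrl: int
    n_case: int
    n_ctrl: int
    risk_ratio: float  # nan when control carriers = 0
    flavor: str = "tissue_agnostic"
    fallback_flag: bool = False
    insufficient_flag: bool = False


@dataclass
class CarrierStats:
    carriers_case: int
    carriers_ctrl: int
    n_case: int
    n_ctrl: int
    risk_ratio: float  # nan when undefined

    @property
    def case_carrier_pct(self) -> float:
        return 100.0 * self.carriers_case / self.n_case

    @property
    def ctrl_carrier_pct(self) -> float:
        return 100.0 * self.carriers_ctrl / self.n_ctrl


@dataclass
class InflationStats:
    lambda_obs: float
    lambda_1000: float
    n_case: int
    n_ctrl: int


def risk_ratio(
    carriers_case: int, n_case: int, carriers_ctrl: int, n_ctrl: int
) -> CarrierStats:
    """Carrier-frequency ratio (case freq / control freq) from raw counts."""
    if n_case <= 0 or n_ctrl <= 0:
        raise DataError("need nonzero case and control totals")
    if carriers_ctrl == 0:
        rr = np.nan  # undefined: no control carriers
    else:
        rr = (carriers_case / n_case) / (carriers_ctrl / n_ctrl)
    return CarrierStats(
        carriers_case=carriers_case,
        carriers_ctrl=carriers_ctrl,
        n_case=n_case,
        n_ctrl=n_ctrl,
        risk_ratio=rr,
    )


def carrier_stats(
    variant_idx, gm: GenotypeMatrix, samples: SampleTable
) -> CarrierStats:
    """Carrier = sample with dosage >= 1 at >= 1 retained variant."""
    idx = np.asarray(list(variant_idx), dtype=int)
    status = samples.aligned_to(gm.sample_ids).status
    if idx.size == 0:
        carrier = np.zeros(gm.n_samples, dtype=bool)
    else:
        sub = gm.dosages[:, idx]
        carrier = np.nansum(np.where(np.isnan(sub), 0.0, sub) >= 1, axis=1) > 0
    return risk_ratio(
        carriers_case=int(carrier[status == 1].sum()),
        n_case=int((status == 1).sum()),
        carriers_ctrl=int(carrier[status == 0].sum()),
        n_ctrl=int((status == 0).sum()),
    )


def inflation(pvalues, n_case: int, n_ctrl: int) -> InflationStats:
    """Genomic-control lambda and its 1,000-case/1,000-control rescaling.

    lambda_obs = median of the 1-df chi-square quantile transform of the
    p-values over the 1-df chi-square median;
    lambda_1000 = 1 + (lambda_obs - 1) * (1/n_case + 1/n_ctrl) / (2/1000).
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size < 2:
        raise DataError("need at least two p-values for inflation estimate")
    if np.any((p <= 0) | (p > 1)):
        raise DataError("p-values must lie in (0, 1]")
    chi = stats.chi2.isf(p, 1)
    lam_obs = float(np.median(chi) / CHI2_1DF_MEDIAN)
    lam_1000 = 1.0 + (lam_obs - 1.0) * (1.0 / n_case + 1.0 / n_ctrl) / (
        1.0 / 1000 + 1.0 / 1000
    )
    return InflationStats(
        lambda_obs=lam_obs, lambda_1000=lam_1000, n_case=n_case, n_ctrl=n_ctrl
    )


def qq_points(pvalues) -> pd.DataFrame:
    """Expected vs observed -log10 p pairs for a Q-Q plot (ascending p)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size < 1:
        raise DataError("need at least one p-value")
    obs = np.sort(p)
    n = p.size
    expected = np.arange(1, n + 1) / (n + 1.0)
    return pd.DataFrame(
        {
            "expected_neglog10_p": -np.log10(expected),
            "observed_neglog10_p": -np.log10(obs),
        }
    )


def adjust_multiple(results: pd.DataFrame, p_col: str = "p") -> pd.DataFrame:
    """Add Bonferroni-adjusted p and Benjamini-Hochberg q columns."""
    out = results.copy()
    p = out[p_col].to_numpy(dtype=float)
    m = p.size
    out["p_bonf"] = np.minimum(p * m, 1.0)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    out["q_bh"] = q
    return out
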