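"""Sample- and variant-level quality control.

Default thresholds: sample genotype missingness > 10% removed; variant
missingness > 5% removed; Hardy-Weinberg exact test in controls p < 1e-6
removed; differential case/control missingness (Fisher exact) p < 1e-6
removed; per-variant mean depth beyond 6 s.d. of the cohort depth
distribution removed; monomorphic variants removed. All comparators are
strict on the "bad" side.

Note: the sample-missingness rule is deliberately "exclude when missingness
EXCEEDS the threshold"; the inverted direction would exclude essentially
every sample and cannot be the intended rule.

The HWE test is the exact conditional test (chi-square asymptotics are
invalid for the rare variants this pipeline keeps), and differential
missingness uses Fisher's exact test, valid at all counts.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DataError, EmptyCohortError
from .io_formats import GenotypeMatrix, SampleTable

__all__ = [
    "QcThresholds",
    "QcReport",
    "qc_samples",
    "qc_variants",
    "hwe_exact_p",
    "differential_missingness_p",
]


@dataclass(frozen=True)
class QcThresholds:
    sample_missingness_max: float = 0.10
    variant_missingness_max: float = 0.05
    hwe_p_min: float = 1e-6
    diff_missingness_p_min: float = 1e-6
    depth_sd_max: float = 6.0


@dataclass
class QcReport:
    """Exclusions with one primary reason code each, plus per-rule counts."""

    excluded_samples: list[tuple[str, str]] = field(default_factory=list)
    excluded_variants: list[tuple[str, str]] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def add_sample(self, sample_id: str, reason: str) -> None:
        self.excluded_samples.append((sample_id, reason))
        self.counts[reason] = self.counts.get(reason, 0) + 1

    def add_variant(self, key: str, reason: str) -> None:
        self.excluded_variants.append((key, reason))
        self.counts[reason] = self.counts.get(reason, 0) + 1

    @property
    def n_excluded(self) -> int:
        return len(self.excluded_samples) + len(self.excluded_variants)

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("kind\tid\treason\n")
            for sid, reason in self.excluded_samples:
                fh.write(f"sample\t{sid}\t{reason}\n")
            for key, reason in self.excluded_variants:
                fh.write(f"variant\t{key}\t{reason}\n")
            for msg in self.warnings:
                fh.write(f"# warning: {msg}\n")


def qc_samples(
    gm: GenotypeMatrix,
    samples: SampleTable,
    thresholds: QcThresholds = QcThresholds(),
) -> tuple[GenotypeMatrix, SampleTable, QcReport]:
    """Remove samples whose genotype missingness exceeds the threshold."""
    if gm.n_samples == 0:
        raise EmptyCohortError("genotype matrix has no samples")
    report = QcReport()
    if gm.n_variants == 0:
        return gm, samples, report
    rates = gm.sample_missing_rates()
    keep = rates <= thresholds.sample_missingness_max  # boundary retained
    for i in np.flatnonzero(~keep):
        report.add_sample(gm.sample_ids[i], "missingness")
    if not keep.any():
        raise EmptyCohortError("sample QC removed every sample")
    kept_idx = np.flatnonzero(keep)
    return gm.subset(sample_idx=kept_idx), samples.subset(kept_idx), report


def qc_variants(
    gm: GenotypeMatrix,
    samples: SampleTable,
    thresholds: QcThresholds = QcThresholds(),
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply variant-level QC rules in fixed order.

    Order: missingness, HWE in controls, differential missingness, extreme
    depth, monomorphic. The first failing rule is the variant's primary
    reason code.
    """
    report = QcReport()
    if gm.n_variants == 0:
        return gm, report
    status = samples.aligned_to(gm.sample_ids).status
    is_ctrl = status == 0
    n_case = int(status.sum())
    n_ctrl = int(is_ctrl.sum())
    if n_ctrl == 0:
        report.warnings.append("no control samples: HWE stage skipped")

    depths = np.array(
        [np.nan if v.mean_depth is None else v.mean_depth for v in gm.variants]
    )
    have_depth = np.isfinite(depths)
    if have_depth.any():
        depth_mean = float(depths[have_depth].mean())
        depth_sd = float(depths[have_depth].std(ddof=0))
    else:
        report.warnings.append("no per-variant depth supplied: depth stage skipped")
        depth_mean = depth_sd = 0.0

    keep: list[int] = []
    for j, variant in enumerate(gm.variants):
        col = gm.dosages[:, j]
        missing = np.isnan(col)
        miss_rate = float(missing.mean())
        if miss_rate > thresholds.variant_missingness_max:
            report.add_variant(variant.key, "missingness")
            continue
        if n_ctrl > 0:
            ctrl = col[is_ctrl]
            called = ctrl[~np.isnan(ctrl)]
            if called.size > 0:
                n_aa = int((called == 0).sum())
                n_ab = int((called == 1).sum())
                n_bb = int((called == 2).sum())
                if hwe_exact_p(n_aa, n_ab, n_bb) < thresholds.hwe_p_min:
                    report.add_variant(variant.key, "hwe")
                    continue
        if n_case > 0 and n_ctrl > 0:
            p_diff = differential_missingness_p(
                int(missing[~is_ctrl].sum()), n_case, int(missing[is_ctrl].sum()), n_ctrl
            )
            if p_diff < thresholds.diff_missingness_p_min:
                report.add_variant(variant.key, "differential_missingness")
                continue
        if have_depth.any() and np.isfinite(depths[j]) and depth_sd > 0:
            if abs(depths[j] - depth_mean) > thresholds.depth_sd_max * depth_sd:
                report.add_variant(variant.key, "depth")
                continue
        called_all = col[~missing]
        if called_all.size == 0 or np.unique(called_all).size <= 1:
            report.add_variant(variant.key, "monomorphic")
            continue
        keep.append(j)
    return gm.subset(variant_idx=keep), report


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Sums, over all heterozygote counts compatible with the observed allele
    counts, the conditional probabilities no larger than the observed
    configuration's (two-sided exact test).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise DataError("genotype counts must be nonnegative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise DataError("all-zero genotype counts: HWE undefined")
    n_rare = 2 * min(n_AA, n_aa) + n_Aa  # minor allele count
    if n_rare == 0:
        return 1.0

    # log P(n_het | n, n_rare) up to a constant, via log-factorials
    n_common = 2 * n - n_rare
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    rare_homs = (n_rare - hets) // 2
    common_homs = n - hets - rare_homs
    from scipy.special import gammaln

    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(rare_homs + 1)
        - gammaln(common_homs + 1)
        - (
            gammaln(2 * n + 1)
            - gammaln(n_rare + 1)
            - gammaln(n_common + 1)
        )
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = probs[np.flatnonzero(hets == n_Aa)[0]]
    p = float(probs[probs <= obs * (1 + 1e-12)].sum())
    return min(p, 1.0)


def differential_missingness_p(
    miss_case: int, n_case: int, miss_ctrl: int, n_ctrl: int
) -> float:
    """Two-sided Fisher exact p for (missing vs called) x (case vs control)."""
    if n_case <= 0 or n_ctrl <= 0:
        raise DataError("need nonzero case and control counts")
    if miss_case > n_case or miss_ctrl > n_ctrl:
        raise DataError("missing count exceeds group size")
    table = [
        [miss_case, n_case - miss_case],
        [miss_ctrl, n_ctrl - miss_ctrl],
    ]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])
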