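"""Seeded synthetic-cohort generator.

Emulates the statistical structure the pipeline assumes — rare-variant MAF
spectra, case/control genotypes, enhancer interval layout, conservation
scores, covariates, and planted set-level carrier risk ratios — so every
stage runs and is validated without external data.

All randomness flows through one seeded generator per run and the seed is
recorded in every output header; identical configs produce byte-identical
outputs.

The planted signal operates at carrier level: a target risk ratio r and
case carrier frequency f give control carrier frequency f/r; carriers are
drawn per sample and each carrier's single alternate allele lands on a
uniformly chosen variant of the set. This makes the ground truth directly
comparable to the carrier-statistics output.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .errors import ConfigError
from .io_formats import (
    EnhancerGeneMap,
    GenotypeMatrix,
    SampleTable,
    VariantRecord,
    write_annotations,
    write_enhancer_map,
    write_sample_table,
    write_vcf,
)

__all__ = [
    "SimConfig",
    "PlantedSet",
    "SimulatedCohort",
    "BatteryResult",
    "simulate_cohort",
    "generate_cohort",
    "null_pvalue_battery",
    "power_battery",
]

_EFFECT_CHOICES = ("MODERATE", "HIGH", "LOW", "synonymous", "TF_binding_site_variant")
_EFFECT_PROBS = (0.6, 0.15, 0.15, 0.05, 0.05)


@dataclass(frozen=True)
class PlantedSet:
    set_id: str
    risk_ratio: float
    case_carrier_freq: float

    def __post_init__(self) -> None:
        if self.risk_ratio < 1:
            raise ConfigError("planted risk ratios must be >= 1")
        if not 0.0 <= self.case_carrier_freq <= 1.0:
            raise ConfigError("carrier frequency must lie in [0, 1]")


@dataclass
class SimConfig:
    seed: int = 0
    n_case: int = 500
    n_ctrl: int = 500
    n_sets: int = 10
    variants_per_set: int = 20
    # true MAFs ~ Beta(maf_a, maf_b) truncated to (maf_floor, maf_max)
    maf_a: float = 1.0
    maf_b: float = 80.0
    maf_floor: float = 0.002
    maf_max: float = 0.05
    # fraction of variants with conservation score above 0.8
    cons_high_frac: float = 0.7
    planted_sets: list[PlantedSet] = field(default_factory=list)
    # covariate model (retrospective sampling: shifts in cases)
    sex_effect: float = 0.0
    pc_effects: tuple[float, ...] = (0.0,) * 10
    missingness_rate: float = 0.0
    depth_mean: float = 40.0
    depth_sd: float = 4.0
    # Beta-density weight parameters used by the batteries
    weight_a1: float = 1.0
    weight_a2: float = 25.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missingness_rate <= 1.0:
            raise ConfigError("missingness rate must lie in [0, 1]")
        if not 0.0 <= self.cons_high_frac <= 1.0:
            raise ConfigError("cons_high_frac must lie in [0, 1]")
        if len(self.pc_effects) != 10:
            raise ConfigError("pc_effects must have length 10")
        for ps in self.planted_sets:
            if ps.case_carrier_freq / ps.risk_ratio > 1.0:
                raise ConfigError(f"{ps.set_id}: infeasible carrier frequencies")


@dataclass
class SimulatedCohort:
    genotypes: GenotypeMatrix
    samples: SampleTable
    maps: list[EnhancerGeneMap]
    annotations: dict[str, dict]
    truth: pd.DataFrame


def _draw_mafs(cfg: SimConfig, rng: np.random.Generator, m: int) -> np.ndarray:
    """Truncated-Beta MAFs via inverse-CDF sampling (exact truncation)."""
    lo = stats.beta.cdf(cfg.maf_floor, cfg.maf_a, cfg.maf_b)
    hi = stats.beta.cdf(cfg.maf_max, cfg.maf_a, cfg.maf_b)
    u = rng.uniform(lo, hi, size=m)
    return stats.beta.ppf(u, cfg.maf_a, cfg.maf_b)


def generate_cohort(cfg: SimConfig) -> SimulatedCohort:
    """Generate the full cohort in memory (deterministic in cfg.seed)."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_case + cfg.n_ctrl
    status = np.concatenate([np.ones(cfg.n_case), np.zeros(cfg.n_ctrl)])
    sample_ids = [f"S{i:06d}" for i in range(n)]

    # covariates: retrospective shifts in cases
    sex = np.where(
        status == 1,
        rng.random(n) < expit(logit(0.5) + cfg.sex_effect),
        rng.random(n) < 0.5,
    ).astype(float)
    pcs = rng.normal(0.0, 1.0, size=(n, 10))
    pcs += status[:, None] * np.asarray(cfg.pc_effects)[None, :]
    samples = SampleTable(sample_ids=sample_ids, status=status, sex=sex, pcs=pcs)

    planted_by_id = {p.set_id: p for p in cfg.planted_sets}
    spacing = 10
    set_span = cfg.variants_per_set * spacing
    variants: list[VariantRecord] = []
    dosage_cols: list[np.ndarray] = []
    maps: list[EnhancerGeneMap] = []
    annotations: dict[str, dict] = {}
    truth_rows = []
    bases = np.array(list("ACGT"))

    for k in range(cfg.n_sets):
        set_id = f"SET{k:04d}"
        chrom = f"chr{(k % 22) + 1}"
        start0 = 10_000 + (k // 22) * 1_000_000
        maps.append(
            EnhancerGeneMap(
                set_id=set_id,
                intervals=[(chrom, start0, start0 + set_span)],
                flavor="tissue_agnostic",
            )
        )
        m = cfg.variants_per_set
        mafs = _draw_mafs(cfg, rng, m)
        planted = planted_by_id.get(set_id)
        if planted is None:
            dos = rng.binomial(2, mafs[None, :], size=(n, m)).astype(float)
            carriers_case = carriers_ctrl = None
        else:
            f_case = planted.case_carrier_freq
            f_ctrl = f_case / planted.risk_ratio
            carrier = np.where(
                status == 1, rng.random(n) < f_case, rng.random(n) < f_ctrl
            )
            dos = np.zeros((n, m))
            which = rng.integers(0, m, size=n)
            rows = np.flatnonzero(carrier)
            dos[rows, which[rows]] = 1.0
            carriers_case = int(carrier[status == 1].sum())
            carriers_ctrl = int(carrier[status == 0].sum())
        if cfg.missingness_rate > 0:
            miss = rng.random((n, m)) < cfg.missingness_rate
            dos[miss] = np.nan

        cons_high = rng.random(m) < cfg.cons_high_frac
        cons = np.where(
            cons_high,
            rng.uniform(0.8 + 1e-9, 1.0, size=m),
            rng.uniform(0.0, 0.8, size=m),
        )
        effects = rng.choice(_EFFECT_CHOICES, size=m, p=_EFFECT_PROBS)
        depths = rng.normal(cfg.depth_mean, cfg.depth_sd, size=m)
        for j in range(m):
            pos1 = start0 + j * spacing + 1
            ref = str(rng.choice(bases))
            alt = str(rng.choice(bases[bases != ref]))
            v = VariantRecord(chrom=chrom, pos=pos1, ref=ref, alt=alt)
            variants.append(v)
            dosage_cols.append(dos[:, j])
            annotations[v.key] = {
                "pop_af": float(mafs[j]),
                "cons_score": float(cons[j]),
                "effect_class": str(effects[j]),
                "mean_depth": float(depths[j]),
            }
        truth_rows.append(
            {
                "set_id": set_id,
                "planted": planted is not None,
                "is_null": planted is None or planted.risk_ratio == 1.0,
                "target_risk_ratio": planted.risk_ratio if planted else 1.0,
                "case_carrier_freq": planted.case_carrier_freq if planted else 0.0,
                "realized_carriers_case": carriers_case,
                "realized_carriers_ctrl": carriers_ctrl,
            }
        )

    gm = GenotypeMatrix(
        sample_ids=sample_ids,
        variants=variants,
        dosages=np.column_stack(dosage_cols) if dosage_cols else np.empty((n, 0)),
        meta={"seed": cfg.seed},
    )
    truth = pd.DataFrame(truth_rows)
    return SimulatedCohort(
        genotypes=gm, samples=samples, maps=maps, annotations=annotations, truth=truth
    )


def simulate_cohort(cfg: SimConfig, outdir: str) -> dict[str, str]:
    """Generate a cohort and write every pipeline input format to ``outdir``.

    Returns the mapping of artifact name -> path. Outputs are byte-stable
    for a fixed config.
    """
    cohort = generate_cohort(cfg)
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "vcf": os.path.join(outdir, "cohort.vcf"),
        "samples": os.path.join(outdir, "samples.tsv"),
        "enhancer_map": os.path.join(outdir, "enhancers.tsv"),
        "annotations": os.path.join(outdir, "annotations.tsv"),
        "truth": os.path.join(outdir, "truth.tsv"),
    }
    write_vcf(
        cohort.genotypes,
        paths["vcf"],
        extra_headers=[f"##enhburden_seed={cfg.seed}"],
    )
    write_sample_table(
        cohort.samples, paths["samples"], header_comments=[f"seed: {cfg.seed}"]
    )
    write_enhancer_map(cohort.maps, paths["enhancer_map"])
    write_annotations(cohort.annotations, paths["annotations"])
    with open(paths["truth"], "w") as fh:
        fh.write(f"# seed: {cfg.seed}\n")
        cohort.truth.to_csv(fh, sep="\t", index=False, float_format="%.12g")
    return paths


@dataclass
class BatteryResult:
    table: pd.DataFrame
    pvalues: np.ndarray


def _battery_null_model(cfg: SimConfig, rng: np.random.Generator):
    from .assoc import fit_null

    n = cfg.n_case + cfg.n_ctrl
    status = np.concatenate([np.ones(cfg.n_case), np.zeros(cfg.n_ctrl)])
    samples = SampleTable(
        sample_ids=[f"S{i:06d}" for i in range(n)], status=status
    )
    return fit_null(samples), status


def null_pvalue_battery(
    cfg: SimConfig,
    n_replicates: int,
    alphas: tuple[float, ...] = (0.05, 0.01, 0.001),
) -> BatteryResult:
    """Empirical type-I error of the optimal unified test on null sets.

    Each replicate draws a fresh genotype set independent of status under
    the config's MAF spectrum and computes its p-value against a shared
    null model; the table reports rejection fractions with exact binomial
    99% intervals.
    """
    from .assoc import SkatOConfig, beta_weight, cohort_maf, skato_p

    if cfg.planted_sets:
        raise ConfigError("null battery requires an all-null config")
    if n_replicates == 0:
        return BatteryResult(table=pd.DataFrame(), pvalues=np.array([]))
    rng = np.random.default_rng(cfg.seed)
    null, _ = _battery_null_model(cfg, rng)
    n = cfg.n_case + cfg.n_ctrl
    m = cfg.variants_per_set
    skato_cfg = SkatOConfig()
    pvals = np.empty(n_replicates)
    for r in range(n_replicates):
        mafs = _draw_mafs(cfg, rng, m)
        G = rng.binomial(2, mafs[None, :], size=(n, m)).astype(float)
        p_hat = cohort_maf(G)
        keep = p_hat > 0
        if not keep.any():
            pvals[r] = 1.0
            continue
        w = beta_weight(p_hat[keep], cfg.weight_a1, cfg.weight_a2)
        pvals[r] = skato_p(G[:, keep], w, null, skato_cfg).p
    rows = []
    for alpha in alphas:
        k = int((pvals <= alpha).sum())
        lo, hi = _binomial_interval(k, n_replicates, 0.99)
        rows.append(
            {
                "alpha": alpha,
                "n_replicates": n_replicates,
                "n_reject": k,
                "rejection_fraction": k / n_replicates if n_replicates else np.nan,
                "ci99_low": lo,
                "ci99_high": hi,
            }
        )
    return BatteryResult(table=pd.DataFrame(rows), pvalues=pvals)


def power_battery(
    cfg: SimConfig, n_replicates: int, alpha: float = 1e-3
) -> BatteryResult:
    """Rejection rate when the configured carrier signal is planted.

    Uses the first planted set's (risk ratio, case carrier frequency).
    """
    from .assoc import SkatOConfig, beta_weight, cohort_maf, skato_p

    if not cfg.planted_sets:
        raise ConfigError("power battery requires a planted set in the config")
    planted = cfg.planted_sets[0]
    rng = np.random.default_rng(cfg.seed)
    null, status = _battery_null_model(cfg, rng)
    n = cfg.n_case + cfg.n_ctrl
    m = cfg.variants_per_set
    f_case = planted.case_carrier_freq
    f_ctrl = f_case / planted.risk_ratio
    skato_cfg = SkatOConfig()
    pvals = np.empty(n_replicates)
    for r in range(n_replicates):
        carrier = np.where(
            status == 1, rng.random(n) < f_case, rng.random(n) < f_ctrl
        )
        G = np.zeros((n, m))
        which = rng.integers(0, m, size=n)
        rows = np.flatnonzero(carrier)
        G[rows, which[rows]] = 1.0
        p_hat = cohort_maf(G)
        keep = p_hat > 0
        if not keep.any():
            pvals[r] = 1.0
            continue
        w = beta_weight(p_hat[keep], cfg.weight_a1, cfg.weight_a2)
        pvals[r] = skato_p(G[:, keep], w, null, skato_cfg).p
    k = int((pvals <= alpha).sum())
    lo, hi = _binomial_interval(k, n_replicates, 0.99)
    table = pd.DataFrame(
        [
            {
                "alpha": alpha,
                "n_replicates": n_replicates,
                "n_reject": k,
                "rejection_fraction": k / n_replicates,
                "ci99_low": lo,
                "ci99_high": hi,
            }
        ]
    )
    return BatteryResult(table=table, pvalues=pvals)


def _binomial_interval(k: int, n: int, level: float) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval for k/n."""
    if n == 0:
        return (np.nan, np.nan)
    tail = (1.0 - level) / 2.0
    lo = 0.0 if k == 0 else float(stats.beta.ppf(tail, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - tail, k + 1, n - k))
    return lo, hi
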