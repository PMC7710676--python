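from __future__ import annotations

import hashlib

import numpy as np
import pytest

from enhburden.errors import ConfigError
from enhburden.io_formats import (
    read_annotations,
    read_enhancer_map,
    read_sample_table,
    read_vcf,
)
from enhburden.simulate import (
    PlantedSet,
    SimConfig,
    generate_cohort,
    null_pvalue_battery,
    power_battery,
    simulate_cohort,
)


def small_cfg(**kw):
    defaults = dict(seed=123, n_case=40, n_ctrl=40, n_sets=3, variants_per_set=6)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestGenerateCohort:
    def test_shapes(self):
        co = generate_cohort(small_cfg())
        assert co.genotypes.n_samples == 80
        assert co.genotypes.n_variants == 18
        assert len(co.maps) == 3
        assert len(co.annotations) == 18

    def test_all_null_truth(self):
        co = generate_cohort(small_cfg())
        assert co.truth["is_null"].all()

    def test_planted_rr_one_is_null(self):
        cfg = small_cfg(planted_sets=[PlantedSet("SET0000", 1.0, 0.2)])
        co = generate_cohort(cfg)
        assert co.truth["is_null"].all()

    def test_planted_carrier_expectation(self):
        # RR 12 at 1.25% case carrier frequency on the discovery cohort sizes
        cfg = SimConfig(
            seed=77,
            n_case=4495,
            n_ctrl=1925,
            n_sets=1,
            variants_per_set=10,
            planted_sets=[PlantedSet("SET0000", 12.0, 0.0125)],
        )
        co = generate_cohort(cfg)
        row = co.truth.iloc[0]
        # expectations ~ (56.2, 2.0); realized counts are binomial
        assert abs(row["realized_carriers_case"] - 56.2) < 4 * np.sqrt(56.2)
        assert abs(row["realized_carriers_ctrl"] - 2.0) < 4 * np.sqrt(2.0) + 1

    def test_infeasible_plant_rejected(self):
        with pytest.raises(ConfigError):
            PlantedSet("S", 0.5, 0.01)

    def test_maf_law_of_large_numbers(self):
        cfg = SimConfig(seed=5, n_case=5000, n_ctrl=5000, n_sets=1, variants_per_set=40)
        co = generate_cohort(cfg)
        sample_maf = np.nanmean(co.genotypes.dosages, axis=0) / 2
        true_maf = np.array(
            [co.annotations[v.key]["pop_af"] for v in co.genotypes.variants]
        )
        se = np.sqrt(true_maf * (1 - true_maf) / (2 * 10_000))
        assert np.all(np.abs(sample_maf - true_maf) < 5 * se + 1e-4)

    def test_cons_spectrum_fraction(self):
        cfg = SimConfig(seed=6, n_case=20, n_ctrl=20, n_sets=40, variants_per_set=20)
        co = generate_cohort(cfg)
        cons = np.array(
            [co.annotations[v.key]["cons_score"] for v in co.genotypes.variants]
        )
        frac = (cons > 0.8).mean()
        assert abs(frac - cfg.cons_high_frac) < 0.05


class TestSimulateCohortFiles:
    def test_outputs_parse_through_io(self, tmp_path):
        paths = simulate_cohort(small_cfg(missingness_rate=0.02), str(tmp_path))
        gm = read_vcf(paths["vcf"])
        st = read_sample_table(paths["samples"])
        maps = read_enhancer_map(paths["enhancer_map"])
        ann = read_annotations(paths["annotations"])
        assert gm.n_samples == 80 and gm.n_variants == 18
        assert st.n_case == 40 and st.pcs.shape == (80, 10)
        assert len(maps) == 3 and len(ann) == 18

    def test_same_seed_byte_identical(self, tmp_path):
        cfg = small_cfg(missingness_rate=0.05)
        p1 = simulate_cohort(cfg, str(tmp_path / "a"))
        p2 = simulate_cohort(cfg, str(tmp_path / "b"))
        for key in p1:
            h1 = hashlib.sha256(open(p1[key], "rb").read()).hexdigest()
            h2 = hashlib.sha256(open(p2[key], "rb").read()).hexdigest()
            assert h1 == h2, key

    def test_different_seed_differs(self, tmp_path):
        p1 = simulate_cohort(small_cfg(seed=1), str(tmp_path / "a"))
        p2 = simulate_cohort(small_cfg(seed=2), str(tmp_path / "b"))
        assert open(p1["vcf"]).read() != open(p2["vcf"]).read()

    def test_seed_recorded_in_headers(self, tmp_path):
        paths = simulate_cohort(small_cfg(seed=9), str(tmp_path))
        assert "##enhburden_seed=9" in open(paths["vcf"]).read()
        assert "# seed: 9" in open(paths["samples"]).read()


class TestEndToEndNullCalibration:
    def test_pipeline_lambda_within_bounds(self, tmp_path):
        """Full pipeline (VCF -> QC -> filters -> SKAT-O) on a null cohort."""
        from enhburden.cli import RunConfig, run_burden
        from enhburden.assoc import inflation

        cfg = SimConfig(
            seed=7,
            n_case=500,
            n_ctrl=500,
            n_sets=150,
            variants_per_set=20,
            cons_high_frac=1.0,  # conservation filter must not thin null sets
            maf_floor=0.002,
        )
        paths = simulate_cohort(cfg, str(tmp_path))
        rc = RunConfig(
            vcf=paths["vcf"],
            samples=paths["samples"],
            enhancer_map=paths["enhancer_map"],
            annotations=paths["annotations"],
            out_dir=str(tmp_path / "out"),
            mode="enhancer",
            a2=25.0,
            maf_max=0.2,
        )
        results, _, _ = run_burden(rc)
        assert len(results) == 150
        lam = inflation(results["p"], 500, 500).lambda_obs
        assert 0.9 <= lam <= 1.1


class TestBatteries:
    def test_zero_replicates_empty_table(self):
        out = null_pvalue_battery(small_cfg(), 0)
        assert out.table.empty and out.pvalues.size == 0

    def test_alpha_one_fraction_one(self):
        cfg = SimConfig(seed=3, n_case=100, n_ctrl=100, variants_per_set=8)
        out = null_pvalue_battery(cfg, 20, alphas=(1.0,))
        assert out.table["rejection_fraction"].iloc[0] == 1.0

    def test_planted_config_rejected_by_null_battery(self):
        cfg = small_cfg(planted_sets=[PlantedSet("SET0000", 5.0, 0.1)])
        with pytest.raises(ConfigError):
            null_pvalue_battery(cfg, 5)

    def test_power_battery_needs_plant(self):
        with pytest.raises(ConfigError):
            power_battery(small_cfg(), 5)

    def test_battery_table_columns(self):
        cfg = SimConfig(seed=4, n_case=100, n_ctrl=100, variants_per_set=8)
        out = null_pvalue_battery(cfg, 25)
        assert {"alpha", "rejection_fraction", "ci99_low", "ci99_high"} <= set(
            out.table.columns
        )
        assert np.all((out.pvalues > 0) & (out.pvalues <= 1))
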