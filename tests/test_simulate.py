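import dataclasses

import numpy as np
import pandas as pd
import pytest

from tsage.clocks import apply_clock
from tsage.pipeline import simulate_and_score
from tsage.simulate import (
    SaturationError,
    SimConfig,
    build_true_clock,
    generate_cohort,
    mix_contamination,
    simulate_intensity_table,
    write_cohort,
)


class TestSimConfig:
    def test_defaults_match_cohort_summary(self):
        cfg = SimConfig()
        assert (cfg.n_oligo, cfg.n_normo) == (10, 24)
        assert cfg.age_mean_oligo == pytest.approx(32.73)
        assert cfg.age_se_oligo == pytest.approx(1.9)
        assert cfg.age_mean_normo == pytest.approx(31.64)
        assert cfg.age_se_normo == pytest.approx(1.3)

    @pytest.mark.parametrize("bad", [
        dict(n_oligo=0),
        dict(beta_noise_sd=-0.1),
        dict(contamination_fraction=1.5),
        dict(sperm_accel_oligo=-1.0),
    ])
    def test_invalid(self, bad):
        with pytest.raises(ValueError):
            SimConfig(**bad)


class TestGenerateCohort:
    def test_counts(self):
        bundle = generate_cohort(SimConfig(n_oligo=10, n_normo=24, seed=1))
        assert bundle.sheet["individual_id"].nunique() == 34
        assert len(bundle.sheet) == 68  # one sperm + one blood each
        assert bundle.sperm_betas.shape[1] == 34
        assert bundle.blood_betas.shape[1] == 34

    def test_columns_match_sheet(self, default_bundle):
        for tissue, betas in (("sperm", default_bundle.sperm_betas),
                              ("blood", default_bundle.blood_betas)):
            expected = set(default_bundle.sheet.loc[
                default_bundle.sheet["tissue"] == tissue, "sample_id"])
            assert set(betas.columns) == expected

    def test_truth_covers_every_sample(self, default_bundle):
        assert set(default_bundle.truth.index) == set(default_bundle.sheet["sample_id"])

    def test_betas_in_unit_interval(self):
        for seed in range(5):
            bundle = generate_cohort(SimConfig(seed=seed, beta_noise_sd=0.05))
            for betas in (bundle.sperm_betas, bundle.blood_betas):
                v = betas.to_numpy()
                assert v.min() >= 0.0 and v.max() <= 1.0

    def test_deterministic_given_seed(self):
        a = generate_cohort(SimConfig(seed=42))
        b = generate_cohort(SimConfig(seed=42))
        pd.testing.assert_frame_equal(a.sperm_betas, b.sperm_betas)
        pd.testing.assert_frame_equal(a.blood_betas, b.blood_betas)
        pd.testing.assert_frame_equal(a.sheet, b.sheet)
        pd.testing.assert_series_equal(a.truth, b.truth)
        c = generate_cohort(SimConfig(seed=43))
        assert not a.sperm_betas.equals(c.sperm_betas)

    def test_noise_free_clock_inverts_exactly(self, noise_free_config):
        cfg = dataclasses.replace(noise_free_config, sperm_accel_oligo=0.0)
        bundle = generate_cohort(cfg)
        ages = bundle.sheet.set_index("sample_id")["age_years"]
        for clock, betas in ((bundle.true_sperm_clock, bundle.sperm_betas),
                             (bundle.true_blood_clock, bundle.blood_betas)):
            table = apply_clock(clock, betas)
            chron = ages.loc[table["sample_id"]].to_numpy()
            assert np.max(np.abs(table["predicted_age_years"].to_numpy() - chron)) < 1e-8

    def test_effective_age_multiplicative(self):
        cfg = SimConfig(sperm_accel_oligo=0.2, beta_noise_sd=0.0,
                        n_background_cpgs=1, n_dlk1_cpgs=1, seed=9)
        bundle = generate_cohort(cfg)
        sheet = bundle.sheet.set_index("sample_id")
        for sid, eff in bundle.truth.items():
            chron = sheet.loc[sid, "age_years"]
            factor = 1.2 if (sheet.loc[sid, "group"] == "oligozoospermic"
                             and sheet.loc[sid, "tissue"] == "sperm") else 1.0
            assert eff == pytest.approx(chron * factor)

    def test_ages_truncated(self):
        # huge SD forces truncation to bite
        cfg = SimConfig(age_se_oligo=8.0, age_se_normo=8.0, seed=3,
                        n_background_cpgs=1, n_dlk1_cpgs=1)
        ages = generate_cohort(cfg).sheet["age_years"]
        assert ages.between(18, 60).all()

    def test_background_mass_outside_valley(self):
        bundle = generate_cohort(SimConfig(seed=2, n_background_cpgs=2000))
        bg = bundle.sperm_betas.loc[
            [c for c in bundle.sperm_betas.index if c.startswith("cg_bg")]].to_numpy()
        mid = np.mean((bg > 0.2) & (bg < 0.8))
        assert mid <= 0.2

    def test_dlk1_means(self, default_bundle):
        dlk1 = [c for c in default_bundle.sperm_betas.index if c.startswith("cg_dlk1_")]
        assert default_bundle.sperm_betas.loc[dlk1].to_numpy().mean() == pytest.approx(0.05, abs=0.02)
        assert default_bundle.blood_betas.loc[dlk1].to_numpy().mean() == pytest.approx(0.80, abs=0.02)

    def test_contamination_shifts_dlk1_affinely(self):
        means = {}
        for f in (0.0, 0.25, 0.5):
            cfg = SimConfig(seed=8, beta_noise_sd=0.0, contamination_fraction=f)
            bundle = generate_cohort(cfg)
            dlk1 = [c for c in bundle.sperm_betas.index if c.startswith("cg_dlk1_")]
            means[f] = bundle.sperm_betas.loc[dlk1].to_numpy().mean()
        slope1 = (means[0.25] - means[0.0]) / 0.25
        slope2 = (means[0.5] - means[0.25]) / 0.25
        assert slope1 == pytest.approx(slope2, rel=1e-9)
        assert slope1 == pytest.approx(0.80 - 0.05, abs=1e-9)

    def test_glad_monotone_in_acceleration(self, fast_config):
        """Expected oligo sperm GLAD gap increases with injected acceleration."""
        means = []
        for accel in (0.0, 0.1, 0.3):
            gaps = []
            for s in range(40):
                cfg = dataclasses.replace(fast_config, sperm_accel_oligo=accel, seed=1000 + s)
                gaps.append(simulate_and_score(cfg)["sperm_glad_gap"])
            means.append(np.mean(gaps))
        assert means[0] < means[1] < means[2]


class TestMixContamination:
    def setup_method(self):
        idx = ["cg1", "cg2", "cg3"]
        self.sperm = pd.Series([0.05, 0.1, 0.0], index=idx)
        self.blood = pd.Series([0.8, 0.9, 1.0], index=idx)

    def test_fraction_zero_identity(self):
        pd.testing.assert_series_equal(
            mix_contamination(self.sperm, self.blood, 0.0), self.sperm, check_exact=False)

    def test_fraction_one_is_blood(self):
        pd.testing.assert_series_equal(
            mix_contamination(self.sperm, self.blood, 1.0),
            self.blood, check_exact=False)

    def test_midpoint_mean(self):
        sperm = pd.Series([0.05, 0.05], index=["a", "b"])
        blood = pd.Series([0.8, 0.8], index=["a", "b"])
        mixed = mix_contamination(sperm, blood, 0.5)
        assert mixed.mean() == pytest.approx(0.425)

    def test_mismatched_cpgs(self):
        with pytest.raises(ValueError, match="mismatched"):
            mix_contamination(self.sperm, self.blood.rename({"cg3": "cgX"}), 0.5)

    def test_bad_fraction(self):
        with pytest.raises(ValueError):
            mix_contamination(self.sperm, self.blood, 1.5)


class TestBuildTrueClock:
    def test_single_cpg_algebraic_inverse(self):
        # beta = 0.2 + 0.005 * age  =>  age = 200*beta - 40
        clock = build_true_clock([0.2], [0.005], ["cg1"])
        assert clock.coefficients["cg1"] == pytest.approx(200.0)
        assert clock.intercept == pytest.approx(-40.0)
        assert clock.predict_age(pd.Series({"cg1": 0.35})) == pytest.approx(30.0)

    def test_exact_inverse_on_grid(self, rng):
        b0 = rng.uniform(0.2, 0.4, 10)
        s = rng.uniform(0.002, 0.008, 10)
        ids = [f"cg{i}" for i in range(10)]
        clock = build_true_clock(b0, s, ids)
        for age in (20.0, 30.0, 40.0):
            betas = pd.Series(b0 + s * age, index=ids)
            assert clock.predict_age(betas) == pytest.approx(age, abs=1e-10)

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError, match="nonzero"):
            build_true_clock([0.2, 0.3], [0.005, 0.0], ["a", "b"])

    def test_error_sd_scales_inverse_sqrt_cpgs(self, rng):
        """Monte-Carlo: prediction error SD ~ 1/sqrt(n_cpgs)."""
        sds = {}
        for n_cpgs in (25, 100):
            b0 = np.full(n_cpgs, 0.3)
            s = np.full(n_cpgs, 0.005)
            ids = [f"cg{i}" for i in range(n_cpgs)]
            clock = build_true_clock(b0, s, ids)
            errs = []
            for _ in range(200):
                betas = pd.Series(b0 + s * 30.0 + rng.normal(0, 0.01, n_cpgs), index=ids)
                errs.append(clock.predict_age(betas) - 30.0)
            sds[n_cpgs] = np.std(errs)
        # quadrupling the CpGs should halve the error SD (ratio 2, MC slack)
        assert sds[25] / sds[100] == pytest.approx(2.0, rel=0.35)


class TestSaturationGuard:
    def test_bad_regime_rejected(self, monkeypatch):
        import tsage.simulate as sim
        monkeypatch.setattr(sim, "SLOPE_RANGE", (0.02, 0.05))
        with pytest.raises(SaturationError):
            generate_cohort(SimConfig(seed=0, n_background_cpgs=1, n_dlk1_cpgs=1))


class TestOutputs:
    def test_write_cohort_round_trip(self, tmp_path, default_bundle):
        from tsage import io as tio
        paths = write_cohort(default_bundle, tmp_path)
        betas = tio.read_beta_matrix(paths["betas_sperm"])
        assert betas.shape == default_bundle.sperm_betas.shape
        np.testing.assert_allclose(betas.to_numpy(),
                                   default_bundle.sperm_betas.to_numpy(), atol=1e-12)
        sheet = tio.read_sample_sheet(paths["sheet"])
        assert list(sheet.columns) == ["sample_id", "individual_id", "tissue", "group", "age_years"]
        dlk1 = tio.read_dlk1_annotation(paths["dlk1"])
        assert all(c.startswith("cg_dlk1_") for c in dlk1)
        import json
        truth = json.loads(paths["truth"].read_text())
        assert truth["config"]["n_oligo"] == 10

    def test_intensity_table(self, default_bundle):
        table = simulate_intensity_table(default_bundle)
        assert len(table) == 68
        assert (table["median_log2_intensity"] > 0).all()
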