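"""Synthetic cohort generator: reproducibility, the Bernoulli outcome
model, missingness mechanics, the anonymization emulator, and the hidden
ground-truth oracle."""

import numpy as np
import pandas as pd
import pytest

import metscate as mc
from metscate.cohort import (
    SyntheticConfig,
    cate_age_linear,
    cate_constant,
    cate_department_step,
    default_covariate_spec,
    homogeneous_covariate_spec,
)


def _flat_config(n0, n1, baseline, tau_fn, seed):
    return SyntheticConfig(
        n_unexposed=n0, n_exposed=n1,
        baseline_risk_fn=lambda df: np.full(len(df), baseline),
        cate_fn=tau_fn, seed=seed)


def test_generation_is_bit_reproducible():
    cfg = mc.study_cohort_config(seed=42, n_unexposed=300, n_exposed=200)
    a = mc.generate_cohort(cfg)
    b = mc.generate_cohort(mc.study_cohort_config(seed=42, n_unexposed=300,
                                                  n_exposed=200))
    pd.testing.assert_frame_equal(a, b)
    c = mc.generate_cohort(mc.study_cohort_config(seed=43, n_unexposed=300,
                                                  n_exposed=200))
    assert not a["age"].equals(c["age"])


def test_null_effect_gives_equal_arm_rates():
    df = mc.generate_cohort(_flat_config(1000, 1000, 0.10, cate_constant(0.0), 1))
    r0 = df[df.exposure == 0].y_mets_followup.mean()
    r1 = df[df.exposure == 1].y_mets_followup.mean()
    se = np.sqrt(2 * 0.10 * 0.90 / 1000)
    assert abs(r1 - r0) < 3 * se


def test_constant_effect_shifts_exposed_rate():
    """Baseline 3%, tau = 5% -> exposed arm ~8% (binomial Monte Carlo)."""
    df = mc.generate_cohort(_flat_config(2000, 2000, 0.03, cate_constant(0.05), 2))
    r1 = df[df.exposure == 1].y_mets_followup.mean()
    assert abs(r1 - 0.08) < 3 * np.sqrt(0.08 * 0.92 / 2000)
    r0 = df[df.exposure == 0].y_mets_followup.mean()
    assert abs(r0 - 0.03) < 3 * np.sqrt(0.03 * 0.97 / 2000)


def test_default_cohort_matches_configured_marginals():
    """Arm sizes, sex mix and age distribution follow the per-arm spec."""
    df = mc.generate_cohort(mc.study_cohort_config(seed=5))
    un, ex = df[df.exposure == 0], df[df.exposure == 1]
    assert (len(un), len(ex)) == (2181, 1391)
    assert abs((un.sex == "female").mean() - 0.708) < 3 * np.sqrt(0.708 * 0.292 / 2181)
    assert abs((ex.sex == "female").mean() - 0.623) < 3 * np.sqrt(0.623 * 0.377 / 1391)
    assert abs(un.age.mean() - 48.2) < 3 * 8.2 / np.sqrt(2181) + 0.15  # truncation shift
    assert abs(ex.age.mean() - 47.8) < 3 * 8.3 / np.sqrt(1391) + 0.15
    # overall prevalence equals mean generating risk within 3 MC SE
    p = mc.cohort.default_baseline_risk(df) + df.exposure.to_numpy() * df.true_tau.to_numpy()
    se = np.sqrt(np.sum(p * (1 - p))) / len(df)
    assert abs(df.y_mets_followup.mean() - p.mean()) < 3 * se


def test_fasting_casual_exclusivity_everywhere():
    df = mc.generate_cohort(mc.study_cohort_config(seed=11))
    for stem in ("tg", "bs"):
        both = df[f"{stem}_fasting"].notna() & df[f"{stem}_casual"].notna()
        assert not both.any()


def test_invalid_effect_surface_rejected():
    with pytest.raises(ValueError, match="invalid effect surface"):
        mc.generate_cohort(_flat_config(50, 50, 0.9, cate_constant(0.2), 0))
    with pytest.raises(ValueError, match="invalid effect surface"):
        mc.generate_cohort(_flat_config(50, 50, 0.05, cate_constant(-0.2), 0))


def test_config_validation_rejects_bad_proportions():
    cfg = mc.study_cohort_config()
    cfg.covariate_spec["department_props"] = ((0.5, 0.5, 0.5, 0.5),) * 2
    with pytest.raises(ValueError, match="sum to 1"):
        cfg.validate()


class TestApplyMissingness:
    def test_rate_zero_is_identity_and_rate_one_blanks_all(self):
        df = mc.generate_cohort(mc.study_cohort_config(seed=3, n_unexposed=200,
                                                       n_exposed=100))
        same = mc.apply_missingness(df, {"hba1c": 0.0}, seed=0)
        pd.testing.assert_series_equal(same["hba1c"], df["hba1c"])
        gone = mc.apply_missingness(df, {"hba1c": 1.0}, seed=0)
        assert gone["hba1c"].isna().all()

    def test_half_rate_is_binomial(self):
        cfg = _flat_config(1000, 1000, 0.03, cate_constant(0.0), 4)
        df = mc.generate_cohort(cfg)
        df["ldl"] = 100.0
        out = mc.apply_missingness(df, {"ldl": 0.5}, seed=9)
        frac = out["ldl"].isna().mean()
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / 2000)

    def test_unknown_field_and_bad_rate_raise(self):
        df = mc.generate_cohort(mc.study_cohort_config(seed=0, n_unexposed=30,
                                                       n_exposed=30))
        with pytest.raises(KeyError):
            mc.apply_missingness(df, {"nope": 0.5}, seed=0)
        with pytest.raises(ValueError):
            mc.apply_missingness(df, {"hba1c": 1.5}, seed=0)


class TestAnonymize:
    def test_zero_noise_permutation_preserves_values(self):
        df = mc.generate_cohort(mc.study_cohort_config(seed=8, n_unexposed=300,
                                                       n_exposed=200))
        out = mc.anonymize(df, noise_sd_per_field={}, resample_fraction=1.0,
                           seed=1, replace=False)
        assert sorted(out["age"]) == sorted(df["age"])
        assert sorted(out["department"]) == sorted(df["department"])

    def test_noise_inflates_variance_additively(self):
        cfg = _flat_config(2500, 2500, 0.03, cate_constant(0.0), 5)
        df = mc.generate_cohort(cfg)
        out = mc.anonymize(df, noise_sd_per_field={"age": 1.0}, seed=2,
                           replace=False)
        # var(X + eps) = var(X) + 1 up to estimation noise in the eps terms
        assert abs(out["age"].var() - (df["age"].var() + 1.0)) < 0.5

    def test_record_ids_are_regenerated(self):
        df = mc.generate_cohort(mc.study_cohort_config(seed=9, n_unexposed=100,
                                                       n_exposed=100))
        out = mc.anonymize(df, seed=3)
        assert not set(out["record_id"]) & set(df["record_id"])
        assert len(out) == len(df)

    def test_resample_fraction_controls_size(self):
        df = mc.generate_cohort(mc.study_cohort_config(seed=9, n_unexposed=100,
                                                       n_exposed=100))
        assert len(mc.anonymize(df, resample_fraction=0.5, seed=0)) == 100
        with pytest.raises(ValueError):
            mc.anonymize(df, resample_fraction=0.0, seed=0)


class TestTrueSubgroupCate:
    def test_constant_surface(self):
        df = mc.generate_cohort(_flat_config(200, 200, 0.03, cate_constant(0.05), 6))
        assert mc.true_subgroup_cate(df, "overall") == {"overall": pytest.approx(0.05)}
        for v in mc.true_subgroup_cate(df, "sex").values():
            assert v == pytest.approx(0.05)

    def test_department_step_surface(self):
        step = {"administrative": 0.03, "research": 0.03, "medical": 0.03,
                "intensive_care": 0.15}
        cfg = SyntheticConfig(n_unexposed=500, n_exposed=500,
                              baseline_risk_fn=lambda df: np.full(len(df), 0.03),
                              cate_fn=cate_department_step(step), seed=7)
        got = mc.true_subgroup_cate(mc.generate_cohort(cfg), "department")
        assert got["intensive_care"] == pytest.approx(0.15)
        assert got["medical"] == pytest.approx(0.03)

    def test_age_linear_surface_matches_bruteforce_mean(self):
        fn = cate_age_linear(0.02, 0.001)
        cfg = SyntheticConfig(n_unexposed=400, n_exposed=400,
                              baseline_risk_fn=lambda df: np.full(len(df), 0.10),
                              cate_fn=fn, seed=8)
        df = mc.generate_cohort(cfg)
        got = mc.true_subgroup_cate(df, "sex")
        for sex, grp in df.groupby("sex"):
            brute = np.mean([0.02 + 0.001 * (a - 48.0) for a in grp["age"]])
            assert got[sex] == pytest.approx(brute)

    def test_rejects_records_without_ground_truth(self):
        df = mc.generate_cohort(mc.study_cohort_config(seed=0, n_unexposed=30,
                                                       n_exposed=30))
        with pytest.raises(ValueError, match="ground truth"):
            mc.true_subgroup_cate(df.drop(columns="true_tau"), "sex")


def test_csv_round_trip(tmp_path):
    df = mc.generate_cohort(mc.study_cohort_config(seed=12, n_unexposed=80,
                                                   n_exposed=60))
    path = tmp_path / "cohort.csv"
    mc.write_cohort_csv(df, path, seed=12)
    back = mc.read_cohort_csv(path)
    assert list(back.columns) == list(df.columns)
    assert len(back) == len(df)
    np.testing.assert_allclose(back["age"], df["age"], rtol=1e-12)


def test_yaml_config_loader(tmp_path):
    p = tmp_path / "cfg.yaml"
    p.write_text("n_unexposed: 120\nn_exposed: 80\nseed: 3\nsurface: null\n"
                 "missingness_rates:\n  hba1c: 0.25\n")
    cfg = SyntheticConfig.from_yaml(p)
    assert (cfg.n_unexposed, cfg.n_exposed, cfg.seed) == (120, 80, 3)
    assert cfg.missingness_rates == {"hba1c": 0.25}
    df = mc.generate_cohort(cfg)
    assert (df.true_tau == 0).all()


def test_homogeneous_spec_collapses_arm_differences():
    spec = homogeneous_covariate_spec()
    assert spec["female_prop"][0] == spec["female_prop"][1]
    assert spec["hba1c_available_prop"][0] == spec["hba1c_available_prop"][1]
    default = default_covariate_spec()
    assert default["female_prop"][0] != default["female_prop"][1]
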