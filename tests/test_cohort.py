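"""Tests for the synthetic lifespan cohort generator."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from patsep.cohort import (
    ACTIVATION_MOMENTS,
    SUBFIELDS,
    VOLUME_MOMENTS,
    AgeSampler,
    CohortConfig,
    TrialSimConfig,
    default_config,
    load_config,
    save_config,
    simulate_cohort,
    simulate_trials,
    volume_normalize,
)
from patsep.scoring import Phase, Response, TrialType, score_session


class TestDefaultConfig:
    def test_structural_slopes_match_targets(self, cfg):
        assert cfg.crs_model.age_slope == -0.007
        assert cfg.volume_models["ca1_left"].age_slope == -0.06
        assert cfg.volume_models["dg_left"].age_slope == -0.02
        assert cfg.volume_models["dg_right"].age_slope == -0.03
        assert cfg.volume_models["ca3_right"].age_slope == 0.0

    def test_intercepts_are_cohort_means(self, cfg):
        for key, (mean, _) in VOLUME_MOMENTS.items():
            assert cfg.volume_models[key].intercept == mean
        for key, (mean, _) in ACTIVATION_MOMENTS.items():
            assert cfg.activation_models[key].mean == mean

    def test_moderation_pattern_signs(self, cfg):
        """DG-volume effect negative in midlife, positive (left) late;
        CA3-activation effect positive early, negative late."""
        b_dgl = cfg.ldi_model.moderators["dg_left_vol"]
        assert b_dgl(50.0) < 0 and b_dgl(70.0) > 0 and b_dgl(25.0) == 0
        b_dgr = cfg.ldi_model.moderators["dg_right_vol"]
        assert b_dgr(48.0) < 0 and b_dgr(70.0) == 0
        b_ca3 = cfg.ldi_model.moderators["ca3_left_act"]
        assert b_ca3(25.0) > 0 and b_ca3(70.0) < 0

    def test_age_function_declines_from_plateau(self, cfg):
        g = cfg.ldi_model.g
        ages = np.linspace(21, 73, 200)
        vals = np.asarray(g(ages))
        assert np.all(np.diff(vals) <= 1e-12)  # monotone decline
        assert vals[0] - vals[-1] > 0.2  # plateau-to-old drop


class TestAgeSampler:
    def test_stratum_counts_at_study_scale(self):
        assert AgeSampler().stratum_counts(53) == [18, 18, 17]

    def test_quadrature_matches_monte_carlo(self, rng):
        s = AgeSampler()
        ages = s.sample(rng, 200_000)
        assert s.mean() == pytest.approx(ages.mean(), abs=0.1)
        assert s.var() == pytest.approx(ages.var(), rel=0.02)

    def test_support_and_kinds(self, rng):
        s = AgeSampler()
        assert s.support() == (21.0, 73.0)
        c = AgeSampler(kind="continuous")
        a = c.sample(rng, 1000)
        assert a.min() >= 21.0 and a.max() <= 73.0
        with pytest.raises(ValueError, match="unknown age sampler"):
            AgeSampler(kind="normal")


class TestSimulateCohort:
    def test_seed_determinism(self, cfg):
        a = simulate_cohort(cfg, seed=5, n=200)
        b = simulate_cohort(cfg, seed=5, n=200)
        assert a.to_csv(index=False) == b.to_csv(index=False)
        c = simulate_cohort(cfg, seed=6, n=200)
        assert not a["ldi"].equals(c["ldi"])

    def test_moment_fidelity(self, cfg):
        """Sample means within 4 SD/sqrt(n) of the configured moments."""
        n = 30_000
        df = simulate_cohort(cfg, seed=9, n=n)
        for key, (mean, sd) in VOLUME_MOMENTS.items():
            assert abs(df[f"{key}_vol"].mean() - mean) < 4 * sd / np.sqrt(n)
            assert df[f"{key}_vol"].std() == pytest.approx(sd, rel=0.05)
        for key, (mean, sd) in ACTIVATION_MOMENTS.items():
            assert abs(df[f"{key}_act"].mean() - mean) < 4 * sd / np.sqrt(n)

    def test_zero_noise_limit_reproduces_structural_model(self, cfg):
        """With zero LDI noise, latent LDI is exactly g(age) + moderation."""
        cfg0 = dataclasses.replace(
            cfg, ldi_model=dataclasses.replace(cfg.ldi_model, residual_sd=0.0)
        )
        df = simulate_cohort(cfg0, seed=3, n=10)
        center = cfg0.age_center
        expected = np.asarray(cfg0.ldi_model.g(df.age), dtype=float)
        for source, coeff in cfg0.ldi_model.moderators.items():
            key = source.rsplit("_", 1)[0]
            if source.endswith("_vol"):
                m = cfg0.volume_models[key]
                z = (
                    df[source]
                    - (m.intercept + m.age_slope * (df.age - center))
                ) / m.residual_sd
            else:
                am = cfg0.activation_models[key]
                z = (df[source] - am.mean) / am.sd
            expected = expected + np.asarray(coeff(df.age)) * z.to_numpy()
        assert np.allclose(df.ldi, np.clip(expected, -1, 1), atol=1e-10)

    def test_ols_recovers_configured_slopes(self, cfg):
        """Independent least-squares oracle on a large cohort."""
        df = simulate_cohort(cfg, seed=11, n=30_000)
        X = np.column_stack([np.ones(len(df)), df.age])
        for col, truth, tol in [
            ("ca1_left_vol", -0.06, 0.004),
            ("dg_right_vol", -0.03, 0.002),
        ]:
            beta = np.linalg.lstsq(X, df[col], rcond=None)[0]
            assert beta[1] == pytest.approx(truth, abs=tol)

    def test_sex_and_education_distributions(self, cfg):
        df = simulate_cohort(cfg, seed=13, n=20_000)
        assert (df.sex == "female").mean() == pytest.approx(0.57, abs=0.02)
        assert df.education.between(2, 8).all()
        assert df.education.mean() == pytest.approx(5.4, abs=0.2)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="n must be positive"):
            CohortConfig(n=0)
        with pytest.raises(ValueError, match="probability"):
            CohortConfig(sex_p_female=1.4)


class TestSimulateTrials:
    def test_designed_trial_counts(self):
        recs = simulate_trials({"ldi": 0.2, "crs": 0.5}, seed=0)
        types = [r.trial_type for r in recs]
        assert types.count(TrialType.TARGET) == 50
        assert types.count(TrialType.LURE) == 100
        assert types.count(TrialType.FOIL) == 50

    def test_deterministic_perfect_discrimination(self):
        tcfg = TrialSimConfig(foil_similar_rate=0.0, foil_old_rate=0.0)
        recs = simulate_trials({"ldi": 1.0, "crs": 1.0}, tcfg, seed=0)
        lures = [r for r in recs if r.trial_type is TrialType.LURE]
        assert all(r.response is Response.SIMILAR for r in lures)
        assert score_session(recs).ldi == 1.0

    def test_missingness_flags_but_keeps_rows(self):
        tcfg = TrialSimConfig(missingness=0.5)
        recs = simulate_trials({"ldi": 0.2, "crs": 0.5}, tcfg, seed=1)
        assert len(recs) == 200
        n_none = sum(r.response is Response.NONE for r in recs)
        assert 50 < n_none < 150

    def test_scoring_round_trip_unbiased(self):
        """Mean computed LDI over sessions matches the latent value."""
        rng = np.random.default_rng(42)
        tcfg = TrialSimConfig(foil_similar_rate=0.20)
        ldis = []
        for _ in range(600):
            recs = simulate_trials({"ldi": 0.40, "crs": 0.50}, tcfg, rng=rng)
            ldis.append(score_session(recs).ldi)
        se = np.std(ldis) / np.sqrt(len(ldis))
        assert abs(np.mean(ldis) - 0.40) < 3 * se

    def test_invalid_rates_error_names_trial_type(self):
        tcfg = TrialSimConfig(foil_similar_rate=0.7, foil_old_rate=0.7)
        with pytest.raises(ValueError, match="foil"):
            simulate_trials({"ldi": 0.1, "crs": 0.1}, tcfg, seed=0)

    def test_encoding_phase_records_optional(self):
        tcfg = TrialSimConfig(include_encoding=True)
        recs = simulate_trials({"ldi": 0.2, "crs": 0.5}, tcfg, seed=2)
        enc = [r for r in recs if r.phase is Phase.ENCODING]
        assert len(enc) == 150
        assert all(r.response in (Response.INDOOR, Response.OUTDOOR) for r in enc)


class TestVolumeNormalize:
    def test_direct_arithmetic(self):
        assert volume_normalize(4500, 1_450_000) == pytest.approx(3.10345, abs=1e-4)
        assert volume_normalize(0, 1_000_000) == 0.0
        icv = 1_500_000
        assert volume_normalize(0.03063 * icv, icv) == pytest.approx(30.63)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="intracranial"):
            volume_normalize(4500, 0)
        with pytest.raises(ValueError, match="non-negative"):
            volume_normalize(-1, 1_000_000)


class TestConfigSerialization:
    def test_yaml_round_trip(self, cfg, tmp_path):
        path = tmp_path / "config.yaml"
        save_config(cfg, path)
        loaded = load_config(path)
        a = simulate_cohort(cfg, seed=4, n=50)
        b = simulate_cohort(loaded, seed=4, n=50)
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_keys_rejected(self, cfg, tmp_path):
        import yaml

        path = tmp_path / "config.yaml"
        save_config(cfg, path)
        d = yaml.safe_load(path.read_text())
        d["typo_key"] = 1
        path.write_text(yaml.safe_dump(d))
        with pytest.raises(ValueError, match="unknown config keys"):
            load_config(path)


def test_cohort_columns_match_analysis_schema(cohort53):
    from patsep.pipeline import SCHEMA_COLUMNS

    assert set(SCHEMA_COLUMNS) <= set(cohort53.columns)
    assert list(cohort53.columns[:4]) == ["participant_id", "age", "sex", "education"]
    assert cohort53.ldi.between(-1, 1).all()
    assert (cohort53.filter(like="_vol") > 0).all().all()
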