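import numpy as np
import pandas as pd
import pytest
from pydantic import ValidationError

from vptlab.cohort import (CohortConfig, ParticipantParams, expected_rt,
                           generate_questionnaires, sample_cohort_params,
                           sample_participant, simulate_cohort, simulate_trial)


class TestConfig:
    def test_lapse_count_validated(self):
        with pytest.raises(ValidationError):
            CohortConfig(seed=1, n_lapse=80, n_recruited=79)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValidationError):
            CohortConfig(seed=1, gamma_sd=-1)

    def test_lapse_error_range_above_cutoff(self):
        with pytest.raises(ValidationError):
            CohortConfig(seed=1, lapse_p_error_range=(0.10, 0.30))

    def test_correlations_bounded(self):
        with pytest.raises(ValidationError):
            CohortConfig(seed=1, corr_age=1.5)

    def test_derived_slope_sds(self):
        """Between-participant slope SDs derive from the group t statistics:
        SD = mean * sqrt(61) / t."""
        cfg = CohortConfig(seed=1)
        assert cfg.beta_self_sd == pytest.approx(1.39 * np.sqrt(61) / 19.181)
        assert cfg.beta_other_sd == pytest.approx(0.38 * np.sqrt(61) / 7.209)

    def test_json_roundtrip(self, tmp_path):
        cfg = CohortConfig(seed=42, gamma_mean=700.0)
        cfg.to_json(tmp_path / "c.json")
        assert CohortConfig.from_json(tmp_path / "c.json") == cfg


class TestSampling:
    def test_degenerate_sds_give_configured_means(self, rng):
        cfg = CohortConfig(seed=1, gamma_sd=0, beta_self_sd=0, beta_other_sd=0)
        p = sample_participant(cfg, rng)
        assert p.beta_self == cfg.beta_self_mean
        assert p.beta_other == cfg.beta_other_mean

    def test_slope_mean_law_of_large_numbers(self, rng):
        cfg = CohortConfig(seed=1)
        draws = np.array([sample_participant(cfg, rng).beta_self for _ in range(10_000)])
        se = cfg.beta_self_sd / 100
        assert abs(draws.mean() - 1.39) < 3 * se

    def test_exactly_n_lapse_flagged(self, rng):
        params = sample_cohort_params(CohortConfig(seed=1), rng)
        assert len(params) == 79
        assert params.lapse.sum() == 18
        assert (params[params.lapse].p_error > 0.20).all()

    def test_lapse_invariant_enforced(self):
        with pytest.raises(ValueError):
            ParticipantParams("p1", 700, 1.4, 0.4, 15, p_error=0.10, lapse=True)


class TestExpectedRT:
    PARAMS = ParticipantParams("p1", 700.0, 1.0, 0.5, 0.0, 0.0, False)

    def _spec(self, **kw):
        base = dict(movement="free", person_location="none", orientation_deg=0)
        base.update(kw)
        return pd.Series(base)

    def test_self_rotation_only(self):
        assert expected_rt(self._spec(orientation_deg=180), self.PARAMS) == 880.0

    def test_dual_viewpoint(self):
        # theta=270: d_self=90; person-left (phi=90): d_other=180
        spec = self._spec(orientation_deg=270, person_location="left")
        assert expected_rt(spec, self.PARAMS) == 700 + 90 + 0.5 * 180

    def test_no_other_slope_means_location_irrelevant(self):
        p = ParticipantParams("p1", 700.0, 1.0, 0.0, 0.0, 0.0, False)
        for theta in (0, 45, 90, 135, 180):
            left = expected_rt(self._spec(orientation_deg=theta, person_location="left"), p)
            right = expected_rt(self._spec(orientation_deg=theta, person_location="right"), p)
            assert left == right

    def test_movement_shift(self):
        p = ParticipantParams("p1", 700.0, 1.0, 0.5, 25.0, 0.0, False)
        free = expected_rt(self._spec(), p)
        restricted = expected_rt(self._spec(movement="restricted"), p)
        assert restricted - free == 25.0


class TestSimulateTrial:
    def test_zero_noise_returns_linear_predictor(self, rng):
        cfg = CohortConfig(seed=1, sigma=0.0, tau=0.0)
        p = ParticipantParams("p1", 700.0, 1.0, 0.5, 0.0, 0.0, False)
        spec = pd.Series(dict(movement="free", person_location="none", orientation_deg=90))
        rt, _ = simulate_trial(spec, p, cfg, rng)
        assert rt == expected_rt(spec, p)

    def test_zero_error_probability_all_correct(self, rng):
        cfg = CohortConfig(seed=1)
        p = ParticipantParams("p1", 700.0, 1.0, 0.5, 0.0, 0.0, False)
        spec = pd.Series(dict(movement="free", person_location="none", orientation_deg=0))
        assert all(simulate_trial(spec, p, cfg, rng)[1] for _ in range(200))

    def test_ex_gaussian_residual_sd(self, rng):
        """Empirical RT residual SD matches sqrt(sigma^2 + tau^2) within 10%."""
        cfg = CohortConfig(seed=1)
        p = ParticipantParams("p1", 700.0, 1.0, 0.5, 0.0, 0.0, False)
        spec = pd.Series(dict(movement="free", person_location="none", orientation_deg=0))
        rts = np.array([simulate_trial(spec, p, cfg, rng)[0] for _ in range(5000)])
        expected_sd = np.hypot(cfg.sigma, cfg.tau)
        assert abs(rts.std(ddof=1) - expected_sd) / expected_sd < 0.10

    def test_rt_window_respected(self, rng):
        cfg = CohortConfig(seed=1, sigma=2000.0)
        p = ParticipantParams("p1", 700.0, 1.0, 0.5, 0.0, 0.0, False)
        spec = pd.Series(dict(movement="free", person_location="none", orientation_deg=0))
        rts = np.array([simulate_trial(spec, p, cfg, rng)[0] for _ in range(500)])
        assert rts.min() >= cfg.rt_floor and rts.max() <= cfg.rt_ceiling


class TestSimulateCohort:
    def test_shape_and_determinism(self, default_cohort):
        cfg, trials, quest, _ = default_cohort
        assert len(trials) == 79 * 576
        assert trials.participant_id.nunique() == 79
        trials2, quest2, _ = simulate_cohort(CohortConfig(seed=cfg.seed))
        assert trials.to_csv(index=False) == trials2.to_csv(index=False)
        assert quest.to_csv(index=False) == quest2.to_csv(index=False)

    def test_distinct_seeds_distinct_orderings_same_design(self, default_cohort):
        _, trials, _, _ = default_cohort
        other, _, _ = simulate_cohort(CohortConfig(seed=999))
        cols = ["participant_id", "movement", "person_location", "character",
                "form", "orientation_deg"]
        a = trials[cols].sort_values(cols).reset_index(drop=True)
        b = other[cols].sort_values(cols).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)
        assert not trials[cols].equals(other[cols])


@pytest.fixture(scope="module")
def big_sample():
    cfg = CohortConfig(seed=5, n_recruited=10_000, n_lapse=0,
                       n_missing_questionnaire=0)
    rng = np.random.default_rng(5)
    params = sample_cohort_params(cfg, rng)
    return cfg, params, generate_questionnaires(params, cfg, rng)


class TestQuestionnaires:
    def test_aq_marginal_mean(self, big_sample):
        cfg, _, quest = big_sample
        se = cfg.aq_sd / np.sqrt(len(quest))
        # truncation at 0/50 shifts the mean by well under one SE at n=1e4
        assert abs(quest.aq_total.mean() - 16.64) < 3 * se + 0.1

    def test_iri_marginal_mean_and_subscale_sum(self, big_sample):
        cfg, _, quest = big_sample
        se = cfg.iri_sd / np.sqrt(len(quest))
        assert abs(quest.iri_total.mean() - 68.45) < 3 * se + 0.1
        subs = quest[["iri_pt", "iri_ec", "iri_fs", "iri_pd"]]
        assert (subs.sum(axis=1) == quest.iri_total).all()

    def test_hard_ranges(self, big_sample):
        _, _, quest = big_sample
        assert quest.aq_total.between(0, 50).all()
        assert quest.iri_total.between(0, 112).all()
        assert quest.stq_sta.between(0, 37).all()
        assert quest.age.between(18, 35).all()

    def test_age_correlation_with_propensity(self, big_sample):
        """Copula consistency: empirical r between age and the true
        other-viewpoint slope lands within 0.03 of the 0.38 target at n=1e4."""
        _, params, quest = big_sample
        r = np.corrcoef(quest.age, params.beta_other)[0, 1]
        assert abs(r - 0.38) < 0.03

    def test_null_targets_give_near_zero_correlation(self, big_sample):
        _, params, quest = big_sample
        for col in ("aq_total", "iri_total"):
            assert abs(np.corrcoef(quest[col], params.beta_other)[0, 1]) < 0.1

    def test_stq_correlation_negative(self, big_sample):
        _, params, quest = big_sample
        r = np.corrcoef(quest.stq_sta, params.beta_other)[0, 1]
        assert abs(r - (-0.26)) < 0.03

    def test_missingness_applied_to_non_lapse_participants(self, default_cohort):
        _, _, quest, params = default_cohort
        missing = quest[quest.aq_total.isna()]
        assert len(missing) == 3
        assert not params.set_index("participant_id").loc[
            missing.participant_id, "lapse"].any()
        assert missing.age.notna().all()  # age comes from recruitment
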