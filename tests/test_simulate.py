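import numpy as np
import pandas as pd
import pytest

import burstrti as b
from burstrti.simulate import GeneratingParams, ParameterError


class TestGeneratingParams:
    def test_non_psd_covariance_rejected(self):
        bad = np.array([[1.0, 2.0, 0.0], [2.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        with pytest.raises(ParameterError):
            GeneratingParams(level3_cov=bad)

    def test_rates_validated(self):
        with pytest.raises(ParameterError):
            GeneratingParams(rate_missing=1.5)

    def test_group_mix_must_sum_to_one(self):
        with pytest.raises(ParameterError):
            GeneratingParams(group_mix=(0.5, 0.5, 0.5))


class TestSeedDeterminism:
    def test_identical_seed_identical_tables(self, small_design):
        d1 = b.generate_dataset(small_design, seed=9)
        d2 = b.generate_dataset(small_design, seed=9)
        for name in ("trials", "covariates", "domain_scores", "norms"):
            pd.testing.assert_frame_equal(d1[name], d2[name])

    def test_different_seed_differs(self, small_design):
        d1 = b.generate_dataset(small_design, seed=9)
        d2 = b.generate_dataset(small_design, seed=10)
        assert not d1["trials"]["rt_ms"].equals(d2["trials"]["rt_ms"])


class TestCovariates:
    def test_group_counts_match_mix(self, default_design):
        cov = b.sample_covariates(default_design, GeneratingParams(),
                                  np.random.default_rng(0))
        counts = cov["true_group"].value_counts()
        # expected counts 136 / 88 / 80 at n=304 under the default mix
        assert counts["HC"] == 136
        assert counts["CIND-S"] == 88
        assert counts["CIND-M"] == 80

    def test_age_within_range(self, default_design):
        cov = b.sample_covariates(default_design, GeneratingParams(),
                                  np.random.default_rng(1))
        assert cov["age_baseline"].between(64, 92).all()
        assert set(cov["sex"]) <= {0, 1}


class TestTrials:
    def test_full_trial_count_before_injection(self, small_design):
        p = GeneratingParams(rate_missing=0.0, rate_incorrect=0.0,
                             rate_outlier=0.0,
                             attrition_hazard=(0.0, 0.0, 0.0))
        trials, cov, _ = b.generate_trials(small_design, p,
                                           np.random.default_rng(2))
        per_cell = trials.groupby(["person_id", "task", "year",
                                   "session"]).size()
        n_tr = small_design.trials_per_session
        crt = per_cell.xs("CRT", level="task")
        brt = per_cell.xs("BRT", level="task")
        assert (crt == n_tr).all()
        assert (brt == n_tr + 1).all()   # structural extra leading trial

    def test_degenerate_generator_constant_latency(self, tiny_design):
        p = GeneratingParams(
            gamma100=0.0, gamma010=0.0, gamma001=0.0, gamma002=0.0,
            level3_cov=np.zeros((3, 3)), level2_vars=(0.0, 0.0),
            level1_var=0.0, rate_missing=0.0, rate_incorrect=0.0,
            rate_outlier=0.0, attrition_hazard=(0.0,),
            group_rti_shift=(0.0, 0.0, 0.0),
            group_year_slope_shift=(0.0, 0.0, 0.0),
            trial_noise_model=b.TrialNoiseModel(
                base_sd_ms=0.0, sd_per_t_unit=0.0, min_sd_ms=0.0,
                person_mean_sd_ms=0.0, trial_trend_ms=0.0,
                distribution="normal"))
        trials, _, _ = b.generate_trials(tiny_design, p,
                                         np.random.default_rng(3))
        crt = trials[trials["task"] == "CRT"]
        assert np.allclose(crt["rt_ms"], p.trial_noise_model.mean_rt_ms)

    def test_clean_rates_give_full_usability(self, tiny_design):
        p = GeneratingParams(rate_missing=0.0, rate_incorrect=0.0,
                             rate_outlier=0.0, attrition_hazard=(0.0,),
                             trial_noise_model=b.TrialNoiseModel(
                                 distribution="normal"))
        trials, _, _ = b.generate_trials(tiny_design, p,
                                         np.random.default_rng(4))
        clean, report = b.screen_trials(trials)
        for task in ("CRT", "BRT"):
            pct = report.percentages(task)
            assert pct["missing"] == 0.0
            assert pct["incorrect"] == 0.0
            # only natural distribution-tail trims remain
            assert pct["usable"] > 98.0

    def test_attrition_monotone(self, small_dataset):
        trials = small_dataset["trials"]
        present = trials.groupby(["person_id", "year"]).size().reset_index()
        for pid, sub in present.groupby("person_id"):
            years = sorted(sub["year"])
            assert years == list(range(1, len(years) + 1))

    def test_negative_weekly_dispersion_slope_recovered(self):
        """Monte-Carlo sign check: a generating practice gain in dispersion
        (negative weekly slope) shows up as a negative mean weekly trend in
        the measured ISDs."""
        design = b.BurstDesign(n_persons=25, n_years=1,
                               sessions_per_year=(5,),
                               trials_per_session=30, tasks=("BRT",))
        p = GeneratingParams.brt_like(
            gamma100=-1.0, attrition_hazard=(),
            rate_missing=0.0, rate_incorrect=0.0, rate_outlier=0.0)
        slopes = []
        for seed in range(50):
            trials, _, _ = b.generate_trials(design, {"BRT": p},
                                             np.random.default_rng(seed))
            clean, _ = b.screen_trials(trials)
            isd = b.compute_isd(b.residualize_trials(clean))
            by_week = isd.groupby("session")["isd_raw"].mean()
            x = by_week.index.to_numpy(float)
            slopes.append(np.polyfit(x, by_week.to_numpy(), 1)[0])
        assert np.mean(slopes) < 0


class TestDomainScores:
    def test_zero_noise_hc_scores_at_norm_mean(self, tiny_design):
        p = GeneratingParams(domain_noise_sd=0.0,
                             group_mix=(1.0, 0.0, 0.0))
        rng = np.random.default_rng(5)
        cov = b.sample_covariates(tiny_design, p, rng)
        scores, norms = b.generate_domain_scores(tiny_design, p, cov, rng)
        z = b.zscore_domains(scores, norms, cov)
        assert np.allclose(z["z"], 0.0)

    def test_zero_noise_cindm_two_deficits(self, tiny_design):
        p = GeneratingParams(domain_noise_sd=0.0,
                             group_mix=(0.0, 0.0, 1.0))
        rng = np.random.default_rng(6)
        cov = b.sample_covariates(tiny_design, p, rng)
        scores, norms = b.generate_domain_scores(tiny_design, p, cov, rng)
        clf = b.CognitiveStatusClassifier().fit(norms, cov)
        labels = clf.transform(scores)
        assert (labels["label"] == "CIND-M").all()
        assert (labels["deficit_count"] == 2).all()

    def test_missing_norm_cell_raises(self, tiny_design):
        p = GeneratingParams()
        rng = np.random.default_rng(7)
        cov = b.sample_covariates(tiny_design, p, rng)
        norms = b.make_norm_table().iloc[:-3]
        with pytest.raises(ParameterError):
            b.generate_domain_scores(tiny_design, p, cov, rng, norms=norms)


class TestLatentVarianceStructure:
    def test_decomposition_ratio_recovered(self, default_design):
        """The latent draw respects the generating level variances."""
        p = GeneratingParams.unconditional(34.0, 3.0, 13.0)
        rti = b.simulate_rti(default_design, p, np.random.default_rng(8))
        person_means = rti.groupby("person_id")["t_score"].mean()
        total = rti["t_score"].var()
        assert abs(total - 50.0) < 5.0
        assert abs(person_means.var() - 34.0) < 5.0
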