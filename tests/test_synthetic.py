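"""Schedule generation, simulated choosers and the BOLD forward model."""

import numpy as np
import pandas as pd
import pytest

from valuechoice import prospect, roi, synthetic
from valuechoice.synthetic import (
    BoldGroundTruth,
    RtConfig,
    generate_schedule,
    greedy_value_correlation,
    simulate_agent,
    simulate_bold,
    simulate_weighted_agent,
    trial_amplitudes,
)


class TestSchedule:
    def test_block_structure_and_counts(self, schedule):
        assert len(schedule) == 210
        assert schedule["condition"].value_counts().to_dict() == {
            "short": 70, "middle": 70, "long": 70,
        }
        # alternating blocks of 10 consecutive trials
        for block, grp in schedule.groupby("block_index"):
            assert len(grp) == 10
            assert grp["condition"].nunique() == 1
        block_conds = schedule.groupby("block_index")["condition"].first()
        assert list(block_conds[:6]) == ["short", "middle", "long"] * 2

    def test_attribute_ranges(self, schedule):
        for side in ("left", "right"):
            m = schedule[f"magnitude_{side}"]
            p = schedule[f"probability_{side}"]
            assert ((m > 0.1 - 1e-9) & (m <= 1.0 + 1e-9)).all()
            assert ((p >= 0.0999) & (p <= 0.9001)).all()
            # whole-percent probability grid
            np.testing.assert_allclose(np.round(p * 100), p * 100, atol=1e-9)

    def test_correlation_bound_via_independent_routine(self, schedule):
        # pandas' corr as the independent correlation implementation
        ev_l = schedule["magnitude_left"] * schedule["probability_left"]
        ev_r = schedule["magnitude_right"] * schedule["probability_right"]
        hi = pd.Series(np.maximum(ev_l, ev_r))
        lo = pd.Series(np.minimum(ev_l, ev_r))
        assert abs(hi.corr(lo)) <= 0.2
        assert greedy_value_correlation(schedule) == pytest.approx(
            hi.corr(lo), abs=1e-12
        )

    def test_nobrainers_dominate_and_fraction_zero_disables(self):
        sched = generate_schedule(n_per_condition=20, nobrainer_fraction=0.2, seed=5)
        nb = sched[sched["is_nobrainer"]]
        assert len(nb) == round(0.2 * len(sched))
        dom_left = (nb["magnitude_left"] > nb["magnitude_right"]) & (
            nb["probability_left"] > nb["probability_right"]
        )
        dom_right = (nb["magnitude_right"] > nb["magnitude_left"]) & (
            nb["probability_right"] > nb["probability_left"]
        )
        assert (dom_left | dom_right).all()

        none = generate_schedule(n_per_condition=20, nobrainer_fraction=0.0, seed=5)
        dom = (
            (none["magnitude_left"] > none["magnitude_right"])
            & (none["probability_left"] > none["probability_right"])
        ) | (
            (none["magnitude_left"] < none["magnitude_right"])
            & (none["probability_left"] < none["probability_right"])
        )
        assert not dom.any()

    def test_same_seed_identical(self):
        a = generate_schedule(n_per_condition=10, seed=42)
        b = generate_schedule(n_per_condition=10, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_timing_jitter_ranges(self, schedule):
        assert schedule["planned_iti_s"].between(3.5, 6.0).all()
        assert schedule["planned_outcome_delay_s"].between(3.5, 6.0).all()
        assert schedule["stimulus_onset_s"].is_monotonic_increasing

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            generate_schedule(n_per_condition=7)
        with pytest.raises(ValueError):
            generate_schedule(nobrainer_fraction=0.6)
        with pytest.raises(RuntimeError):
            generate_schedule(corr_target=1e-6, max_candidates=3, seed=0)


class TestAgent:
    def test_near_deterministic_agent_is_greedy(self, schedule):
        params = prospect.ProspectParams(1.0, 1.0, 1e-8)
        ds = simulate_agent(schedule, params, seed=0)
        ev_l = schedule["magnitude_left"] * schedule["probability_left"]
        ev_r = schedule["magnitude_right"] * schedule["probability_right"]
        unequal = ev_l != ev_r
        expected = np.where(ev_l > ev_r, "left", "right")
        assert (ds.loc[unequal, "choice"].to_numpy() == expected[unequal]).all()

    def test_rt_medians_near_calibration_targets(self, dataset):
        med = dataset.groupby("condition")["reaction_time_s"].median()
        for cond, target in [("short", 0.793), ("middle", 1.180), ("long", 3.366)]:
            assert med[cond] == pytest.approx(target, rel=0.10)

    def test_long_rts_include_viewing_period(self, dataset):
        long_rt = dataset.loc[dataset["condition"] == "long", "reaction_time_s"]
        assert (long_rt > 3.0).all()
        assert (long_rt <= 4.0).all()  # 3 s viewing + 1 s response window

    def test_equal_sev_trial_choice_rate_half(self):
        # one equal-option trial replicated: empirical left rate -> 0.5
        from conftest import make_trials

        base = make_trials([(0.5, 0.4, 0.5, 0.4, "left")] * 400)
        base["condition"] = "middle"
        params = prospect.ProspectParams(0.7, 1.3, 0.08)
        ds = simulate_agent(base.drop(columns=["choice"]).assign(choice="left"), params, seed=9)
        rate = (ds["choice"] == "left").mean()
        assert rate == pytest.approx(0.5, abs=0.07)  # binomial CI at n=400

    def test_choice_frequencies_converge_to_softmax(self, small_schedule):
        params = prospect.ProspectParams(0.9, 0.8, 0.1)
        trial = small_schedule.iloc[[0]]
        big = pd.concat([trial] * 10_000, ignore_index=True)
        big["block_index"] = 0
        ds = simulate_agent(big, params, seed=11)
        sev_l = prospect.subjective_ev(
            trial["magnitude_left"].item(), trial["probability_left"].item(), params
        )
        sev_r = prospect.subjective_ev(
            trial["magnitude_right"].item(), trial["probability_right"].item(), params
        )
        p_left, _ = prospect.choice_probability(sev_l, sev_r, params.tau)
        observed = (ds["choice"] == "left").mean()
        # binomial test against the closed-form softmax probability
        from scipy.stats import binomtest

        k = int((ds["choice"] == "left").sum())
        assert binomtest(k, 10_000, p_left).pvalue > 1e-4
        assert observed == pytest.approx(p_left, abs=0.02)

    def test_outcomes_independent_and_match_probability(self, schedule):
        params = prospect.ProspectParams(1.0, 1.0, 0.1)
        ds = simulate_agent(schedule, params, seed=21)
        both = (ds["outcome_left"] & ds["outcome_right"]).mean()
        neither = (~ds["outcome_left"] & ~ds["outcome_right"]).mean()
        assert 0 < both < 1 and 0 < neither < 1

    def test_missing_condition_in_rt_model_rejected(self, small_schedule):
        rt = RtConfig(median_s={"short": 0.8}, sigma={"short": 0.1})
        with pytest.raises(ValueError):
            simulate_agent(small_schedule, prospect.ProspectParams(1, 1, 0.1), rt)

    def test_missed_responses_only_in_deadline_conditions(self, schedule):
        rt = RtConfig(missed_prob=0.3)
        ds = simulate_agent(schedule, prospect.ProspectParams(1, 1, 0.1), rt, seed=2)
        missed = ds.loc[ds["choice"] == "missed"]
        assert len(missed) > 0
        assert set(missed["condition"]) <= {"short", "long"}
        assert missed["reaction_time_s"].isna().all()
        assert missed["chosen_value"].isna().all()


class TestWeightedAgent:
    def test_probability_only_agent_follows_probability(self, schedule):
        ds = simulate_weighted_agent(schedule, weight_probability=50.0, weight_magnitude=0.0, seed=1)
        dp = ds["probability_left"] - ds["probability_right"]
        informative = dp.abs() > 0.05
        agree = (ds.loc[informative, "choice"] == "left") == (dp[informative] > 0)
        assert agree.mean() > 0.95


@pytest.fixture(scope="module")
def sparse_dataset():
    """Widely spaced, epoch-grid-aligned trials: no overlap between responses."""
    sched = synthetic.generate_schedule(
        n_per_condition=20, iti_range=(20, 24), seed=7
    )
    sched["stimulus_onset_s"] = (
        np.round(sched["stimulus_onset_s"] / 0.3) * 0.3
        + np.arange(len(sched)) * 6.0
    )
    return simulate_agent(sched, prospect.ProspectParams(0.9, 0.8, 0.1), seed=8)


class TestBoldForwardModel:
    def test_equal_drive_trials_have_identical_epochs(self, sparse_dataset):
        truth = BoldGroundTruth("roi", "diff_coder", weight=1.0, noise_sd=0.0, tr_s=0.3)
        ts = simulate_bold(sparse_dataset, truth, seed=0)
        amp = trial_amplitudes(sparse_dataset, truth)
        epochs = roi.epoch_timeseries(
            ts, sparse_dataset.loc[sparse_dataset["choice"].isin(["left", "right"])]
        )
        # two trials with (near-)equal planted amplitude give equal responses
        order = np.argsort(amp.to_numpy())
        i, j = order[0], order[1]
        scale = amp.iloc[j] / amp.iloc[i]
        np.testing.assert_allclose(
            epochs.data[j], epochs.data[i] * scale, atol=1e-10 + 1e-8 * abs(scale)
        )

    def test_null_regime_yields_zero_value_betas(self, sparse_dataset):
        truth = BoldGroundTruth("roi", "null", noise_sd=0.0, tr_s=0.3)
        ts = simulate_bold(sparse_dataset, truth, seed=0)
        assert np.allclose(ts.values, ts.values[-1] * 0 + ts.values, atol=1e-12)
        _, amp = roi.analyze_subject(sparse_dataset, {"roi": ts})
        value_amp = amp.loc[
            amp["regressor"].isin(["chosen_value", "unchosen_value"]), "amplitude"
        ]
        np.testing.assert_allclose(value_amp, 0.0, atol=1e-10)

    def test_sum_coder_recovered_via_sum_diff_design(self, sparse_dataset):
        truth = BoldGroundTruth("roi", "sum_coder", weight=1.0, noise_sd=0.0, tr_s=0.3)
        ts = simulate_bold(sparse_dataset, truth, seed=0)
        valid = sparse_dataset.loc[sparse_dataset["choice"].isin(["left", "right"])]
        epochs = roi.epoch_timeseries(ts, valid)
        h = roi.canonical_hrf(0.3)
        for cond in ("short", "middle", "long"):
            sub = epochs.subset(epochs.conditions == cond)
            cond_ds = valid.loc[valid["condition"] == cond].copy()
            # identical standardization in both variants: z-score the raw
            # chosen/unchosen columns first, then form sum and difference
            cond_ds["chosen_value"] = synthetic.zscore(cond_ds["chosen_value"].to_numpy())
            cond_ds["unchosen_value"] = synthetic.zscore(cond_ds["unchosen_value"].to_numpy())
            design = roi.build_trial_design(cond_ds, "sum_diff", standardize=False)
            betas = roi.fit_timepoint_glm(sub, design)
            a_sum, *_ = roi.hrf_amplitude(betas["value_sum"].to_numpy(), h)
            a_diff, *_ = roi.hrf_amplitude(betas["value_difference"].to_numpy(), h)
            assert a_sum == pytest.approx(1.0, abs=1e-8)
            assert a_diff == pytest.approx(0.0, abs=1e-8)

    def test_ar1_noise_statistics(self, sparse_dataset):
        truth = BoldGroundTruth("roi", "null", noise_sd=2.0, ar1_coefficient=0.5, tr_s=1.0)
        ts = simulate_bold(sparse_dataset, truth, seed=3)
        x = ts.values - ts.values.mean()
        sd = x.std()
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert sd == pytest.approx(2.0, rel=0.15)
        assert r1 == pytest.approx(0.5, abs=0.1)

    def test_determinism(self, sparse_dataset):
        truth = BoldGroundTruth("roi", "diff_coder", noise_sd=1.0)
        a = simulate_bold(sparse_dataset, truth, seed=5)
        b = simulate_bold(sparse_dataset, truth, seed=5)
        np.testing.assert_array_equal(a.values, b.values)

    def test_invalid_regime_rejected(self):
        with pytest.raises(ValueError):
            BoldGroundTruth("roi", "max_coder")
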