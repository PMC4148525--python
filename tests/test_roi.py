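"""Epoching, trial-level GLMs, HRF amplitude fitting and group statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from valuechoice import roi, synthetic
from valuechoice.hrf import HrfParams, canonical_hrf
from valuechoice.roi import (
    EpochedTrials,
    RoiTimeseries,
    build_trial_design,
    epoch_timeseries,
    fit_timepoint_glm,
    hrf_amplitude,
    one_sample_t,
    paired_t,
    rm_anova_area_by_condition,
)


class TestCanonicalHrf:
    def test_causal_and_peak_normalized(self):
        h = canonical_hrf(0.3)
        assert h.size == 54
        assert h[0] == 0.0
        assert np.max(h) == pytest.approx(1.0, abs=1e-3)
        assert np.argmax(h) * 0.3 == pytest.approx(6.0, abs=0.3)

    def test_matches_gamma_density_difference(self):
        p = HrfParams()
        t = np.arange(54) * 0.3
        peak = stats.gamma.pdf(t, p.peak_delay_s + 1.0, scale=1.0)
        under = stats.gamma.pdf(t, p.undershoot_delay_s + 1.0, scale=1.0)
        raw = peak - under / 6.0
        scale = stats.gamma.pdf(6.0, 7.0) - stats.gamma.pdf(6.0, 17.0) / 6.0
        np.testing.assert_allclose(canonical_hrf(0.3), raw / scale, atol=1e-10)

    def test_undershoot_present(self):
        h = canonical_hrf(0.1, duration_s=32.0)
        t = np.arange(h.size) * 0.1
        assert h[(t > 12) & (t < 20)].min() < -0.02

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            HrfParams(peak_delay_s=-1)
        with pytest.raises(ValueError):
            canonical_hrf(0.0)


class TestEpoching:
    def test_constant_series_reproduced(self):
        ts = RoiTimeseries("r", np.full(100, 3.7), tr_s=3.0)
        ep = epoch_timeseries(ts, [0.0, 10.0, 33.3])
        np.testing.assert_allclose(ep.data, 3.7, atol=1e-10)
        assert ep.times.size == 54

    def test_aligned_onsets_pass_through_samples(self):
        rng = np.random.default_rng(0)
        ts = RoiTimeseries("r", rng.standard_normal(60), tr_s=2.0)
        ep = epoch_timeseries(ts, [10.0, 30.0], window_s=16.0, dt_s=2.0)
        for k, onset in enumerate([10.0, 30.0]):
            i0 = int(onset / 2.0)
            np.testing.assert_allclose(ep.data[k], ts.values[i0 : i0 + 8], atol=1e-12)

    def test_smooth_sine_interpolated_accurately(self):
        tr = 0.5
        t = np.arange(400) * tr
        f = 0.05  # well below Nyquist (1 Hz)
        ts = RoiTimeseries("r", np.sin(2 * np.pi * f * t), tr_s=tr)
        onsets = [20.0, 50.2, 100.7]
        ep = epoch_timeseries(ts, onsets)
        for k, onset in enumerate(onsets):
            expected = np.sin(2 * np.pi * f * (onset + ep.times))
            np.testing.assert_allclose(ep.data[k], expected, atol=1e-3)

    def test_overrunning_trials_dropped(self):
        ts = RoiTimeseries("r", np.zeros(20), tr_s=1.0)
        ep = epoch_timeseries(ts, [0.0, 10.0])
        assert ep.n_trials == 1 and ep.n_dropped == 1
        with pytest.raises(ValueError):
            epoch_timeseries(ts, [10.0, 15.0])


class TestTrialDesign:
    def test_zscored_columns(self, dataset):
        d = dataset.loc[dataset["condition"] == "middle"]
        X = build_trial_design(d, "chosen_unchosen")
        for col in X.columns:
            if col == "intercept":
                continue
            assert X[col].mean() == pytest.approx(0.0, abs=1e-12)
            assert X[col].std(ddof=0) == pytest.approx(1.0, abs=1e-12)

    def test_sum_diff_is_linear_map_of_chosen_unchosen(self, dataset):
        d = dataset.loc[dataset["condition"] == "short"]
        a = build_trial_design(d, "chosen_unchosen", standardize=False)
        b = build_trial_design(d, "sum_diff", standardize=False)
        np.testing.assert_allclose(
            b["value_sum"], a["chosen_value"] + a["unchosen_value"], atol=1e-12
        )
        np.testing.assert_allclose(
            b["value_difference"], a["chosen_value"] - a["unchosen_value"], atol=1e-12
        )

    def test_constant_column_dropped_with_warning(self, dataset):
        d = dataset.loc[dataset["condition"] == "short"].copy()
        d["outcome_left"] = True
        d["outcome_right"] = True
        with pytest.warns(UserWarning, match="outcome_value"):
            X = build_trial_design(d, "chosen_unchosen")
        assert "outcome_value" not in X.columns

    def test_missed_trials_excluded(self, dataset):
        d = dataset.loc[dataset["condition"] == "short"].copy()
        d.iloc[0, d.columns.get_loc("choice")] = "missed"
        X = build_trial_design(d, "chosen_unchosen")
        assert len(X) == len(d) - 1


@pytest.fixture(scope="module")
def planted():
    """Noiseless epochs built directly as design @ beta(t)."""
    rng = np.random.default_rng(1)
    n, t = 40, 54
    X = pd.DataFrame(
        {
            "a": rng.standard_normal(n),
            "b": rng.standard_normal(n),
            "intercept": np.ones(n),
        },
        index=np.arange(n),
    )
    times = np.arange(t) * 0.3
    beta = np.vstack([np.sin(times), np.cos(times), times * 0.1])
    data = X.to_numpy() @ beta
    epochs = EpochedTrials(
        data=data, times=times, trial_index=np.arange(n),
        conditions=np.full(n, "middle"),
    )
    return X, beta, epochs


class TestTimepointGlm:
    def test_recovers_planted_beta_timecourse(self, planted):
        X, beta, epochs = planted
        est = fit_timepoint_glm(epochs, X)
        np.testing.assert_allclose(est.to_numpy().T, beta, atol=1e-8)

    def test_intercept_only_returns_mean(self, planted):
        X, _, epochs = planted
        only = X[["intercept"]]
        est = fit_timepoint_glm(epochs, only)
        np.testing.assert_allclose(
            est["intercept"].to_numpy(), epochs.data.mean(axis=0), atol=1e-10
        )

    def test_column_order_invariance(self, planted):
        X, _, epochs = planted
        a = fit_timepoint_glm(epochs, X)
        b = fit_timepoint_glm(epochs, X[["b", "intercept", "a"]])
        np.testing.assert_allclose(a["a"], b["a"], atol=1e-10)

    def test_singular_design_fails(self, planted):
        X, _, epochs = planted
        X2 = X.copy()
        X2["dup"] = X2["a"]
        with pytest.raises(np.linalg.LinAlgError):
            fit_timepoint_glm(epochs, X2)


class TestHrfAmplitude:
    def test_exact_scalar(self):
        h = canonical_hrf(0.3)
        a, resid, lag = hrf_amplitude(2.5 * h, h)
        assert a == pytest.approx(2.5, abs=1e-12)
        assert resid == pytest.approx(0.0, abs=1e-10)
        assert lag == 0.0

    def test_orthogonal_gives_zero(self):
        h = canonical_hrf(0.3)
        e = np.zeros_like(h)
        e[0] = 1.0  # h[0] == 0, so e is orthogonal to h
        a, _, _ = hrf_amplitude(e, h)
        assert a == pytest.approx(0.0, abs=1e-12)

    def test_noisy_recovery_monte_carlo(self):
        h = canonical_hrf(0.3)
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(100):
            e = 1.7 * h + rng.normal(0, 0.1, size=h.size)
            a, _, _ = hrf_amplitude(e, h)
            hits += abs(a - 1.7) <= 0.1
        assert hits >= 90  # ~95% within the analytic +/-0.1 band

    def test_lag_search_finds_shift(self):
        h = canonical_hrf(0.3)
        shifted = np.roll(h, 4)
        shifted[:4] = 0
        a, _, lag = hrf_amplitude(3.0 * shifted, h, lag_search_s=3.0)
        assert lag == pytest.approx(1.2, abs=1e-9)
        assert a == pytest.approx(3.0, abs=1e-9)

    def test_zero_hrf_rejected(self):
        with pytest.raises(ValueError):
            hrf_amplitude(np.ones(5), np.zeros(5))


class TestGroupStats:
    def test_one_sample_t_matches_hand_computation(self):
        # 5-subject toy vector worked through the textbook formula
        x = np.array([0.3, -0.1, 0.5, 0.2, 0.4])
        mean, sd = x.mean(), x.std(ddof=1)
        t_hand = mean / (sd / np.sqrt(5))
        t, df, p = one_sample_t(x)
        assert t == pytest.approx(t_hand, abs=1e-10)
        assert df == 4
        assert p == pytest.approx(2 * stats.t.sf(abs(t_hand), 4), abs=1e-12)

    def test_paired_t_matches_hand_computation(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([1.2, 1.8, 2.6, 4.5, 4.9])
        d = a - b
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        t, df, p = paired_t(a, b)
        assert t == pytest.approx(t_hand, abs=1e-10)

    def test_identical_conditions_give_t0_p1(self):
        x = np.array([0.2, 0.4, 0.1])
        t, df, p = paired_t(x, x)
        assert t == 0.0 and p == 1.0

    def test_one_tailed_is_half_of_two_tailed_for_positive_t(self):
        x = np.array([0.3, 0.1, 0.5, 0.2])
        t2, _, p2 = one_sample_t(x, tail="two-sided")
        t1, _, p1 = one_sample_t(x, tail="greater")
        assert t1 == t2 and t1 > 0
        assert p1 == pytest.approx(p2 / 2, abs=1e-12)


def _anova_table(y):
    """Tidy amplitude frame from an (n_subj, 2 areas, 3 conds) array."""
    n = y.shape[0]
    rows = []
    for s in range(n):
        for i, area in enumerate(["A", "B"]):
            for j, cond in enumerate(["short", "middle", "long"]):
                rows.append((s, area, cond, "unchosen_value", y[s, i, j]))
    return pd.DataFrame(
        rows, columns=["subject", "roi", "condition", "regressor", "amplitude"]
    )


class TestRmAnova:
    def test_df_convention(self):
        rng = np.random.default_rng(0)
        table = _anova_table(rng.standard_normal((28, 2, 3)))
        res = rm_anova_area_by_condition(table, "unchosen_value").set_index("effect")
        assert (res.loc["area", ["df1", "df2"]] == [1, 27]).all()
        assert (res.loc["condition", ["df1", "df2"]] == [2, 54]).all()
        assert (res.loc["area:condition", ["df1", "df2"]] == [2, 54]).all()

    def test_zero_between_cell_variation_gives_f0(self):
        y = np.tile(np.arange(4)[:, None, None], (1, 2, 3)).astype(float)
        res = rm_anova_area_by_condition(_anova_table(y), "unchosen_value")
        np.testing.assert_allclose(res["F"], 0.0, atol=1e-12)

    def test_matches_explicit_ss_formulas_on_toy_table(self):
        # 4-subject toy table worked through the explicit SS decomposition
        rng = np.random.default_rng(3)
        y = rng.standard_normal((4, 2, 3)) + np.array([[0.5, 0, -0.5], [0, 0, 0]])
        n, a, c = y.shape
        grand = y.mean()
        ss_area = n * c * ((y.mean(axis=(0, 2)) - grand) ** 2).sum()
        m_sa = y.mean(axis=2)
        ss_err_area = c * (
            (m_sa - y.mean(axis=(1, 2))[:, None] - y.mean(axis=(0, 2))[None, :] + grand) ** 2
        ).sum()
        f_area = (ss_area / (a - 1)) / (ss_err_area / ((a - 1) * (n - 1)))
        res = rm_anova_area_by_condition(_anova_table(y), "unchosen_value").set_index("effect")
        assert res.loc["area", "F"] == pytest.approx(f_area, abs=1e-10)

    def test_matches_pingouin_two_way_rm(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(9)
        y = rng.standard_normal((6, 2, 3))
        table = _anova_table(y)
        ours = rm_anova_area_by_condition(table, "unchosen_value").set_index("effect")
        theirs = pingouin.rm_anova(
            data=table, dv="amplitude", within=["roi", "condition"],
            subject="subject", detailed=True,
        )
        mapping = {"roi": "area", "condition": "condition", "roi * condition": "area:condition"}
        for src, dst in mapping.items():
            row = theirs.loc[theirs["Source"] == src].iloc[0]
            assert ours.loc[dst, "F"] == pytest.approx(row["F"], rel=1e-8)

    def test_missing_cells_rejected(self):
        table = _anova_table(np.zeros((3, 2, 3))).iloc[:-1]
        with pytest.raises(ValueError):
            rm_anova_area_by_condition(table, "unchosen_value")


class TestAnalyzeSubject:
    def test_tidy_output_shape(self, dataset):
        truth = synthetic.BoldGroundTruth("vmPFC", "diff_coder", noise_sd=0.5)
        ts = synthetic.simulate_bold(dataset, truth, seed=0)
        tc, amp = roi.analyze_subject(dataset, {"vmPFC": ts})
        assert set(amp["condition"]) == {"short", "middle", "long"}
        assert {"chosen_value", "unchosen_value", "intercept"} <= set(amp["regressor"])
        n_reg = amp.groupby("condition").size().iloc[0]
        assert len(tc) == 3 * n_reg * 54
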