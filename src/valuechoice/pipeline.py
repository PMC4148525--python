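"""End-to-end pipeline: simulate -> fit -> behaviour -> ROI -> brain-behaviour.

Every stage is deterministic given the run configuration's seed: per-subject
seeds are drawn once from a master generator, all tables are written in fixed
column and row order, and re-running with the same configuration reproduces
byte-identical tables.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import behaviour, brain_behaviour, io, prospect, roi, synthetic
from .config import RunConfig
from .hrf import HrfParams

log = logging.getLogger("valuechoice")

_SEED_MOD = 2**31 - 1


def _subject_seeds(master_seed: int, n: int, stream: int) -> np.ndarray:
    """Independent per-subject seeds for one pipeline stage."""
    rng = np.random.default_rng([master_seed, stream])
    return rng.integers(0, _SEED_MOD, size=n)


def _roi_truths(config: RunConfig) -> list[synthetic.BoldGroundTruth]:
    return [
        synthetic.BoldGroundTruth(roi_label=label, tr_s=config.tr_s, **kwargs)
        for label, kwargs in config.rois.items()
    ]


def simulate_cohort(config: RunConfig, out_dir=None, rt_model=None):
    """Simulate a cohort: one schedule (shared by default), one softmax agent
    and one BOLD series per ROI per subject.

    Returns ``(datasets, timeseries)``: dict subject -> events DataFrame and
    dict subject -> {roi: RoiTimeseries}.  When ``out_dir`` is given, events,
    timeseries and ground-truth sidecars are written there.
    """
    config.validate()
    rt_model = rt_model or synthetic.RtConfig(**config.rt)
    truths = _roi_truths(config)
    sched_seeds = _subject_seeds(config.seed, config.n_subjects, stream=1)
    agent_seeds = _subject_seeds(config.seed, config.n_subjects, stream=2)
    bold_seeds = _subject_seeds(config.seed, config.n_subjects * len(truths), stream=3)
    param_rng = np.random.default_rng([config.seed, 4])

    shared = (
        synthetic.generate_schedule(seed=int(sched_seeds[0]), **config.schedule)
        if config.shared_schedule
        else None
    )
    datasets: dict[int, pd.DataFrame] = {}
    series: dict[int, dict[str, roi.RoiTimeseries]] = {}
    a_lo, a_hi = config.agent["alpha_range"]
    g_lo, g_hi = config.agent["gamma_range"]
    t_lo, t_hi = config.agent["tau_range"]
    for s in range(config.n_subjects):
        schedule = shared if shared is not None else synthetic.generate_schedule(
            seed=int(sched_seeds[s]), **config.schedule
        )
        params = prospect.ProspectParams(
            alpha=float(np.exp(param_rng.uniform(np.log(a_lo), np.log(a_hi)))),
            gamma=float(np.exp(param_rng.uniform(np.log(g_lo), np.log(g_hi)))),
            tau=float(np.exp(param_rng.uniform(np.log(t_lo), np.log(t_hi)))),
            softmax_form=config.fit["softmax_form"],
        )
        ds = synthetic.simulate_agent(schedule, params, rt_model, seed=int(agent_seeds[s]))
        ds.attrs["true_params"] = params
        datasets[s] = ds
        series[s] = {}
        for j, truth in enumerate(truths):
            ts = synthetic.simulate_bold(
                ds, truth, seed=int(bold_seeds[s * len(truths) + j])
            )
            series[s][truth.roi_label] = ts
        if out_dir is not None:
            out_dir = Path(out_dir)
            (out_dir / "events").mkdir(parents=True, exist_ok=True)
            (out_dir / "timeseries").mkdir(parents=True, exist_ok=True)
            io.write_events(ds, io.events_path(out_dir / "events", s))
            io.write_timeseries(series[s], io.bold_path(out_dir / "timeseries", s))
    if out_dir is not None:
        io.write_truth_sidecar(truths, Path(out_dir) / "ground_truth.txt")
    return datasets, series


def fit_stage(datasets, config: RunConfig) -> pd.DataFrame:
    """Grid-Bayesian prospect fits for every subject (per condition by default)."""
    fit_cfg = prospect.FitConfig(
        n_points=config.fit.get("n_points", 150),
        softmax_form=config.fit.get("softmax_form", "temperature_divide"),
        per_condition=config.fit.get("per_condition", True),
    )
    if config.fit.get("bounds"):
        fit_cfg.bounds = {k: tuple(v) for k, v in config.fit["bounds"].items()}
    tables = []
    for s, ds in datasets.items():
        fits = prospect.fit_prospect(ds, fit_cfg)
        tables.append(prospect.fits_to_table(fits, subject=s))
    return pd.concat(tables, ignore_index=True)


def behaviour_stage(datasets, config: RunConfig):
    """Accuracy, choice regressions and group comparisons across subjects."""
    acc_rows, coef_tables = [], []
    for s, ds in datasets.items():
        acc = behaviour.accuracy_higher_ev(ds)
        for cond, val in acc.items():
            acc_rows.append((s, cond, val))
        coefs = behaviour.choice_regression(ds)
        coefs.insert(0, "subject", s)
        coef_tables.append(coefs)
    accuracy = pd.DataFrame(acc_rows, columns=["subject", "condition", "accuracy_pct"])
    coefs = pd.concat(coef_tables, ignore_index=True)
    comparisons = []
    acc_cmp = behaviour.compare_conditions(
        accuracy.rename(columns={"accuracy_pct": "value"})
    )
    acc_cmp.insert(0, "measure", "accuracy_pct")
    comparisons.append(acc_cmp)
    if len(datasets) >= 2:
        rp_rm = behaviour.probability_vs_magnitude_tests(coefs)
        rp_rm.insert(0, "measure", "rp_minus_rm")
        comparisons.append(rp_rm)
    return accuracy, coefs, pd.concat(comparisons, ignore_index=True)


def parameter_comparisons(param_table: pd.DataFrame) -> pd.DataFrame:
    """Between-condition and vs-reference tests of fitted alpha, gamma, tau."""
    out = []
    for name, ref in [("alpha", 1.0), ("gamma", 1.0), ("tau", None)]:
        tidy = param_table.rename(columns={name: "value"})[
            ["subject", "condition", "value"]
        ]
        cmp = behaviour.compare_conditions(tidy, reference=ref)
        cmp.insert(0, "parameter", name)
        out.append(cmp)
    return pd.concat(out, ignore_index=True)


def roi_stage(datasets, series, config: RunConfig, param_table=None):
    """Epoched GLMs, HRF amplitudes and group statistics for every subject."""
    hrf_params = HrfParams()
    tcs, amps = [], []
    for s, ds in datasets.items():
        d = ds
        if config.use_fitted_values:
            if param_table is None:
                raise ValueError("use_fitted_values requires the fit stage output")
            d = ds.copy()
            for cond, row in (
                param_table.loc[param_table["subject"] == s].set_index("condition").iterrows()
            ):
                params = prospect.ProspectParams(row["alpha"], row["gamma"], row["tau"])
                sub = roi.with_subjective_values(ds.loc[ds["condition"] == cond], params)
                d.loc[sub.index, ["chosen_value", "unchosen_value"]] = sub[
                    ["chosen_value", "unchosen_value"]
                ]
        tc, amp = roi.analyze_subject(
            d,
            series[s],
            variant=config.glm_variant,
            hrf_params=hrf_params,
            window_s=config.epoch["window_s"],
            dt_s=config.epoch["dt_s"],
        )
        tc.insert(0, "subject", s)
        amp.insert(0, "subject", s)
        tcs.append(tc)
        amps.append(amp)
    timecourses = pd.concat(tcs, ignore_index=True)
    amplitudes = pd.concat(amps, ignore_index=True)
    group = contrasts = anova = None
    if len(datasets) >= 3:
        group = roi.group_effect_tests(amplitudes)
        value_regs = [
            r for r in ("unchosen_value", "chosen_value", "value_sum", "value_difference")
            if r in set(amplitudes["regressor"])
        ]
        contrasts = pd.concat(
            [roi.condition_contrasts(amplitudes, regressor=r) for r in value_regs],
            ignore_index=True,
        )
        if len(config.rois) == 2 and config.glm_variant == "chosen_unchosen":
            anova = pd.concat(
                [
                    roi.rm_anova_area_by_condition(amplitudes, r).assign(regressor=r)
                    for r in ("chosen_value", "unchosen_value")
                ],
                ignore_index=True,
            )
    return timecourses, amplitudes, group, contrasts, anova


def brain_behaviour_stage(amplitudes, accuracy, config: RunConfig):
    """Per-condition GLM of accuracy on chosen/unchosen amplitudes of two ROIs."""
    rois = tuple(config.rois)
    if len(rois) != 2 or config.glm_variant != "chosen_unchosen":
        return None
    if config.n_subjects < 8:  # 5-regressor across-subject GLM needs headroom
        log.info("brain-behaviour stage skipped: fewer than 8 subjects")
        return None
    tables = []
    for cond in sorted(accuracy["condition"].unique()):
        X, y = brain_behaviour.build_brain_behaviour_design(
            amplitudes, accuracy, cond, rois
        )
        table = brain_behaviour.fit_brain_behaviour(X, y)
        table.insert(0, "condition", cond)
        tables.append(table)
    return pd.concat(tables, ignore_index=True)


def _write(df: pd.DataFrame | None, path: Path) -> None:
    if df is not None:
        df.to_csv(path, sep="\t", index=False, na_rep="n/a")


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute all stages in order, writing tidy tables under ``out_dir``.

    Returns a summary dict (also written as ``report.json``).  Any stage
    failure aborts with the stage name in the exception context.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_dir / "config_used.yaml")
    stage = "simulate"
    try:
        log.info("stage %s", stage)
        datasets, series = simulate_cohort(config, out_dir=out_dir)

        stage = "fit"
        log.info("stage %s", stage)
        params = fit_stage(datasets, config)
        _write(params, out_dir / "parameters.tsv")
        if config.fit.get("per_condition", True) and config.n_subjects >= 2:
            _write(parameter_comparisons(params), out_dir / "parameter_comparisons.tsv")

        stage = "behaviour"
        log.info("stage %s", stage)
        accuracy, coefs, comparisons = behaviour_stage(datasets, config)
        _write(accuracy, out_dir / "accuracy.tsv")
        _write(coefs, out_dir / "choice_regression.tsv")
        if config.n_subjects >= 2:
            _write(comparisons, out_dir / "behaviour_comparisons.tsv")

        stage = "roi-analysis"
        log.info("stage %s", stage)
        timecourses, amplitudes, group, contrasts, anova = roi_stage(
            datasets, series, config, param_table=params
        )
        _write(timecourses, out_dir / "effect_timecourses.tsv")
        _write(amplitudes, out_dir / "amplitudes.tsv")
        _write(group, out_dir / "group_effect_tests.tsv")
        _write(contrasts, out_dir / "condition_contrasts.tsv")
        _write(anova, out_dir / "anova_area_by_condition.tsv")

        stage = "brain-behaviour"
        log.info("stage %s", stage)
        bb = brain_behaviour_stage(amplitudes, accuracy, config)
        _write(bb, out_dir / "brain_behaviour.tsv")

        stage = "report"
        summary = {
            "seed": config.seed,
            "n_subjects": config.n_subjects,
            "mean_accuracy_pct": {
                cond: round(float(g["accuracy_pct"].mean()), 4)
                for cond, g in accuracy.groupby("condition")
            },
            "mean_fitted_params": {
                name: round(float(params[name].mean()), 4)
                for name in ("alpha", "gamma", "tau")
            },
            "n_trials_per_subject": int(len(next(iter(datasets.values())))),
            "rois": list(config.rois),
        }
        (out_dir / "report.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        if config.make_plots:
            stage = "plots"
            from . import plots

            plots.plot_behaviour_summary(accuracy, coefs, out_dir / "behaviour.png")
            plots.plot_effect_timecourses(timecourses, out_dir / "effect_timecourses.png")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return summary
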