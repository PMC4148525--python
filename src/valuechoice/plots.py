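"""Summary figures: behavioural panels and effect-size timecourses."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

_CONDITION_ORDER = ["short", "middle", "long"]


def plot_behaviour_summary(accuracy, coefs, path) -> None:
    """Accuracy per condition and group-mean choice-regression coefficients."""
    fig, axes = plt.subplots(1, 1 + coefs["condition"].nunique(), figsize=(12, 3.2))
    conds = [c for c in _CONDITION_ORDER if c in set(accuracy["condition"])]
    means = [accuracy.loc[accuracy["condition"] == c, "accuracy_pct"].mean() for c in conds]
    sems = [
        accuracy.loc[accuracy["condition"] == c, "accuracy_pct"].sem() for c in conds
    ]
    axes[0].bar(conds, means, yerr=np.nan_to_num(sems), color="0.6")
    axes[0].set_ylabel("% higher-EV choices")
    axes[0].set_ylim(50, 100)
    for ax, cond in zip(axes[1:], conds):
        sub = coefs.loc[(coefs["condition"] == cond) & (coefs["regressor"] != "intercept")]
        g = sub.groupby("regressor")["coef"].agg(["mean", "sem"])
        ax.bar(g.index, g["mean"], yerr=np.nan_to_num(g["sem"].to_numpy()), color="0.6")
        ax.axhline(0, color="k", lw=0.5)
        ax.set_title(cond)
        ax.tick_params(axis="x", rotation=60)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_effect_timecourses(timecourses, path, regressors=None) -> None:
    """Across-subject mean +/- SEM effect timecourses per ROI and condition."""
    regressors = regressors or [
        r
        for r in ("chosen_value", "unchosen_value", "value_sum", "value_difference")
        if r in set(timecourses["regressor"])
    ]
    rois = sorted(timecourses["roi"].unique())
    conds = [c for c in _CONDITION_ORDER if c in set(timecourses["condition"])]
    fig, axes = plt.subplots(
        len(rois), len(conds), figsize=(3.6 * len(conds), 2.8 * len(rois)),
        squeeze=False, sharex=True,
    )
    for i, roi_label in enumerate(rois):
        for j, cond in enumerate(conds):
            ax = axes[i][j]
            for reg in regressors:
                sub = timecourses.loc[
                    (timecourses["roi"] == roi_label)
                    & (timecourses["condition"] == cond)
                    & (timecourses["regressor"] == reg)
                ]
                g = sub.groupby("time_s")["beta"].agg(["mean", "sem"])
                ax.plot(g.index, g["mean"], label=reg)
                if g["sem"].notna().all():
                    ax.fill_between(
                        g.index, g["mean"] - g["sem"], g["mean"] + g["sem"], alpha=0.25
                    )
            ax.axhline(0, color="k", lw=0.5)
            if i == 0:
                ax.set_title(cond)
            if j == 0:
                ax.set_ylabel(f"{roi_label}\neffect size")
            if i == len(rois) - 1:
                ax.set_xlabel("time from stimulus (s)")
    axes[0][0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
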