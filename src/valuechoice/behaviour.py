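"""Choice-accuracy metrics, trial-level choice regressions and group comparisons.

The trial-level regression models the probability of choosing the *left*
option with a logistic GLM whose regressors follow the sign convention
"positive = increases the probability to select the option":

- ``RP`` / ``RM``: left-minus-right differences in reward probability /
  magnitude;
- ``pC``: previous-trial choice side (+1 left, -1 right; 0 at block starts);
- ``pO``: previous-trial outcome of the chosen side (+1 rewarded, -1 not;
  0 at block starts) under the default ``side`` coding, or the rewarded-side
  code ``pC`` when rewarded / ``-pC`` when not under the ``winstay`` coding;
- ``RPxRT`` / ``RMxRT``: products of the within-condition standardized
  reaction time with the RP / RM columns.

Regressions are fitted per subject and condition; group inference is by
paired and one-sample t-tests across subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .roi import one_sample_t, paired_t
from .synthetic import zscore

DEFAULT_REGRESSORS = ("RP", "RM", "pO", "pC", "RPxRT", "RMxRT")


def accuracy_higher_ev(dataset: pd.DataFrame) -> pd.Series:
    """Percent choices of the higher objective-EV option, per condition.

    Only non-missed trials with unequal objective EVs enter the numerator and
    denominator.  Fails if a condition has no eligible trials.
    """
    ev_l = (dataset["magnitude_left"] * dataset["probability_left"]).to_numpy()
    ev_r = (dataset["magnitude_right"] * dataset["probability_right"]).to_numpy()
    valid = dataset["choice"].isin(["left", "right"]).to_numpy() & (ev_l != ev_r)
    out = {}
    for cond in sorted(dataset["condition"].unique()):
        m = valid & (dataset["condition"] == cond).to_numpy()
        if not m.any():
            raise ValueError(f"condition {cond!r} has no eligible trials")
        left_better = ev_l[m] > ev_r[m]
        chose_left = dataset.loc[m, "choice"].to_numpy() == "left"
        out[cond] = 100.0 * float(np.mean(chose_left == left_better))
    return pd.Series(out, name="accuracy_pct")


@dataclass
class ChoiceRegressionSpec:
    """Regressor set and coding conventions for the choice regression."""

    regressors: tuple[str, ...] = DEFAULT_REGRESSORS
    previous_coding: str = "side"  # or "winstay"
    standardize_rt: bool = True
    ridge_alpha: float = 0.0

    def __post_init__(self) -> None:
        unknown = set(self.regressors) - set(DEFAULT_REGRESSORS)
        if unknown:
            raise ValueError(f"unknown regressors: {sorted(unknown)}")
        if self.previous_coding not in ("side", "winstay"):
            raise ValueError(f"unknown previous_coding {self.previous_coding!r}")


def _previous_trial_codes(d: pd.DataFrame, coding: str):
    """pC/pO columns from the preceding trial within the same block."""
    n = len(d)
    pc = np.zeros(n)
    po = np.zeros(n)
    block = d["block_index"].to_numpy()
    tidx = d["trial_index"].to_numpy()
    choice = d["choice"].to_numpy()
    out_l = d["outcome_left"].to_numpy(bool)
    out_r = d["outcome_right"].to_numpy(bool)
    for i in range(1, n):
        if block[i] != block[i - 1] or tidx[i] != tidx[i - 1] + 1:
            continue  # block start or gap: coded 0
        if choice[i - 1] == "missed":
            continue
        side = 1.0 if choice[i - 1] == "left" else -1.0
        rewarded = out_l[i - 1] if choice[i - 1] == "left" else out_r[i - 1]
        pc[i] = side
        if coding == "side":
            po[i] = 1.0 if rewarded else -1.0
        else:  # winstay: points at the previously rewarded side
            po[i] = side if rewarded else -side
    return pc, po


def _design_for_condition(d: pd.DataFrame, spec: ChoiceRegressionSpec) -> pd.DataFrame:
    rp = (d["probability_left"] - d["probability_right"]).to_numpy(float)
    rm = (d["magnitude_left"] - d["magnitude_right"]).to_numpy(float)
    pc, po = _previous_trial_codes(d, spec.previous_coding)
    rt = d["reaction_time_s"].to_numpy(float)
    z_rt = zscore(rt) if spec.standardize_rt else rt
    cols = {
        "RP": rp,
        "RM": rm,
        "pO": po,
        "pC": pc,
        "RPxRT": rp * z_rt,
        "RMxRT": rm * z_rt,
    }
    X = pd.DataFrame({k: cols[k] for k in spec.regressors}, index=d.index)
    X.insert(0, "intercept", 1.0)
    return X


def choice_regression(
    dataset: pd.DataFrame, spec: ChoiceRegressionSpec | None = None
) -> pd.DataFrame:
    """Per-condition logistic regression of choose-left on the requested columns.

    Returns a tidy coefficient table (condition, regressor, coef, se, z, p,
    diagnostic).  Quasi-separation or non-convergence is flagged in the
    diagnostic column rather than failing silently; with ``ridge_alpha > 0``
    a small L2 penalty is used as a fallback in those cases.
    """
    spec = spec or ChoiceRegressionSpec()
    rows = []
    for cond in sorted(dataset["condition"].unique()):
        d = dataset.loc[
            (dataset["condition"] == cond) & dataset["choice"].isin(["left", "right"])
        ]
        if len(d) < 20:
            raise ValueError(f"condition {cond!r} has fewer than 20 valid trials")
        y = (d["choice"] == "left").astype(float).to_numpy()
        X = _design_for_condition(d, spec)
        rank = np.linalg.matrix_rank(X.to_numpy())
        if rank < X.shape[1]:
            rows.extend(
                (cond, reg, np.nan, np.nan, np.nan, np.nan, "rank_deficient")
                for reg in X.columns
            )
            continue
        diagnostic = "ok"
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            if not res.mle_retvals.get("converged", False):
                diagnostic = "not_converged"
            elif np.any(np.abs(res.params) > 20):
                diagnostic = "separation_suspected"
            params, bse, z, p = res.params, res.bse, res.tvalues, res.pvalues
        except Exception:
            diagnostic = "failed"
            params = pd.Series(np.nan, index=X.columns)
            bse = z = p = params
        if diagnostic != "ok" and spec.ridge_alpha > 0:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(y, X, family=sm.families.Binomial()).fit_regularized(
                    alpha=spec.ridge_alpha, L1_wt=0.0
                )
            params = pd.Series(res.params, index=X.columns)
            bse = z = p = pd.Series(np.nan, index=X.columns)
            diagnostic += "+ridge"
        for reg in X.columns:
            rows.append(
                (cond, reg, params[reg], bse[reg], z[reg], p[reg], diagnostic)
            )
    return pd.DataFrame(
        rows, columns=["condition", "regressor", "coef", "se", "z", "p", "diagnostic"]
    )


# ---------------------------------------------------------------------------
# Group-level comparisons
# ---------------------------------------------------------------------------

def compare_conditions(
    per_subject: pd.DataFrame,
    value_col: str = "value",
    pairs=(("short", "middle"), ("short", "long"), ("middle", "long")),
    reference: float | None = None,
    tail: str = "two-sided",
) -> pd.DataFrame:
    """Paired t-tests between conditions and one-sample tests vs a reference.

    ``per_subject`` is tidy with columns (subject, condition, ``value_col``).
    Paired tests use only subjects present in both conditions.
    """
    wide = per_subject.pivot_table(index="subject", columns="condition", values=value_col)
    if wide.shape[0] < 2:
        raise ValueError("need >= 2 subjects")
    rows = []
    for a, b in pairs:
        if a not in wide.columns or b not in wide.columns:
            continue
        pairdata = wide[[a, b]].dropna()
        if len(pairdata) < 2:  # failed per-subject fits leave too few pairs
            rows.append((f"{a} vs {b}", a, b, np.nan, len(pairdata) - 1, np.nan, tail))
            continue
        t, df, p = paired_t(pairdata[a], pairdata[b], tail)
        rows.append((f"{a} vs {b}", a, b, t, df, p, tail))
    if reference is not None:
        for cond in wide.columns:
            vals = wide[cond].dropna()
            if len(vals) < 2:
                rows.append((f"{cond} vs {reference}", cond, None, np.nan, len(vals) - 1, np.nan, tail))
                continue
            t, df, p = one_sample_t(vals, reference, tail)
            rows.append((f"{cond} vs {reference}", cond, None, t, df, p, tail))
    return pd.DataFrame(
        rows, columns=["comparison", "cond_a", "cond_b", "t", "df", "p", "tail"]
    )


def probability_vs_magnitude_tests(
    coef_table: pd.DataFrame,
    pairs=(("short", "middle"), ("short", "long"), ("middle", "long")),
) -> pd.DataFrame:
    """Tests on the probability-minus-magnitude coefficient difference.

    ``coef_table`` is the stacked per-subject output of
    :func:`choice_regression` with an added ``subject`` column.  Within each
    condition the RP-RM difference is tested against zero across subjects;
    between conditions the differences are compared pairwise.
    """
    wide = coef_table.pivot_table(
        index=["subject", "condition"], columns="regressor", values="coef"
    ).reset_index()
    wide["rp_minus_rm"] = wide["RP"] - wide["RM"]
    rows = []
    for cond, grp in wide.groupby("condition"):
        vals = grp["rp_minus_rm"].dropna().to_numpy()
        if vals.size < 2:
            rows.append((f"RP-RM within {cond}", cond, None, np.nan, vals.size - 1, np.nan, "two-sided"))
            continue
        t, df, p = one_sample_t(vals, 0.0, "two-sided")
        rows.append((f"RP-RM within {cond}", cond, None, t, df, p, "two-sided"))
    diff = wide.pivot_table(index="subject", columns="condition", values="rp_minus_rm")
    for a, b in pairs:
        if a not in diff.columns or b not in diff.columns:
            continue
        pairdata = diff[[a, b]].dropna()
        if len(pairdata) < 2:
            rows.append((f"RP-RM {a} vs {b}", a, b, np.nan, len(pairdata) - 1, np.nan, "two-sided"))
            continue
        t, df, p = paired_t(pairdata[a], pairdata[b], "two-sided")
        rows.append((f"RP-RM {a} vs {b}", a, b, t, df, p, "two-sided"))
    return pd.DataFrame(
        rows, columns=["comparison", "cond_a", "cond_b", "t", "df", "p", "tail"]
    )
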