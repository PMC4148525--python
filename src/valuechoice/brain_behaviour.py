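"""Across-subject GLM linking ROI value coding to choice performance.

For each timing condition, choice performance (% choices of the higher
objective-EV option) is regressed on the HRF-fitted chosen- and
unchosen-value amplitudes of two ROIs, z-scored across subjects.  Contrasts
test the chosen-value effect in each region and the direct region difference
of the chosen-value effect; one-tailed p-values in a stated direction are
reported alongside two-tailed ones.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .synthetic import zscore


def build_brain_behaviour_design(
    amplitudes: pd.DataFrame,
    accuracy: pd.DataFrame,
    condition: str,
    rois: tuple[str, str],
) -> tuple[pd.DataFrame, pd.Series]:
    """One-row-per-subject design (intercept + chosen/unchosen per ROI) and response.

    ``amplitudes``: tidy (subject, roi, condition, regressor, amplitude) with
    the ``chosen_value`` / ``unchosen_value`` regressors.  ``accuracy``: tidy
    (subject, condition, accuracy_pct).
    """
    sub = amplitudes.loc[
        (amplitudes["condition"] == condition)
        & amplitudes["regressor"].isin(["chosen_value", "unchosen_value"])
        & amplitudes["roi"].isin(rois)
    ]
    wide = sub.pivot_table(
        index="subject", columns=["regressor", "roi"], values="amplitude"
    )
    wide.columns = [f"{reg.split('_')[0]}_{roi}" for reg, roi in wide.columns]
    acc = accuracy.loc[accuracy["condition"] == condition].set_index("subject")[
        "accuracy_pct"
    ]
    common = wide.index.intersection(acc.index)
    wide = wide.loc[common]
    X = pd.DataFrame(
        {c: zscore(wide[c].to_numpy()) for c in sorted(wide.columns)}, index=common
    )
    X.insert(0, "intercept", 1.0)
    order = ["intercept"] + [
        f"{reg}_{roi}" for roi in rois for reg in ("chosen", "unchosen")
    ]
    return X[order], acc.loc[common]


def fit_brain_behaviour(
    design: pd.DataFrame,
    response: pd.Series,
    contrasts: dict[str, np.ndarray] | None = None,
    tails: dict[str, str] | None = None,
) -> pd.DataFrame:
    """OLS of choice performance on ROI value amplitudes, with contrast t-tests.

    Default contrasts: the chosen-value effect of each ROI and their direct
    difference (second ROI minus first, in design column order).  Returns a
    tidy table with estimate, t, df, two- and one-tailed p.  A zero-variance
    response is reported as degenerate (t = 0, p = 1).
    """
    X = design.to_numpy(float)
    y = np.asarray(response, dtype=float)
    n, k = X.shape
    if n < k + 3:
        raise ValueError(f"need at least {k + 3} subjects for {k} regressors")
    if np.linalg.matrix_rank(X) < k:
        raise ValueError(f"rank-deficient design; columns: {list(design.columns)}")

    if contrasts is None:
        chosen_cols = [c for c in design.columns if c.startswith("chosen_")]
        if len(chosen_cols) != 2:
            raise ValueError("default contrasts need exactly two chosen_* columns")
        contrasts = {}
        for c in chosen_cols:
            vec = np.zeros(k)
            vec[design.columns.get_loc(c)] = 1.0
            contrasts[c] = vec
        diff = np.zeros(k)
        diff[design.columns.get_loc(chosen_cols[1])] = 1.0
        diff[design.columns.get_loc(chosen_cols[0])] = -1.0
        contrasts[f"{chosen_cols[1]} - {chosen_cols[0]}"] = diff
    tails = tails or {}

    degenerate = np.std(y) == 0
    res = sm.OLS(y, X).fit()
    df_resid = int(res.df_resid)
    rows = []
    for name, vec in contrasts.items():
        vec = np.asarray(vec, dtype=float)
        est = float(vec @ res.params)
        if degenerate:
            rows.append((name, 0.0, 0.0, df_resid, 1.0, 1.0, "degenerate"))
            continue
        tt = res.t_test(vec)
        t = float(np.squeeze(tt.tvalue))
        p_two = float(np.squeeze(tt.pvalue))
        tail = tails.get(name, "greater")
        if tail == "greater":
            p_one = float(stats.t.sf(t, df_resid))
        elif tail == "less":
            p_one = float(stats.t.cdf(t, df_resid))
        else:
            p_one = p_two
        rows.append((name, est, t, df_resid, p_two, p_one, tail))
    return pd.DataFrame(
        rows, columns=["contrast", "estimate", "t", "df", "p_two_tailed", "p_one_tailed", "tail"]
    )
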