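"""Trial-epoched ROI BOLD analysis.

The continuous ROI signal (sampled at the repetition time, TR = 3 s by
default) is cut into 16-s trial epochs locked to stimulus onset and resampled
to 300-ms resolution by cubic-spline interpolation of the whole series.  At
each of the 54 epoch timepoints, a trial-level ordinary-least-squares GLM is
fitted across trials, yielding an effect-size timecourse per regressor.  Two
regressor sets are available: value difference + value sum, or their
constituent terms chosen value + unchosen value; both include outcome value,
response side, reaction time and an intercept.  Each effect timecourse is
summarized by the least-squares amplitude of a canonical HRF, giving one
parameter estimate per regressor, ROI, condition and subject, which feed the
group t-tests and the area-by-condition repeated-measures ANOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import CubicSpline

from .hrf import HrfParams, canonical_hrf
from .prospect import ProspectParams, subjective_ev

GLM_VARIANTS = ("sum_diff", "chosen_unchosen")

#: mean event times within an epoch, per condition (seconds after stimulus onset)
CANONICAL_EVENT_TIMES = {
    "response_s": {"short": 0.77, "middle": 1.41, "long": 3.4},
    "outcome_s": {"short": 5.56, "middle": 6.21, "long": 8.24},
}


@dataclass
class RoiTimeseries:
    """One ROI's BOLD series sampled at the repetition time."""

    roi_label: str
    values: np.ndarray
    tr_s: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be a 1-D vector")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("timeseries contains non-finite values")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be > 0")

    @property
    def n_volumes(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_volumes) * self.tr_s


@dataclass
class EpochedTrials:
    """Trials x timepoints matrix on the epoch grid."""

    data: np.ndarray  # (n_trials, n_timepoints)
    times: np.ndarray  # epoch grid, seconds from stimulus onset
    trial_index: np.ndarray  # dataset index of each kept trial
    conditions: np.ndarray
    n_dropped: int = 0

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def subset(self, mask: np.ndarray) -> "EpochedTrials":
        return EpochedTrials(
            data=self.data[mask],
            times=self.times,
            trial_index=self.trial_index[mask],
            conditions=self.conditions[mask],
            n_dropped=self.n_dropped,
        )


def epoch_timeseries(
    ts: RoiTimeseries,
    onsets,
    window_s: float = 16.0,
    dt_s: float = 0.3,
    conditions=None,
) -> EpochedTrials:
    """Cut a series into onset-locked epochs on a half-open [0, window_s) grid.

    A single cubic spline is fitted through the whole series and evaluated on
    each trial's epoch grid, so samples that coincide with acquisition times
    are reproduced exactly.  Trials whose window overruns the series are
    dropped (their count is recorded).
    """
    if isinstance(onsets, pd.DataFrame):
        conditions = onsets["condition"].to_numpy() if conditions is None else conditions
        index = onsets.index.to_numpy()
        onsets = onsets["stimulus_onset_s"].to_numpy(float)
    else:
        onsets = np.asarray(onsets, dtype=float)
        index = np.arange(onsets.size)
    if conditions is None:
        conditions = np.full(onsets.size, "all")
    conditions = np.asarray(conditions)

    n_points = int(np.ceil(window_s / dt_s - 1e-9))  # half-open [0, window_s)
    grid = np.arange(n_points) * dt_s
    t_max = (ts.n_volumes - 1) * ts.tr_s
    keep = (onsets >= 0) & (onsets + grid[-1] <= t_max)
    n_dropped = int((~keep).sum())
    if not keep.any():
        raise ValueError("all trials dropped: epoch windows overrun the series")
    spline = CubicSpline(ts.times, ts.values)
    data = spline(onsets[keep][:, None] + grid[None, :])
    return EpochedTrials(
        data=data,
        times=grid,
        trial_index=index[keep],
        conditions=conditions[keep],
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# Trial-level design matrices
# ---------------------------------------------------------------------------

def with_subjective_values(dataset: pd.DataFrame, params: ProspectParams) -> pd.DataFrame:
    """Replace chosen/unchosen value columns with sEVs under ``params``.

    Used to build designs from a subject's fitted parameters rather than the
    generating ground truth.  Missed trials keep NaN values.
    """
    ds = dataset.copy()
    sev_l = subjective_ev(
        ds["magnitude_left"].to_numpy(), ds["probability_left"].to_numpy(), params
    )
    sev_r = subjective_ev(
        ds["magnitude_right"].to_numpy(), ds["probability_right"].to_numpy(), params
    )
    left = ds["choice"].to_numpy() == "left"
    missed = ~ds["choice"].isin(["left", "right"]).to_numpy()
    chosen = np.where(left, sev_l, sev_r)
    unchosen = np.where(left, sev_r, sev_l)
    chosen[missed] = np.nan
    unchosen[missed] = np.nan
    ds["chosen_value"] = chosen
    ds["unchosen_value"] = unchosen
    return ds


def build_trial_design(
    dataset: pd.DataFrame,
    variant: str = "chosen_unchosen",
    standardize: bool = True,
) -> pd.DataFrame:
    """Trial-level design matrix for the epoched GLMs.

    Rows are non-missed trials of ``dataset`` (callers normally pass one
    condition at a time).  Parametric columns are z-scored across the given
    trials when ``standardize`` is set; constant columns are dropped with a
    warning; rank deficiency raises, naming the offending columns.
    """
    if variant not in GLM_VARIANTS:
        raise ValueError(f"unknown GLM variant {variant!r}")
    d = dataset.loc[dataset["choice"].isin(["left", "right"])]
    if d.empty:
        raise ValueError("no non-missed trials to build a design from")
    chosen = d["chosen_value"].to_numpy(float)
    unchosen = d["unchosen_value"].to_numpy(float)
    left = d["choice"].to_numpy() == "left"
    outcome_chosen = np.where(
        left, d["outcome_left"].to_numpy(bool), d["outcome_right"].to_numpy(bool)
    ).astype(float)

    cols: dict[str, np.ndarray] = {}
    if variant == "sum_diff":
        cols["value_difference"] = chosen - unchosen
        cols["value_sum"] = chosen + unchosen
    else:
        cols["chosen_value"] = chosen
        cols["unchosen_value"] = unchosen
    cols["outcome_value"] = outcome_chosen
    cols["response_side"] = np.where(left, 1.0, -1.0)
    cols["rt_covariate"] = d["reaction_time_s"].to_numpy(float)

    X = {}
    for name, col in cols.items():
        sd = col.std()
        if sd == 0:
            warnings.warn(f"design column {name!r} is constant; dropped", stacklevel=2)
            continue
        X[name] = (col - col.mean()) / sd if standardize else col
    X["intercept"] = np.ones(len(d))
    design = pd.DataFrame(X, index=d.index)
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {design.shape[1]}); "
            f"columns: {list(design.columns)}"
        )
    return design


def fit_timepoint_glm(epochs: EpochedTrials, design: pd.DataFrame) -> pd.DataFrame:
    """OLS across trials at each epoch timepoint.

    Returns the effect-size timecourse: a (timepoints x regressors) frame
    indexed by epoch time.  Trials present in both the epochs and the design
    are used; a singular design fails loudly.
    """
    common = pd.Index(epochs.trial_index).intersection(design.index)
    if len(common) < design.shape[1] + 5:
        raise ValueError(
            f"too few trials ({len(common)}) for {design.shape[1]} regressors"
        )
    pos = {t: i for i, t in enumerate(epochs.trial_index)}
    rows = [pos[t] for t in common]
    Y = epochs.data[rows]
    X = design.loc[common].to_numpy()
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("singular trial design matrix")
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return pd.DataFrame(beta.T, index=epochs.times, columns=design.columns)


# ---------------------------------------------------------------------------
# HRF amplitude summary
# ---------------------------------------------------------------------------

def hrf_amplitude(
    effect_tc: np.ndarray,
    hrf: np.ndarray,
    dt_s: float = 0.3,
    lag_search_s: float | None = None,
) -> tuple[float, float, float]:
    """Least-squares scalar amplitude of an HRF in an effect timecourse.

    Returns ``(amplitude, residual_norm, lag_s)``.  Without lag search the
    amplitude is the projection ``<e, h> / <h, h>``; with it, the HRF is
    shifted over a +/- lag grid (zero-padded) and the shift with the smallest
    residual is kept.
    """
    e = np.asarray(effect_tc, dtype=float)
    h = np.asarray(hrf, dtype=float)
    if e.shape != h.shape:
        raise ValueError("effect timecourse and HRF grids do not match")
    if not np.any(h):
        raise ValueError("zero-norm HRF")
    lags = [0]
    if lag_search_s:
        max_shift = int(round(lag_search_s / dt_s))
        lags = range(-max_shift, max_shift + 1)
    best = None
    for lag in lags:
        hs = np.roll(h, lag)
        if lag > 0:
            hs[:lag] = 0.0
        elif lag < 0:
            hs[lag:] = 0.0
        denom = float(hs @ hs)
        if denom == 0:
            continue
        a = float(e @ hs) / denom
        resid = float(np.linalg.norm(e - a * hs))
        if best is None or resid < best[1]:
            best = (a, resid, lag * dt_s)
    return best


def analyze_subject(
    dataset: pd.DataFrame,
    timeseries: dict[str, RoiTimeseries],
    variant: str = "chosen_unchosen",
    hrf_params: HrfParams | None = None,
    window_s: float = 16.0,
    dt_s: float = 0.3,
    lag_search_s: float | None = None,
    standardize: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Epoch + per-timepoint GLM + HRF amplitude for every ROI and condition.

    Returns ``(timecourses, amplitudes)`` as tidy frames:
    timecourses have columns (roi, condition, regressor, time_s, beta);
    amplitudes have columns (roi, condition, regressor, amplitude,
    residual_norm, lag_s).
    """
    valid = dataset.loc[dataset["choice"].isin(["left", "right"])]
    h = canonical_hrf(dt_s, hrf_params, duration_s=window_s)
    tc_rows, amp_rows = [], []
    for roi, ts in timeseries.items():
        epochs = epoch_timeseries(ts, valid, window_s=window_s, dt_s=dt_s)
        for cond in sorted(valid["condition"].unique()):
            sub = epochs.subset(epochs.conditions == cond)
            design = build_trial_design(
                valid.loc[valid["condition"] == cond], variant, standardize=standardize
            )
            betas = fit_timepoint_glm(sub, design)
            for reg in betas.columns:
                tc = betas[reg].to_numpy()
                for t, b in zip(betas.index, tc):
                    tc_rows.append((roi, cond, reg, float(t), float(b)))
                a, resid, lag = hrf_amplitude(tc, h, dt_s=dt_s, lag_search_s=lag_search_s)
                amp_rows.append((roi, cond, reg, a, resid, lag))
    timecourses = pd.DataFrame(
        tc_rows, columns=["roi", "condition", "regressor", "time_s", "beta"]
    )
    amplitudes = pd.DataFrame(
        amp_rows,
        columns=["roi", "condition", "regressor", "amplitude", "residual_norm", "lag_s"],
    )
    return timecourses, amplitudes


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------

def _p_from_t(t: float, df: int, tail: str) -> float:
    if tail == "two-sided":
        return 2 * stats.t.sf(abs(t), df)
    if tail == "greater":
        return stats.t.sf(t, df)
    if tail == "less":
        return stats.t.cdf(t, df)
    raise ValueError(f"unknown tail {tail!r}")


def one_sample_t(values, popmean: float = 0.0, tail: str = "two-sided"):
    """One-sample t-test; returns (t, df, p) with the requested tail."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 observations")
    df = x.size - 1
    se = x.std(ddof=1) / np.sqrt(x.size)
    t = 0.0 if se == 0 else float((x.mean() - popmean) / se)
    return t, df, _p_from_t(t, df, tail)


def paired_t(a, b, tail: str = "two-sided"):
    """Paired t-test a vs b; returns (t, df, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    return one_sample_t(a - b, 0.0, tail)


def group_effect_tests(
    amplitudes: pd.DataFrame,
    tails=None,
) -> pd.DataFrame:
    """One-sample t-tests of HRF amplitudes against zero.

    ``amplitudes`` is the tidy per-subject table with columns
    (subject, roi, condition, regressor, amplitude).  ``tails`` maps
    (roi, condition, regressor) to a tail; unlisted cells are two-sided.
    """
    tails = tails or {}
    rows = []
    for (roi, cond, reg), grp in amplitudes.groupby(
        ["roi", "condition", "regressor"], sort=True
    ):
        tail = tails.get((roi, cond, reg), "two-sided")
        t, df, p = one_sample_t(grp["amplitude"].to_numpy(), 0.0, tail)
        rows.append((roi, cond, reg, grp.shape[0], t, df, p, tail))
    return pd.DataFrame(
        rows, columns=["roi", "condition", "regressor", "n", "t", "df", "p", "tail"]
    )


def condition_contrasts(
    amplitudes: pd.DataFrame,
    regressor: str = "unchosen_value",
    pairs=(("short", "middle"), ("short", "long"), ("middle", "long")),
    tails=None,
) -> pd.DataFrame:
    """Paired between-condition contrasts of one regressor's amplitude per ROI."""
    tails = tails or {}
    sub = amplitudes.loc[amplitudes["regressor"] == regressor]
    wide = sub.pivot_table(
        index=["roi", "subject"], columns="condition", values="amplitude"
    )
    rows = []
    for roi, grp in wide.groupby(level="roi"):
        for a, b in pairs:
            pairdata = grp[[a, b]].dropna()
            tail = tails.get((roi, a, b), "two-sided")
            t, df, p = paired_t(pairdata[a], pairdata[b], tail)
            rows.append((roi, regressor, a, b, t, df, p, tail))
    return pd.DataFrame(
        rows, columns=["roi", "regressor", "cond_a", "cond_b", "t", "df", "p", "tail"]
    )


def rm_anova_area_by_condition(
    amplitudes: pd.DataFrame, regressor: str
) -> pd.DataFrame:
    """Two-way within-subject ANOVA with factors brain area and condition.

    Expects a complete areas x conditions table per subject for the given
    regressor.  Uses the standard repeated-measures sum-of-squares
    decomposition where each effect is tested against its own
    subject-by-effect interaction, giving df (a-1, (a-1)(n-1)) for area,
    (c-1, (c-1)(n-1)) for condition, and (a-1)(c-1), (a-1)(c-1)(n-1) for the
    interaction.
    """
    sub = amplitudes.loc[amplitudes["regressor"] == regressor]
    cube = sub.pivot_table(
        index="subject", columns=["roi", "condition"], values="amplitude"
    )
    if cube.isna().any().any():
        raise ValueError("missing cells: every subject needs every area x condition")
    areas = cube.columns.get_level_values(0).unique()
    conds = cube.columns.get_level_values(1).unique()
    n, a, c = cube.shape[0], areas.size, conds.size
    y = cube.to_numpy().reshape(n, a, c)

    grand = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_c = y.mean(axis=(0, 1))
    m_ac = y.mean(axis=0)
    m_sa = y.mean(axis=2)
    m_sc = y.mean(axis=1)

    ss_a = n * c * np.sum((m_a - grand) ** 2)
    ss_c = n * a * np.sum((m_c - grand) ** 2)
    ss_ac = n * np.sum((m_ac - m_a[:, None] - m_c[None, :] + grand) ** 2)
    ss_err_a = c * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_err_c = a * np.sum((m_sc - m_s[:, None] - m_c[None, :] + grand) ** 2)
    resid = (
        y
        - m_sa[:, :, None]
        - m_sc[:, None, :]
        - m_ac[None, :, :]
        + m_s[:, None, None]
        + m_a[None, :, None]
        + m_c[None, None, :]
        - grand
    )
    ss_err_ac = np.sum(resid**2)

    rows = []
    for name, ss, df1, ss_err, df2 in [
        ("area", ss_a, a - 1, ss_err_a, (a - 1) * (n - 1)),
        ("condition", ss_c, c - 1, ss_err_c, (c - 1) * (n - 1)),
        ("area:condition", ss_ac, (a - 1) * (c - 1), ss_err_ac, (a - 1) * (c - 1) * (n - 1)),
    ]:
        ms, ms_err = ss / df1, ss_err / df2
        f = 0.0 if ms_err == 0 and ms == 0 else ms / ms_err
        p = float(stats.f.sf(f, df1, df2))
        rows.append((name, ss, df1, ss_err, df2, f, p))
    return pd.DataFrame(
        rows, columns=["effect", "ss", "df1", "ss_error", "df2", "F", "p"]
    )
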