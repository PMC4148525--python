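"""Synthetic task schedules, simulated choosers and ROI BOLD forward model.

Emulates a timed two-attribute gambling task: on every trial two options are
shown, each defined by a reward magnitude and an independent reward
probability, under one of three timing conditions (``short``: respond within
1 s; ``middle``: free response; ``long``: 3 s forced viewing then respond
within 1 s).  Conditions alternate in blocks of 10 trials, 70 trials per
condition by default.  A subset of "no brainer" trials has one option
dominating on both attributes.

The schedule generator targets a low correlation between the values of the
to-be-chosen and to-be-unchosen options (assessed with a greedy chooser that
always takes the higher objective expected value), so that downstream
regressions can separate chosen- and unchosen-value variance.

The BOLD forward model places a per-trial neural amplitude — a linear
combination of the standardized chosen and unchosen subjective values — as a
brief event at stimulus onset, convolves with the canonical double-gamma HRF
on a 0.1-s grid, samples at the repetition time and adds AR(1) Gaussian
noise.  Ground-truth coding regimes: ``sum_coder`` (equal positive weights on
chosen and unchosen value), ``diff_coder`` (opposite weights) and ``null``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, signal, stats

from .hrf import HrfParams, canonical_hrf
from .prospect import ProspectParams, _inverse_noise, subjective_ev

CONDITIONS = ("short", "middle", "long")
DISPLAY_MODES = ("magnitude_as_bar", "probability_as_bar")
CODING_REGIMES = ("sum_coder", "diff_coder", "null")

#: nominal stimulus-to-outcome response allowance used when planning onsets
_NOMINAL_RESPONSE_S = {"short": 1.0, "middle": 1.5, "long": 4.0}
_OUTCOME_DISPLAY_S = 1.0
_PRECUE_S = 1.0

SCHEDULE_COLUMNS = [
    "trial_index", "condition", "block_index",
    "magnitude_left", "magnitude_right",
    "probability_left", "probability_right",
    "is_nobrainer", "display_mode",
    "stimulus_onset_s", "planned_outcome_delay_s", "planned_iti_s",
]


def zscore(x: np.ndarray) -> np.ndarray:
    """Population z-score; raises on zero variance."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot z-score a constant vector")
    return (x - x.mean()) / sd


# ---------------------------------------------------------------------------
# Schedule generation
# ---------------------------------------------------------------------------

def _percent_bounds(ev: float) -> tuple[int, int]:
    """Whole-percent probabilities compatible with a magnitude in [0.1, 1]."""
    lo = max(10, int(np.ceil(100 * ev)))
    hi = min(90, int(np.floor(1000 * ev)))
    return lo, hi


def _draw_ev_pair(rng, ev_lo_range, ev_hi_range, hard_fraction: float):
    """Draw the higher/lower objective EV of one trial.

    "Easy" trials draw the two EVs independently (so the greedy chooser's
    chosen and unchosen values are uncorrelated by construction); "hard"
    trials place them within a small multiplicative gap, supplying the
    difficult low-value-difference choices that identify the decision-noise
    parameter.
    """
    if rng.random() < hard_fraction:
        # narrow band: high within-pair similarity, little variance, so these
        # trials barely contribute to the chosen/unchosen covariance
        ev_lo = rng.uniform(0.2, 0.4)
        ev_hi = ev_lo * rng.uniform(1.05, 1.3)
    else:
        for _ in range(100):
            ev_lo = rng.uniform(*ev_lo_range)
            ev_hi = rng.uniform(*ev_hi_range)
            if ev_hi > 1.05 * ev_lo:
                break
    return ev_hi, ev_lo


def _draw_trial(rng, ev_lo_range, ev_hi_range, nobrainer: bool, hard_fraction=0.3):
    """Draw one trial's (magnitude, probability) pair per option.

    Attributes are solved from the EV pair with probabilities on a
    whole-percent grid.  Non-nobrainer trials are anti-dominant (one option
    better on magnitude, the other on probability) with the orientation
    randomized so probability does not systematically track value; nobrainer
    trials let the higher-EV option dominate on both attributes.
    """
    for _ in range(200):
        ev_hi, ev_lo = _draw_ev_pair(rng, ev_lo_range, ev_hi_range, hard_fraction)
        lo_min, lo_max = _percent_bounds(ev_lo)
        hi_min, hi_max = _percent_bounds(ev_hi)
        if lo_min > lo_max or hi_min > hi_max:
            continue
        ratio = ev_hi / ev_lo
        # retry the probability assignment before abandoning the EV pair, so
        # grid feasibility does not select on (and thereby correlate) the EVs;
        # the anti-dominance orientation is drawn once and kept through the
        # retries so both orientations occur at comparable rates
        flip = rng.random() < 0.5
        for attempt in range(20):
            p_lo = int(rng.integers(lo_min, lo_max + 1))
            if nobrainer:
                # dominance: p_hi > p_lo and m_hi > m_lo (p_hi < p_lo * ratio)
                ranges = [(max(hi_min, p_lo + 1), min(hi_max, int(np.ceil(p_lo * ratio)) - 1))]
            else:
                ranges = [
                    # higher-EV option: larger magnitude, smaller probability
                    (hi_min, min(hi_max, p_lo - 1)),
                    # higher-EV option: larger probability, smaller magnitude
                    (max(hi_min, int(np.floor(p_lo * ratio)) + 1), hi_max),
                ]
                if flip:
                    ranges.reverse()
                if attempt < 12:  # stick to the drawn orientation first
                    ranges = ranges[:1]
            for a, b in ranges:
                if a <= b:
                    p_hi = int(rng.integers(a, b + 1))
                    m_hi, m_lo = 100 * ev_hi / p_hi, 100 * ev_lo / p_lo
                    return (m_hi, p_hi / 100.0, ev_hi), (m_lo, p_lo / 100.0, ev_lo)
    raise RuntimeError("could not draw a feasible trial; check EV ranges")


def generate_schedule(
    n_per_condition: int = 70,
    nobrainer_fraction: float = 0.1,
    corr_target: float = 0.2,
    display_mode: str = "magnitude_as_bar",
    seed: int = 0,
    block_length: int = 10,
    iti_range: tuple[float, float] = (3.5, 6.0),
    outcome_delay_range: tuple[float, float] = (3.5, 6.0),
    ev_lo_range: tuple[float, float] = (0.05, 0.45),
    ev_hi_range: tuple[float, float] = (0.15, 0.85),
    max_candidates: int = 10_000,
) -> pd.DataFrame:
    """Generate a trial schedule whose greedy chosen/unchosen value correlation
    satisfies ``|r| <= corr_target``.

    Candidate schedules are drawn and rejected until the correlation bound is
    met; fails with a clear message if ``max_candidates`` is exhausted.
    Deterministic given ``seed``.
    """
    if n_per_condition % block_length != 0:
        raise ValueError("n_per_condition must be a multiple of the block length")
    if not 0 <= nobrainer_fraction < 0.5:
        raise ValueError("nobrainer_fraction must lie in [0, 0.5)")
    if display_mode not in DISPLAY_MODES:
        raise ValueError(f"unknown display_mode {display_mode!r}")
    rng = np.random.default_rng(seed)
    n_blocks_per_cond = n_per_condition // block_length
    conditions = [CONDITIONS[b % 3] for b in range(3 * n_blocks_per_cond)]
    n_trials = 3 * n_per_condition

    for _ in range(max_candidates):
        n_nb = int(round(nobrainer_fraction * n_trials))
        nb_flags = np.zeros(n_trials, dtype=bool)
        if n_nb:
            nb_flags[rng.choice(n_trials, size=n_nb, replace=False)] = True
        rows, chosen_ev, unchosen_ev = [], [], []
        for i in range(n_trials):
            (m_hi, p_hi, ev_hi), (m_lo, p_lo, ev_lo) = _draw_trial(
                rng, ev_lo_range, ev_hi_range, bool(nb_flags[i])
            )
            if rng.random() < 0.5:
                left, right = (m_hi, p_hi), (m_lo, p_lo)
            else:
                left, right = (m_lo, p_lo), (m_hi, p_hi)
            rows.append((left[0], left[1], right[0], right[1]))
            chosen_ev.append(ev_hi)
            unchosen_ev.append(ev_lo)
        r = float(np.corrcoef(chosen_ev, unchosen_ev)[0, 1])
        if abs(r) <= corr_target:
            break
    else:
        raise RuntimeError(
            f"rejection sampling failed: no schedule with |greedy chosen/unchosen "
            f"corr| <= {corr_target} within {max_candidates} candidates"
        )

    mags_probs = np.array(rows)
    delays = rng.uniform(*outcome_delay_range, size=n_trials)
    itis = rng.uniform(*iti_range, size=n_trials)
    onsets = np.empty(n_trials)
    block_index = np.repeat(np.arange(len(conditions)), block_length)
    cond_per_trial = np.repeat(conditions, block_length)
    t = _PRECUE_S
    for i in range(n_trials):
        onsets[i] = t
        t += (_NOMINAL_RESPONSE_S[cond_per_trial[i]] + delays[i]
              + _OUTCOME_DISPLAY_S + itis[i])
        if i + 1 < n_trials and block_index[i + 1] != block_index[i]:
            t += _PRECUE_S

    df = pd.DataFrame(
        {
            "trial_index": np.arange(n_trials),
            "condition": cond_per_trial,
            "block_index": block_index,
            "magnitude_left": mags_probs[:, 0],
            "magnitude_right": mags_probs[:, 2],
            "probability_left": mags_probs[:, 1],
            "probability_right": mags_probs[:, 3],
            "is_nobrainer": nb_flags,
            "display_mode": display_mode,
            "stimulus_onset_s": onsets,
            "planned_outcome_delay_s": delays,
            "planned_iti_s": itis,
        }
    )
    df.attrs["greedy_value_correlation"] = r
    df.attrs["seed"] = seed
    return df


def greedy_value_correlation(schedule: pd.DataFrame) -> float:
    """Chosen/unchosen objective-EV correlation under an argmax-EV chooser."""
    ev_l = schedule["magnitude_left"] * schedule["probability_left"]
    ev_r = schedule["magnitude_right"] * schedule["probability_right"]
    hi = np.maximum(ev_l, ev_r)
    lo = np.minimum(ev_l, ev_r)
    return float(np.corrcoef(hi, lo)[0, 1])


# ---------------------------------------------------------------------------
# Reaction-time model and agents
# ---------------------------------------------------------------------------

def _truncated_lognormal_mu(target_median: float, sigma: float, cap: float | None) -> float:
    """Location parameter so a (possibly right-truncated) log-normal has the
    requested median."""
    if cap is None:
        return float(np.log(target_median))
    if target_median >= cap:
        raise ValueError("target median must be below the truncation cap")

    def median_err(mu):
        q = stats.norm.cdf((np.log(cap) - mu) / sigma)
        return np.exp(mu + sigma * stats.norm.ppf(0.5 * q)) - target_median

    lo, hi = np.log(target_median * 0.5), np.log(cap)
    return float(optimize.brentq(median_err, lo, hi))


@dataclass
class RtConfig:
    """Condition-specific log-normal reaction-time model.

    Default location parameters are calibrated so that condition medians match
    793, 1180 and 3366 ms.  ``long`` reaction times are the 3-s forced viewing
    period plus a response latency truncated at the 1-s response window; the
    ``short`` condition is likewise truncated at its 1-s window.
    """

    median_s: Mapping[str, float] = field(
        default_factory=lambda: {"short": 0.793, "middle": 1.180, "long": 3.366}
    )
    sigma: Mapping[str, float] = field(
        default_factory=lambda: {"short": 0.12, "middle": 0.25, "long": 0.30}
    )
    viewing_period_s: float = 3.0
    response_window_s: float = 1.0
    missed_prob: float = 0.0

    def sample(self, condition: str, n: int, rng: np.random.Generator) -> np.ndarray:
        if condition not in self.median_s:
            raise ValueError(f"rt model has no parameters for condition {condition!r}")
        sigma = self.sigma[condition]
        if condition == "middle":
            mu = np.log(self.median_s[condition])
            return rng.lognormal(mu, sigma, size=n)
        # truncated latency for the deadline conditions
        offset = self.viewing_period_s if condition == "long" else 0.0
        target = self.median_s[condition] - offset
        cap = self.response_window_s
        mu = _truncated_lognormal_mu(target, sigma, cap)
        q = stats.norm.cdf((np.log(cap) - mu) / sigma)
        u = rng.uniform(0.0, q, size=n)
        return offset + np.exp(mu + sigma * stats.norm.ppf(u))


def _finish_dataset(schedule, choose_left, rts, missed, sev_l, sev_r, rng):
    """Assemble choices, outcomes and chosen/unchosen values onto a schedule copy."""
    ds = schedule.copy()
    choice = np.where(choose_left, "left", "right").astype(object)
    choice[missed] = "missed"
    ds["choice"] = choice
    rts = rts.astype(float).copy()
    rts[missed] = np.nan
    ds["reaction_time_s"] = rts
    ds["outcome_left"] = rng.random(len(ds)) < ds["probability_left"].to_numpy()
    ds["outcome_right"] = rng.random(len(ds)) < ds["probability_right"].to_numpy()
    chosen = np.where(choose_left, sev_l, sev_r)
    unchosen = np.where(choose_left, sev_r, sev_l)
    chosen[missed] = np.nan
    unchosen[missed] = np.nan
    ds["chosen_value"] = chosen
    ds["unchosen_value"] = unchosen
    return ds


def simulate_agent(
    schedule: pd.DataFrame,
    params: ProspectParams,
    rt_model: RtConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a softmax chooser with the given prospect-theory parameters.

    Choices are sampled from the softmax over subjective EVs; reaction times
    from the condition-specific log-normal model; outcomes independently per
    option.  The returned dataset records each trial's chosen and unchosen
    subjective value under ``params``.
    """
    rt_model = rt_model or RtConfig()
    for cond in schedule["condition"].unique():
        if cond not in rt_model.median_s:
            raise ValueError(f"rt model has no parameters for condition {cond!r}")
    rng = np.random.default_rng(seed)
    sev_l = subjective_ev(
        schedule["magnitude_left"].to_numpy(), schedule["probability_left"].to_numpy(), params
    )
    sev_r = subjective_ev(
        schedule["magnitude_right"].to_numpy(), schedule["probability_right"].to_numpy(), params
    )
    beta = _inverse_noise(params.tau, params.softmax_form)
    p_left = 1.0 / (1.0 + np.exp(-np.clip((sev_l - sev_r) * beta, -700, 700)))
    choose_left = rng.random(len(schedule)) < p_left

    rts = np.empty(len(schedule))
    for cond in schedule["condition"].unique():
        idx = schedule["condition"] == cond
        rts[idx.to_numpy()] = rt_model.sample(cond, int(idx.sum()), rng)
    deadline = schedule["condition"].isin(["short", "long"]).to_numpy()
    missed = deadline & (rng.random(len(schedule)) < rt_model.missed_prob)
    return _finish_dataset(schedule, choose_left, rts, missed, sev_l, sev_r, rng)


def simulate_weighted_agent(
    schedule: pd.DataFrame,
    weight_probability: float,
    weight_magnitude: float,
    weight_probability_rt: float = 0.0,
    weight_magnitude_rt: float = 0.0,
    bar_speed_advantage: float = 0.0,
    rt_model: RtConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a logistic chooser with explicit attribute decision weights.

    The log-odds of choosing left is a weighted sum of the left-minus-right
    probability and magnitude differences; the ``*_rt`` terms let a weight
    grow (or shrink) with the trial's standardized reaction time, and
    ``bar_speed_advantage`` adds extra weight to the bar-rendered attribute on
    fast trials (a perceptual-speed asymmetry, off by default).  Chosen and
    unchosen values are recorded as objective EVs.
    """
    rt_model = rt_model or RtConfig()
    rng = np.random.default_rng(seed)
    dp = (schedule["probability_left"] - schedule["probability_right"]).to_numpy()
    dm = (schedule["magnitude_left"] - schedule["magnitude_right"]).to_numpy()
    rts = np.empty(len(schedule))
    z_rt = np.empty(len(schedule))
    for cond in schedule["condition"].unique():
        idx = (schedule["condition"] == cond).to_numpy()
        rts[idx] = rt_model.sample(cond, int(idx.sum()), rng)
        z_rt[idx] = zscore(rts[idx])
    w_p = weight_probability + weight_probability_rt * z_rt
    w_m = weight_magnitude + weight_magnitude_rt * z_rt
    if bar_speed_advantage:
        bar_is_mag = (schedule["display_mode"] == "magnitude_as_bar").to_numpy()
        boost = bar_speed_advantage * (-z_rt)
        w_m = w_m + np.where(bar_is_mag, boost, 0.0)
        w_p = w_p + np.where(bar_is_mag, 0.0, boost)
    logits = w_p * dp + w_m * dm
    choose_left = rng.random(len(schedule)) < 1.0 / (1.0 + np.exp(-logits))
    missed = np.zeros(len(schedule), dtype=bool)
    ev_l = (schedule["magnitude_left"] * schedule["probability_left"]).to_numpy()
    ev_r = (schedule["magnitude_right"] * schedule["probability_right"]).to_numpy()
    return _finish_dataset(schedule, choose_left, rts, missed, ev_l, ev_r, rng)


def greedy_agent_dataset(schedule: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Deterministic argmax-objective-EV chooser (reference/test agent)."""
    params = ProspectParams(1.0, 1.0, 1e-6)
    rng = np.random.default_rng(seed)
    ev_l = (schedule["magnitude_left"] * schedule["probability_left"]).to_numpy()
    ev_r = (schedule["magnitude_right"] * schedule["probability_right"]).to_numpy()
    choose_left = ev_l >= ev_r
    rts = np.full(len(schedule), 1.0)
    missed = np.zeros(len(schedule), dtype=bool)
    ds = _finish_dataset(schedule, choose_left, rts, missed, ev_l, ev_r, rng)
    ds.attrs["params"] = params
    return ds


# ---------------------------------------------------------------------------
# BOLD forward model
# ---------------------------------------------------------------------------

@dataclass
class BoldGroundTruth:
    """Planted value-coding regime of one ROI.

    ``coding_regime`` is either a single regime name or a mapping from
    condition to regime.  ``sum_coder`` places weight ``(+w, +w)`` on the
    standardized (chosen, unchosen) values, ``diff_coder`` ``(+w, -w)``, and
    ``null`` ``(0, 0)``.
    """

    roi_label: str
    coding_regime: str | Mapping[str, str] = "null"
    weight: float = 0.5
    intercept: float = 0.0
    noise_sd: float = 1.0
    ar1_coefficient: float = 0.3
    tr_s: float = 3.0

    def __post_init__(self) -> None:
        regimes = (
            [self.coding_regime]
            if isinstance(self.coding_regime, str)
            else list(self.coding_regime.values())
        )
        for reg in regimes:
            if reg not in CODING_REGIMES:
                raise ValueError(f"unknown coding regime {reg!r}")
        if not 0 <= self.ar1_coefficient < 1:
            raise ValueError("ar1_coefficient must lie in [0, 1)")
        if self.noise_sd < 0 or self.tr_s <= 0:
            raise ValueError("noise_sd must be >= 0 and tr_s > 0")

    def regime_for(self, condition: str) -> str:
        if isinstance(self.coding_regime, str):
            return self.coding_regime
        return self.coding_regime[condition]

    def weights_for(self, condition: str) -> tuple[float, float]:
        """(weight_chosen, weight_unchosen) for a condition."""
        reg = self.regime_for(condition)
        if reg == "sum_coder":
            return self.weight, self.weight
        if reg == "diff_coder":
            return self.weight, -self.weight
        return 0.0, 0.0

    @property
    def weight_chosen(self) -> float:
        return self.weights_for(next(iter(
            [self.coding_regime] if isinstance(self.coding_regime, str)
            else self.coding_regime
        )))[0]

    @property
    def weight_unchosen(self) -> float:
        return self.weights_for(next(iter(
            [self.coding_regime] if isinstance(self.coding_regime, str)
            else self.coding_regime
        )))[1]


def trial_amplitudes(dataset: pd.DataFrame, truth: BoldGroundTruth) -> pd.Series:
    """Planted neural amplitude per non-missed trial.

    chosen/unchosen values are z-scored within condition (matching the
    standardization used by the epoched GLMs) before weighting.
    """
    valid = dataset["choice"].isin(["left", "right"])
    d = dataset.loc[valid]
    amp = pd.Series(truth.intercept, index=d.index, dtype=float)
    for cond, sub in d.groupby("condition", observed=True):
        w_c, w_u = truth.weights_for(cond)
        if w_c == 0 and w_u == 0:
            continue
        zc = zscore(sub["chosen_value"].to_numpy())
        zu = zscore(sub["unchosen_value"].to_numpy())
        amp.loc[sub.index] += w_c * zc + w_u * zu
    return amp


def simulate_bold(
    dataset: pd.DataFrame,
    truth: BoldGroundTruth,
    hrf: HrfParams | None = None,
    seed: int = 0,
    fine_dt_s: float = 0.1,
    epoch_window_s: float = 16.0,
):
    """Generate one ROI's BOLD series from a choice dataset.

    Per-trial amplitudes are placed as single-sample events at stimulus onset
    on a ``fine_dt_s`` grid, convolved with the canonical HRF
    (support ``hrf.duration_s``), sampled at ``truth.tr_s`` and summed with
    stationary AR(1) Gaussian noise of standard deviation ``truth.noise_sd``.
    The series is long enough that every trial's ``epoch_window_s`` epoch is
    covered.
    """
    from .roi import RoiTimeseries

    hrf = hrf or HrfParams()
    amp = trial_amplitudes(dataset, truth)
    if amp.empty:
        raise ValueError("dataset has no non-missed trials")
    onsets = dataset.loc[amp.index, "stimulus_onset_s"].to_numpy(float)
    t_end = onsets.max() + max(epoch_window_s, hrf.duration_s) + truth.tr_s
    n_fine = int(np.ceil(t_end / fine_dt_s)) + 1
    impulses = np.zeros(n_fine)
    np.add.at(impulses, np.round(onsets / fine_dt_s).astype(int), amp.to_numpy())
    kernel = canonical_hrf(fine_dt_s, hrf, duration_s=hrf.duration_s)
    fine = np.convolve(impulses, kernel)[:n_fine]

    n_vol = int(np.floor((n_fine - 1) * fine_dt_s / truth.tr_s)) + 1
    sample_idx = np.round(np.arange(n_vol) * truth.tr_s / fine_dt_s).astype(int)
    values = fine[sample_idx]
    if (n_vol - 1) * truth.tr_s < onsets.max() + epoch_window_s:
        raise ValueError("generated series too short to cover the last trial's epoch")

    if truth.noise_sd > 0:
        rng = np.random.default_rng(seed)
        eps = rng.standard_normal(n_vol)
        phi = truth.ar1_coefficient
        noise = signal.lfilter([1.0], [1.0, -phi], eps * np.sqrt(1 - phi**2))
        values = values + truth.noise_sd * noise
    return RoiTimeseries(roi_label=truth.roi_label, values=values, tr_s=truth.tr_s)
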