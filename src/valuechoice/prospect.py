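"""Prospect-theory choice model and grid-based Bayesian parameter estimation.

The model describes two-alternative choices between options that each carry a
reward magnitude ``r`` and an independent reward probability ``p``.  Objective
attributes are warped into subjective ones,

    r_S = r_O ** alpha
    p_S = p_O**gamma / (p_O**gamma + (1 - p_O)**gamma) ** (1 / gamma)

and combined multiplicatively into a subjective expected value
``sEV = r_S * p_S``.  Choices follow a softmax over the two options' sEVs
governed by a noise parameter ``tau``.  Two softmax parameterizations are
supported: ``temperature_divide`` (P proportional to ``exp(sEV / tau)``, so
larger tau means noisier choices) and ``inverse_temperature_multiply``
(P proportional to ``exp(sEV * tau)``).

Estimation is fully Bayesian on a three-dimensional grid over
``(alpha, gamma, tau)``, log-spaced on each axis, with a uniform prior over
grid cells.  The joint posterior is the normalized product of per-trial choice
probabilities; point estimates are the means of the marginal posteriors taken
on the linear parameter scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import logsumexp

SOFTMAX_FORMS = ("temperature_divide", "inverse_temperature_multiply")

#: Default grid bounds: wide enough to cover all behavioural regimes of
#: interest (strong over/under-weighting, near-deterministic through
#: near-random choice) while keeping 150 log-spaced points per axis dense.
DEFAULT_BOUNDS: Mapping[str, tuple[float, float]] = {
    "alpha": (0.05, 5.0),
    "gamma": (0.2, 5.0),
    "tau": (0.01, 100.0),
}


@dataclass(frozen=True)
class ProspectParams:
    """Parameter triple of the prospect-theory softmax model."""

    alpha: float
    gamma: float
    tau: float
    softmax_form: str = "temperature_divide"

    def __post_init__(self) -> None:
        for name in ("alpha", "gamma", "tau"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive and finite, got {v!r}")
        if self.softmax_form not in SOFTMAX_FORMS:
            raise ValueError(f"unknown softmax_form {self.softmax_form!r}")


def subjective_magnitude(r_obj, alpha):
    """Power-law utility of reward magnitude, ``r ** alpha``."""
    r = np.asarray(r_obj, dtype=float)
    if np.any(r <= 0):
        raise ValueError("objective magnitude must be > 0")
    out = r**alpha
    return float(out) if np.isscalar(r_obj) else out


def subjective_probability(p_obj, gamma):
    """One-parameter probability weighting function.

    ``p**g / (p**g + (1-p)**g)**(1/g)``; the endpoints 0 and 1 pass through
    exactly (no distortion of certainty or impossibility).
    """
    p = np.asarray(p_obj, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("objective probability must lie in [0, 1]")
    pg = p**gamma
    qg = (1.0 - p) ** gamma
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where((p == 0) | (p == 1), p, pg / (pg + qg) ** (1.0 / gamma))
    return float(out) if np.isscalar(p_obj) else out


def subjective_ev(r_obj, p_obj, params: ProspectParams):
    """Subjective expected value ``r_S * p_S`` under ``params``."""
    return subjective_magnitude(r_obj, params.alpha) * subjective_probability(
        p_obj, params.gamma
    )


def _inverse_noise(tau: float, form: str) -> float:
    """Map tau to the slope multiplying the sEV difference in the logit."""
    if form not in SOFTMAX_FORMS:
        raise ValueError(f"unknown softmax_form {form!r}")
    return 1.0 / tau if form == "temperature_divide" else tau


def choice_probability(sev_left, sev_right, tau, form="temperature_divide"):
    """Softmax probability of choosing left / right.

    Computed through the log-sigmoid of the scaled sEV difference, which is
    stable for arbitrarily large ``|sEV| / tau``.
    """
    if np.any(np.asarray(tau) <= 0):
        raise ValueError("tau must be > 0")
    beta = _inverse_noise(float(tau), form)
    d = (np.asarray(sev_left, dtype=float) - np.asarray(sev_right, dtype=float)) * beta
    p_left = np.exp(-np.logaddexp(0.0, -d))
    p_right = np.exp(-np.logaddexp(0.0, d))
    if np.isscalar(sev_left) and np.isscalar(sev_right):
        return float(p_left), float(p_right)
    return p_left, p_right


def _choice_arrays(dataset: pd.DataFrame):
    """Extract non-missed trials as plain arrays (mag/prob per side, sign of choice)."""
    valid = dataset["choice"].isin(["left", "right"])
    if not valid.any():
        raise ValueError("dataset contains no non-missed trials")
    d = dataset.loc[valid]
    sign = np.where(d["choice"].to_numpy() == "left", 1.0, -1.0)
    return (
        d["magnitude_left"].to_numpy(float),
        d["probability_left"].to_numpy(float),
        d["magnitude_right"].to_numpy(float),
        d["probability_right"].to_numpy(float),
        sign,
    )


def choice_log_likelihood(dataset: pd.DataFrame, params: ProspectParams) -> float:
    """Summed log probability of the observed choices; missed trials are skipped."""
    ml, pl, mr, pr, sign = _choice_arrays(dataset)
    sev_l = subjective_ev(ml, pl, params)
    sev_r = subjective_ev(mr, pr, params)
    beta = _inverse_noise(params.tau, params.softmax_form)
    # log sigmoid of the signed, scaled value difference
    return float(-np.logaddexp(0.0, -sign * (sev_l - sev_r) * beta).sum())


@dataclass(frozen=True)
class ParameterGrid:
    """Log-spaced axes over (alpha, gamma, tau)."""

    alpha: np.ndarray
    gamma: np.ndarray
    tau: np.ndarray

    def __post_init__(self) -> None:
        for name in ("alpha", "gamma", "tau"):
            ax = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, ax)
            if ax.ndim != 1 or ax.size < 2:
                raise ValueError(f"{name} axis must be 1-D with >= 2 points")
            if np.any(ax <= 0) or np.any(np.diff(ax) <= 0):
                raise ValueError(f"{name} axis must be strictly increasing and positive")
            ratios = ax[1:] / ax[:-1]
            if np.max(np.abs(ratios / ratios[0] - 1.0)) > 1e-10:
                raise ValueError(f"{name} axis is not log-spaced")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.alpha.size, self.gamma.size, self.tau.size)

    def axis(self, name: str) -> np.ndarray:
        return getattr(self, name)


def build_grid(
    bounds: Mapping[str, tuple[float, float]] | None = None, n_points: int = 150
) -> ParameterGrid:
    """Construct log-spaced axes inclusive of both bounds for each parameter."""
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    b = dict(DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    axes = {}
    for name in ("alpha", "gamma", "tau"):
        low, high = b[name]
        if not (0 < low < high):
            raise ValueError(f"invalid bounds for {name}: ({low}, {high})")
        axes[name] = np.geomspace(low, high, n_points)
    return ParameterGrid(**axes)


@dataclass(frozen=True)
class PosteriorGrid:
    """Joint posterior over the parameter grid with per-axis marginals."""

    grid: ParameterGrid
    log_joint: np.ndarray
    posterior_mass: np.ndarray
    softmax_form: str = "temperature_divide"

    @property
    def marginals(self) -> dict[str, np.ndarray]:
        m = self.posterior_mass
        return {
            "alpha": m.sum(axis=(1, 2)),
            "gamma": m.sum(axis=(0, 2)),
            "tau": m.sum(axis=(0, 1)),
        }

    @property
    def log_evidence(self) -> float:
        """Log marginal likelihood under the uniform-over-cells prior."""
        return float(logsumexp(self.log_joint) - np.log(self.log_joint.size))

    @property
    def map_params(self) -> ProspectParams:
        i, j, k = np.unravel_index(np.argmax(self.log_joint), self.log_joint.shape)
        return ProspectParams(
            self.grid.alpha[i], self.grid.gamma[j], self.grid.tau[k], self.softmax_form
        )


def grid_posterior(
    dataset: pd.DataFrame, grid: ParameterGrid, form: str = "temperature_divide"
) -> PosteriorGrid:
    """Evaluate the choice log-likelihood on every grid cell and normalize.

    The likelihood is computed in the log domain and normalized by the
    log-sum-exp over cells, so very sharp posteriors do not underflow.
    Vectorized over (alpha, gamma) with a short loop over the tau axis.
    """
    ml, pl, mr, pr, sign = _choice_arrays(dataset)
    a = grid.alpha[:, None]  # (A, 1) broadcast over trials
    rs_l, rs_r = ml[None, :] ** a, mr[None, :] ** a  # (A, T)
    g = grid.gamma[:, None]
    ps_l = pl[None, :] ** g / (pl[None, :] ** g + (1 - pl[None, :]) ** g) ** (1 / g)
    ps_r = pr[None, :] ** g / (pr[None, :] ** g + (1 - pr[None, :]) ** g) ** (1 / g)
    # signed sEV difference per (alpha, gamma, trial)
    d = rs_l[:, None, :] * ps_l[None, :, :] - rs_r[:, None, :] * ps_r[None, :, :]
    d *= sign[None, None, :]
    log_joint = np.empty(grid.shape)
    for k, tau in enumerate(grid.tau):
        beta = _inverse_noise(float(tau), form)
        log_joint[:, :, k] = -np.logaddexp(0.0, -d * beta).sum(axis=-1)
    log_z = logsumexp(log_joint)
    if not np.isfinite(log_z):
        raise FloatingPointError("posterior normalization failed (all mass underflowed)")
    mass = np.exp(log_joint - log_z)
    return PosteriorGrid(grid=grid, log_joint=log_joint, posterior_mass=mass, softmax_form=form)


def marginal_means(posterior: PosteriorGrid) -> ProspectParams:
    """Posterior-mean estimate per parameter, on the linear parameter scale."""
    marg = posterior.marginals
    est = {
        name: float(np.dot(posterior.grid.axis(name), marg[name]))
        for name in ("alpha", "gamma", "tau")
    }
    return ProspectParams(softmax_form=posterior.softmax_form, **est)


@dataclass
class FitConfig:
    """Configuration of the grid-based Bayesian fit."""

    bounds: Mapping[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    n_points: int = 150
    softmax_form: str = "temperature_divide"
    per_condition: bool = True


@dataclass
class FitResult:
    params: ProspectParams
    posterior: PosteriorGrid
    log_evidence: float
    n_trials: int
    condition: str | None = None


def fit_prospect(dataset: pd.DataFrame, config: FitConfig | None = None):
    """Fit the choice model by grid posterior and marginal means.

    With ``per_condition=True`` (default) each timing condition is fitted
    separately and a dict ``{condition: FitResult}`` is returned; otherwise a
    single FitResult over all trials.
    """
    config = config or FitConfig()
    grid = build_grid(config.bounds, config.n_points)

    def _fit(df: pd.DataFrame, condition=None) -> FitResult:
        post = grid_posterior(df, grid, config.softmax_form)
        n = int(df["choice"].isin(["left", "right"]).sum())
        return FitResult(
            params=marginal_means(post),
            posterior=post,
            log_evidence=post.log_evidence,
            n_trials=n,
            condition=condition,
        )

    if not config.per_condition:
        return _fit(dataset)
    return {
        cond: _fit(sub, cond)
        for cond, sub in dataset.groupby("condition", sort=True, observed=True)
    }


def fits_to_table(fits, subject: str | int | None = None) -> pd.DataFrame:
    """Tidy table (subject, condition, alpha, gamma, tau, log_evidence) from fit results."""
    if isinstance(fits, FitResult):
        fits = {fits.condition or "all": fits}
    rows = []
    for cond, res in fits.items():
        rows.append(
            {
                "subject": subject,
                "condition": cond,
                "alpha": res.params.alpha,
                "gamma": res.params.gamma,
                "tau": res.params.tau,
                "log_evidence": res.log_evidence,
                "n_trials": res.n_trials,
            }
        )
    return pd.DataFrame(rows)


def replace_params(params: ProspectParams, **kwargs) -> ProspectParams:
    return replace(params, **kwargs)
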