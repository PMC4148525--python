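"""Canonical double-gamma hemodynamic response function.

The response is a difference of two gamma densities, parameterized by the
times of the positive peak and the undershoot trough.  With dispersion 1 s the
gamma shape is chosen as ``delay/dispersion + 1`` so that the density's mode
falls exactly at the stated delay.  The kernel is normalized by its analytic
value at the peak delay, which makes the normalization independent of the
sampling grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class HrfParams:
    """Shape parameters of the double-gamma response (seconds)."""

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion_s: float = 1.0
    undershoot_dispersion_s: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    #: kernel support used when convolving event trains (not the epoch window)
    duration_s: float = 32.0

    def __post_init__(self) -> None:
        if min(self.peak_delay_s, self.undershoot_delay_s, self.peak_dispersion_s,
               self.undershoot_dispersion_s, self.duration_s) <= 0:
            raise ValueError("HRF delays, dispersions and duration must be > 0")
        if not 0 <= self.undershoot_ratio < 1:
            raise ValueError("undershoot_ratio must lie in [0, 1)")


def _double_gamma(t: np.ndarray, params: HrfParams) -> np.ndarray:
    peak = stats.gamma.pdf(
        t, params.peak_delay_s / params.peak_dispersion_s + 1.0,
        scale=params.peak_dispersion_s,
    )
    under = stats.gamma.pdf(
        t, params.undershoot_delay_s / params.undershoot_dispersion_s + 1.0,
        scale=params.undershoot_dispersion_s,
    )
    return peak - params.undershoot_ratio * under


def canonical_hrf(
    dt_s: float, params: HrfParams | None = None, duration_s: float = 16.0
) -> np.ndarray:
    """Sample the canonical HRF on the half-open grid [0, duration_s).

    The returned vector is causal (zero at t=0), peaks near the configured
    peak delay, and is scaled so the analytic peak value equals 1.
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be > 0")
    params = params or HrfParams()
    n_points = int(np.ceil(duration_s / dt_s - 1e-9))  # half-open [0, duration_s)
    t = np.arange(n_points) * dt_s
    h = _double_gamma(t, params)
    scale = _double_gamma(np.array([params.peak_delay_s]), params)[0]
    if scale <= 0:
        raise ValueError("degenerate HRF parameters: non-positive peak value")
    return h / scale
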