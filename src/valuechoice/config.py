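"""Run configuration for the end-to-end pipeline (YAML round-trip)."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

#: ROI coding regimes emulating the hypothesized dissociation: a prefrontal
#: region coding overall input value under time pressure and a resolved
#: value comparison without it, and a parietal region comparing values only
#: under time pressure.
DEFAULT_ROIS = {
    "vmPFC": {
        "coding_regime": {"short": "sum_coder", "middle": "diff_coder", "long": "diff_coder"},
        "weight": 0.5,
        "noise_sd": 1.0,
        "ar1_coefficient": 0.3,
    },
    "pSPL": {
        "coding_regime": {"short": "diff_coder", "middle": "diff_coder", "long": "null"},
        "weight": 0.5,
        "noise_sd": 1.0,
        "ar1_coefficient": 0.3,
    },
}


@dataclass
class RunConfig:
    """All knobs of a simulate -> fit -> analyze run; every stage is seeded."""

    seed: int = 0
    n_subjects: int = 28
    #: one shared trial schedule for the whole cohort (as in a fixed design)
    shared_schedule: bool = True
    tr_s: float = 3.0
    glm_variant: str = "chosen_unchosen"
    #: build ROI designs from each subject's fitted parameters (True) or from
    #: the generator's known subjective values (False)
    use_fitted_values: bool = False
    schedule: dict = field(default_factory=dict)
    agent: dict = field(
        default_factory=lambda: {
            "alpha_range": [0.6, 1.2],
            "gamma_range": [0.5, 1.2],
            "tau_range": [0.05, 0.3],
        }
    )
    rt: dict = field(default_factory=dict)
    rois: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_ROIS.items()})
    fit: dict = field(
        default_factory=lambda: {
            "n_points": 150,
            "softmax_form": "temperature_divide",
            "per_condition": True,
        }
    )
    epoch: dict = field(default_factory=lambda: {"window_s": 16.0, "dt_s": 0.3})
    make_plots: bool = True

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.seed < 0:
            raise ValueError("seed must be a non-negative integer")
        if len(self.rois) < 1:
            raise ValueError("at least one ROI must be configured")
        for key in ("alpha_range", "gamma_range", "tau_range"):
            lo, hi = self.agent[key]
            if not (0 < lo <= hi):
                raise ValueError(f"invalid agent {key}: {self.agent[key]}")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg
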