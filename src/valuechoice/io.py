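"""Tab-separated file formats for events tables and ROI timeseries.

Events tables follow the BIDS events convention (``onset`` and ``duration``
first, seconds, tab-separated, missing values as ``n/a``), extended with the
task-specific columns.  ROI timeseries are one column per ROI, one row per
volume, with the repetition time recorded in a ``# tr_s=...`` header comment.
All round-trips are lossless (full float precision).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .roi import RoiTimeseries

#: internal column -> events-file column
_EVENTS_RENAME = {
    "stimulus_onset_s": "onset",
    "reaction_time_s": "rt",
}

EVENTS_REQUIRED = [
    "onset", "duration", "condition", "block_index", "trial_index",
    "magnitude_left", "magnitude_right", "probability_left", "probability_right",
    "is_nobrainer", "display_mode", "choice", "rt",
    "outcome_left", "outcome_right", "chosen_value", "unchosen_value",
    "planned_outcome_delay_s", "planned_iti_s",
]

_BOOL_COLUMNS = ["is_nobrainer", "outcome_left", "outcome_right"]


def write_events(dataset: pd.DataFrame, path) -> None:
    """Write a choice dataset as a BIDS-like events table."""
    df = dataset.rename(columns=_EVENTS_RENAME).copy()
    df["duration"] = df["rt"]
    for col in _BOOL_COLUMNS:
        df[col] = df[col].astype(int)
    df = df[EVENTS_REQUIRED]
    df.to_csv(path, sep="\t", index=False, na_rep="n/a", float_format="%.17g")


def read_events(path) -> pd.DataFrame:
    """Read an events table back into the internal dataset layout.

    Raises a schema error naming the first missing required column.
    """
    df = pd.read_csv(
        path, sep="\t", na_values=["n/a"], keep_default_na=False,
        float_precision="round_trip",
    )
    for col in EVENTS_REQUIRED:
        if col not in df.columns:
            raise ValueError(f"events file {path} lacks required column {col!r}")
    for col in _BOOL_COLUMNS:
        df[col] = df[col].astype(bool)
    df = df.drop(columns=["duration"])
    df = df.rename(columns={v: k for k, v in _EVENTS_RENAME.items()})
    df["choice"] = df["choice"].astype(str)
    bad = ~df["choice"].isin(["left", "right", "missed"])
    if bad.any():
        raise ValueError(f"events file {path} has ill-typed 'choice' values")
    return df


def write_timeseries(series: dict[str, RoiTimeseries] | list[RoiTimeseries], path) -> None:
    """Write ROI series as a TSV with a ``# tr_s=...`` header comment."""
    if isinstance(series, dict):
        series = list(series.values())
    tr = {ts.tr_s for ts in series}
    n = {ts.n_volumes for ts in series}
    if len(tr) != 1 or len(n) != 1:
        raise ValueError("all ROI series must share tr_s and length")
    df = pd.DataFrame({ts.roi_label: ts.values for ts in series})
    with open(path, "w") as fh:
        fh.write(f"# tr_s={tr.pop()!r}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_timeseries(path) -> dict[str, RoiTimeseries]:
    """Read an ROI timeseries table; the TR comes from the header comment."""
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# tr_s="):
            raise ValueError(f"timeseries file {path} lacks the '# tr_s=' header")
        tr_s = float(first.split("=", 1)[1])
        df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    if df.isna().any().any():
        raise ValueError(f"timeseries file {path} has missing/ragged values")
    return {
        col: RoiTimeseries(roi_label=col, values=df[col].to_numpy(float), tr_s=tr_s)
        for col in df.columns
    }


def write_truth_sidecar(truths, path) -> None:
    """Key-value ground-truth sidecar for simulated ROI series."""
    lines = []
    for t in truths:
        regime = (
            t.coding_regime
            if isinstance(t.coding_regime, str)
            else ",".join(f"{k}:{v}" for k, v in sorted(t.coding_regime.items()))
        )
        lines += [
            f"{t.roi_label}.coding_regime={regime}",
            f"{t.roi_label}.weight={t.weight!r}",
            f"{t.roi_label}.noise_sd={t.noise_sd!r}",
            f"{t.roi_label}.ar1_coefficient={t.ar1_coefficient!r}",
            f"{t.roi_label}.tr_s={t.tr_s!r}",
        ]
    Path(path).write_text("\n".join(lines) + "\n")


def events_path(out_dir, subject: int) -> Path:
    return Path(out_dir) / f"sub-{subject:02d}_events.tsv"


def bold_path(out_dir, subject: int) -> Path:
    return Path(out_dir) / f"sub-{subject:02d}_bold.tsv"
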