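"""File dialects: trace CSV with events sidecar JSON, activity-ratio
datasets as CSV, protocols as YAML/JSON, parameter blocks as JSON."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .fret import FretTrace, StimulusEvent
from .tpm import TPMDataset

__all__ = [
    "write_trace",
    "read_trace",
    "write_tpm_dataset",
    "read_tpm_dataset",
    "read_protocol",
    "write_json",
]

PathLike = Union[str, Path]


def write_trace(trace: FretTrace, csv_path: PathLike,
                events_path: Optional[PathLike] = None,
                truth: Optional[Dict] = None,
                truth_path: Optional[PathLike] = None) -> None:
    """Write a trace as ``t_s,ratio`` CSV with an events sidecar JSON.

    The events sidecar defaults to ``<stem>.events.json``; an optional
    hidden-truth record goes to ``<stem>.truth.json``.
    """
    csv_path = Path(csv_path)
    pd.DataFrame({"t_s": trace.t, "ratio": trace.ratio}).to_csv(
        csv_path, index=False)
    if events_path is None:
        events_path = csv_path.with_suffix("").with_suffix(".events.json")
    payload = {
        "strain": trace.strain,
        "events": [{"t_s": e.t, "kind": e.kind, "L_mM": e.L}
                   for e in trace.events],
    }
    Path(events_path).write_text(json.dumps(payload, indent=1))
    if truth is not None:
        if truth_path is None:
            truth_path = csv_path.with_suffix("").with_suffix(".truth.json")
        Path(truth_path).write_text(json.dumps(truth, indent=1))


def read_trace(csv_path: PathLike,
               events_path: Optional[PathLike] = None) -> FretTrace:
    """Read a ``t_s,ratio`` CSV and its events sidecar back into a trace."""
    csv_path = Path(csv_path)
    try:
        df = pd.read_csv(csv_path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed trace CSV {csv_path}: {exc}") from exc
    for col in ("t_s", "ratio"):
        if col not in df.columns:
            raise ValueError(f"{csv_path}: missing required column {col!r}")
    if events_path is None:
        events_path = csv_path.with_suffix("").with_suffix(".events.json")
    strain = "tar-only"
    events: List[StimulusEvent] = []
    events_path = Path(events_path)
    if events_path.exists():
        payload = json.loads(events_path.read_text())
        strain = payload.get("strain", strain)
        events = [StimulusEvent(e["t_s"], e["kind"], e.get("L_mM", 0.0))
                  for e in payload.get("events", [])]
    return FretTrace(t=df["t_s"].to_numpy(), ratio=df["ratio"].to_numpy(),
                     events=events, strain=strain)


def write_tpm_dataset(data: TPMDataset, path: PathLike) -> None:
    """Write an activity-ratio dataset as ``R_nm,ratio,sd`` CSV."""
    df = pd.DataFrame({"R_nm": data.R, "ratio": data.ratio})
    df["sd"] = data.sd if data.sd is not None else np.nan
    df.to_csv(path, index=False)


def read_tpm_dataset(path: PathLike, variant: str = "linear") -> TPMDataset:
    """Read a ``R_nm,ratio[,sd]`` CSV into a ratio dataset.

    Malformed rows are reported with their line numbers.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed dataset CSV {path}: {exc}") from exc
    for col in ("R_nm", "ratio"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df.index[df[["R_nm", "ratio"]].isna().any(axis=1)]
    if len(bad):
        lines = ", ".join(str(i + 2) for i in bad[:5])  # header is line 1
        raise ValueError(f"{path}: non-numeric or missing values at "
                         f"line(s) {lines}")
    sd = df["sd"].to_numpy() if "sd" in df.columns else None
    if sd is not None and np.all(np.isnan(sd)):
        sd = None
    return TPMDataset(R=df["R_nm"].to_numpy(), ratio=df["ratio"].to_numpy(),
                      sd=sd, variant=variant)


def read_protocol(path: PathLike) -> List[Tuple[float, float]]:
    """Read a stimulus protocol: YAML/JSON list of {t_s, L_mM} entries."""
    path = Path(path)
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, list) or not data:
        raise ValueError(f"{path}: protocol must be a non-empty list")
    out = []
    for i, entry in enumerate(data):
        try:
            out.append((float(entry["t_s"]), float(entry["L_mM"])))
        except (KeyError, TypeError) as exc:
            raise ValueError(
                f"{path}: entry {i} must have t_s and L_mM") from exc
    return out


def write_json(obj: Dict, path: PathLike) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))
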