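"""On-disk formats for traces, event tables, behavior tables, and spectra.

Traces are little-endian 32-bit float raw binary next to a JSON metadata
sidecar (``<stem>.json``) holding sampling rate, identity, duration, and
the immobility intervals.  Tabular artifacts are UTF-8 comma-separated
files with a mandatory header and ``.`` decimal.  All readers validate
schema strictly and are total on this module's writer output.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from swrlab.types import MIN_SAMPLING_RATE, LfpTrace, SwrEvent

VALID_GENOTYPES = {"WT", "KO"}
VALID_VIRUSES = {"control", "DREADD", "none"}
VALID_DRUGS = {"VEH", "CNO", "none"}
VALID_TRIALS = {"N1", "F", "N2"}

BEHAVIOR_COLUMNS = ["mouse_id", "genotype", "virus", "drug", "trial", "interaction_time"]
EVENT_COLUMNS = ["onset_s", "offset_s", "duration_ms", "peak_z", "peak_time_s", "immobile_flag"]


class SchemaError(ValueError):
    """An on-disk artifact violates its schema."""


def _intervals_from_track(track: np.ndarray, fs: float) -> list[list[float]]:
    """Immobile per-sample boolean -> list of [start_s, stop_s) intervals."""
    track = np.asarray(track, dtype=bool)
    if not track.any():
        return []
    edges = np.diff(track.astype(np.int8))
    starts = (np.flatnonzero(edges == 1) + 1).tolist()
    stops = (np.flatnonzero(edges == -1) + 1).tolist()
    if track[0]:
        starts.insert(0, 0)
    if track[-1]:
        stops.append(track.size)
    return [[s / fs, e / fs] for s, e in zip(starts, stops)]


def track_from_intervals(intervals: list[list[float]], n: int, fs: float) -> np.ndarray:
    """Immobile interval list -> per-sample boolean track of length ``n``."""
    track = np.zeros(n, dtype=bool)
    for start, stop in intervals:
        a = int(round(start * fs))
        b = int(round(stop * fs))
        track[max(0, a) : min(n, b)] = True
    return track


def write_trace(trace: LfpTrace, path: str | Path) -> Path:
    """Write a trace as float32 little-endian binary + JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    trace.samples.astype("<f4").tofile(path)
    meta = {
        "sampling_rate": trace.sampling_rate,
        "mouse": trace.mouse_id,
        "channel": trace.electrode_id,
        "trial": trace.trial,
        "duration": trace.duration,
        "n_samples": int(trace.samples.size),
    }
    if trace.mobility_track is not None:
        meta["immobile_intervals"] = _intervals_from_track(
            trace.mobility_track, trace.sampling_rate
        )
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path


def read_trace(path: str | Path) -> LfpTrace:
    """Read a binary trace; raises :class:`SchemaError` on any mismatch."""
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise SchemaError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("sampling_rate", "n_samples"):
        if key not in meta:
            raise SchemaError(f"sidecar missing required key {key!r}")
    fs = float(meta["sampling_rate"])
    if fs <= MIN_SAMPLING_RATE:
        raise SchemaError(
            f"sampling rate {fs} Hz cannot represent the 150-250 Hz ripple band"
        )
    samples = np.fromfile(path, dtype="<f4").astype(np.float64)
    if samples.size != int(meta["n_samples"]):
        raise SchemaError(
            f"binary holds {samples.size} samples but sidecar declares {meta['n_samples']}"
        )
    track = None
    if "immobile_intervals" in meta:
        track = track_from_intervals(meta["immobile_intervals"], samples.size, fs)
    return LfpTrace(
        samples=samples,
        sampling_rate=fs,
        mouse_id=str(meta.get("mouse", "m0")),
        electrode_id=int(meta.get("channel", 1)),
        trial=str(meta.get("trial", "baseline")),
        mobility_track=track,
    )


def write_behavior(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table[BEHAVIOR_COLUMNS].to_csv(path, index=False)
    return path


def read_behavior(path: str | Path) -> pd.DataFrame:
    """Read and validate a behavior table.

    Enforces: required columns present; factor levels known (stimulus-mouse
    genotypes such as HET are not valid test rows); nonnegative times; each
    (mouse, drug, trial) key unique.
    """
    table = pd.read_csv(path)
    missing = [c for c in BEHAVIOR_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"behavior table missing columns {missing}")
    for col, valid in (
        ("genotype", VALID_GENOTYPES),
        ("virus", VALID_VIRUSES),
        ("drug", VALID_DRUGS),
        ("trial", VALID_TRIALS),
    ):
        bad = set(table[col].astype(str)) - valid
        if bad:
            raise SchemaError(f"unknown {col} level(s) {sorted(bad)}")
    if (table["interaction_time"] < 0).any():
        raise SchemaError("negative interaction times")
    dup = table.duplicated(subset=["mouse_id", "drug", "trial"])
    if dup.any():
        raise SchemaError("duplicate (mouse, drug, trial) rows")
    return table


def write_events(events: list[SwrEvent], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "onset_s": e.onset,
            "offset_s": e.offset,
            "duration_ms": e.duration_ms,
            "peak_z": e.peak_z,
            "peak_time_s": e.peak_time,
            "immobile_flag": int(e.immobile),
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False)
    return path


def read_events(path: str | Path) -> list[SwrEvent]:
    table = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"event table missing columns {missing}")
    return [
        SwrEvent(
            onset=row.onset_s,
            offset=row.offset_s,
            peak_z=row.peak_z,
            peak_time=row.peak_time_s,
            immobile=bool(row.immobile_flag),
        )
        for row in table.itertuples()
    ]


def write_ground_truth(events: list[tuple[float, float, float]], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(events, columns=["onset_s", "offset_s", "peak_uv"]).to_csv(path, index=False)
    return path


def read_ground_truth(path: str | Path) -> list[tuple[float, float, float]]:
    table = pd.read_csv(path)
    return [tuple(map(float, row)) for row in table[["onset_s", "offset_s", "peak_uv"]].to_numpy()]


def write_spectrum(spectrum, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"frequency_hz": spectrum.frequencies, "normalized_power": spectrum.power}
    ).to_csv(path, index=False)
    return path
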