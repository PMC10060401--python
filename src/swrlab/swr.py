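"""Sharp-wave-ripple detection and event statistics.

Detection follows the Hilbert-envelope convention: the LFP is notched at
60 Hz, band-pass filtered to the ripple band (150–250 Hz), Hilbert
transformed, and the envelope magnitude z-scored against the whole
recording.  Events are excursions of the (lightly smoothed) z-scored
envelope above a 3-SD threshold lasting at least 15 ms; boundaries are
extended outward to a lower crossing (0.5 SD) so that event duration is
not truncated to the supra-threshold core, and events separated by less
than a short gap are merged, since envelope ringing should not split one
ripple into two.

Because ripples are an immobility phenomenon, events whose peak falls in
a mobile epoch are flagged and by default excluded from summaries, and
event frequency is reported per immobility-second.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from swrlab import spectral
from swrlab.types import RIPPLE_BAND, LfpTrace, SwrEvent, SwrSummary

DEFAULT_THRESHOLD_SD = 3.0
DEFAULT_MIN_DURATION_MS = 15.0
DEFAULT_SMOOTH_MS = 8.0
DEFAULT_BOUNDARY_SD = 0.5
DEFAULT_MERGE_GAP_MS = 15.0


def ripple_envelope(
    trace: LfpTrace, rolling_baseline_s: float | None = None
) -> np.ndarray:
    """Z-scored ripple-band Hilbert envelope of an LFP trace.

    The trace is notched at 60 Hz, band-passed to 150–250 Hz, and the
    magnitude of its analytic signal is z-scored.  By default the z-score
    uses the whole recording's envelope mean and SD; passing
    ``rolling_baseline_s`` switches to a local (rolling-window) mean/SD
    of that length in seconds, for recordings whose noise floor drifts.

    Returns a series with mean 0 and SD 1 (global variant).
    """
    if trace.sampling_rate < 600.0:
        raise ValueError("sampling rate must be at least 600 Hz for ripple analysis")
    if np.ptp(trace.samples) == 0.0:
        raise ValueError("constant trace: envelope has zero variance")
    filtered = spectral.band_filter(spectral.notch_60(trace), *RIPPLE_BAND)
    from scipy.signal import hilbert

    env = np.abs(hilbert(filtered.samples))
    if rolling_baseline_s is None:
        sd = env.std()
        if sd == 0.0:
            raise ValueError("constant trace: envelope has zero variance")
        return (env - env.mean()) / sd
    win = int(round(rolling_baseline_s * trace.sampling_rate))
    s = pd.Series(env)
    mu = s.rolling(win, min_periods=1, center=True).mean().to_numpy()
    sd = s.rolling(win, min_periods=1, center=True).std().to_numpy()
    sd = np.where((sd == 0) | ~np.isfinite(sd), np.nan, sd)
    if np.all(np.isnan(sd)):
        raise ValueError("constant trace: envelope has zero variance")
    sd = np.where(np.isnan(sd), np.nanmean(sd), sd)
    return (env - mu) / sd


def _runs_above(x: np.ndarray, level: float) -> list[tuple[int, int]]:
    """Half-open index runs where ``x > level``."""
    above = x > level
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    stops = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.insert(starts, 0, 0)
    if above[-1]:
        stops = np.append(stops, x.size)
    return list(zip(starts.tolist(), stops.tolist()))


def detect_swr(
    envelope: np.ndarray,
    sampling_rate: float,
    threshold_sd: float = DEFAULT_THRESHOLD_SD,
    min_duration_ms: float = DEFAULT_MIN_DURATION_MS,
    smooth_ms: float = DEFAULT_SMOOTH_MS,
    boundary_sd: float = DEFAULT_BOUNDARY_SD,
    merge_gap_ms: float = DEFAULT_MERGE_GAP_MS,
    mobility_track: np.ndarray | None = None,
    raw_envelope_uv: np.ndarray | None = None,
) -> list[SwrEvent]:
    """Detect ripple events on a z-scored envelope.

    An event is a run where the moving-average-smoothed envelope stays
    above ``threshold_sd`` for at least ``min_duration_ms``; its
    boundaries are then extended outward to the nearest ``boundary_sd``
    crossing, and events whose extended boundaries are closer than
    ``merge_gap_ms`` are merged.  Events are returned sorted and
    non-overlapping; an empty list is a valid result.

    ``mobility_track`` (per-sample, True = immobile) sets each event's
    ``immobile`` flag from its peak sample; ``raw_envelope_uv`` records
    each event's raw (pre-z-score) peak amplitude for diagnostics.
    """
    env = np.asarray(envelope, dtype=np.float64)
    fs = sampling_rate
    if smooth_ms > 0:
        k = max(1, int(round(smooth_ms * fs / 1000.0)))
        kernel = np.ones(k) / k
        smoothed = np.convolve(env, kernel, mode="same")
    else:
        smoothed = env

    min_samples = max(1, int(round(min_duration_ms * fs / 1000.0)))
    cores = [(a, b) for a, b in _runs_above(smoothed, threshold_sd) if b - a >= min_samples]
    if not cores:
        return []

    below = smoothed <= boundary_sd
    extended: list[tuple[int, int]] = []
    for a, b in cores:
        left = a
        while left > 0 and not below[left - 1]:
            left -= 1
        right = b
        while right < smoothed.size and not below[right]:
            right += 1
        extended.append((left, right))

    merge_gap = int(round(merge_gap_ms * fs / 1000.0))
    merged: list[list[int]] = []
    for a, b in extended:
        if merged and a - merged[-1][1] < merge_gap:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])

    events = []
    for a, b in merged:
        peak_idx = a + int(np.argmax(smoothed[a:b]))
        immobile = True
        if mobility_track is not None:
            immobile = bool(mobility_track[peak_idx])
        peak_uv = float("nan")
        if raw_envelope_uv is not None:
            peak_uv = float(np.max(raw_envelope_uv[a:b]))
        events.append(
            SwrEvent(
                onset=a / fs,
                offset=b / fs,
                peak_z=float(smoothed[peak_idx]),
                peak_time=peak_idx / fs,
                peak_uv=peak_uv,
                immobile=immobile,
            )
        )
    return events


def detect_swr_trace(trace: LfpTrace, **kwargs) -> list[SwrEvent]:
    """Full detection pipeline from a raw LFP trace (see :func:`detect_swr`)."""
    env = ripple_envelope(trace)
    return detect_swr(
        env,
        trace.sampling_rate,
        mobility_track=trace.mobility_track,
        **kwargs,
    )


def window_slice(events: list[SwrEvent], start_s: float, end_s: float) -> list[SwrEvent]:
    """Events with onset in ``[start_s, end_s)``, re-referenced to window start."""
    if start_s >= end_s:
        raise ValueError("window start must precede end")
    out = []
    for ev in events:
        if start_s <= ev.onset < end_s:
            out.append(
                SwrEvent(
                    onset=ev.onset - start_s,
                    offset=ev.offset - start_s,
                    peak_z=ev.peak_z,
                    peak_time=ev.peak_time - start_s,
                    peak_uv=ev.peak_uv,
                    immobile=ev.immobile,
                )
            )
    return out


_RATIO_MEASURES = ("count", "mean_amplitude", "mean_duration_ms", "mean_interval_s")


def _bin_stats(events: list[SwrEvent]) -> tuple[float, float, float]:
    if not events:
        return float("nan"), float("nan"), float("nan")
    amps = [e.peak_z for e in events]
    durs = [e.duration_ms for e in events]
    onsets = sorted(e.onset for e in events)
    interval = float(np.mean(np.diff(onsets))) if len(onsets) >= 2 else float("nan")
    return float(np.mean(amps)), float(np.mean(durs)), interval


def summarize_swr(
    events: list[SwrEvent],
    mobility_track: np.ndarray | None,
    sampling_rate: float,
    trial_duration: float,
    baseline: SwrSummary | None = None,
    immobile_only: bool = True,
) -> SwrSummary:
    """Per-trial SWR statistics, optionally normalized to a baseline trial.

    ``event_frequency`` is count per immobility-second.  ``mean_interval``
    is onset-to-onset over consecutive events (NaN below two events).
    ``per_minute`` reports the same measures within 60-s bins.  With a
    ``baseline`` summary, each measure's ratio to baseline is stored in
    ``baseline_ratio``.  ``immobile_only`` drops events flagged as
    occurring during mobility before computing statistics.
    """
    for ev in events:
        if not (0.0 <= ev.onset < trial_duration):
            raise ValueError("event onsets must lie within [0, trial_duration)")
    kept = [e for e in events if e.immobile] if immobile_only else list(events)

    if mobility_track is not None:
        immobility_time = float(np.asarray(mobility_track, bool).sum()) / sampling_rate
    else:
        immobility_time = trial_duration
    if immobility_time == 0.0 and kept:
        raise ValueError("events present but immobility time is zero")

    mean_amp, mean_dur, mean_int = _bin_stats(kept)
    freq = len(kept) / immobility_time if immobility_time > 0 else float("nan")

    minutes = []
    n_bins = int(np.ceil(trial_duration / 60.0))
    for m in range(n_bins):
        sub = [e for e in kept if 60.0 * m <= e.onset < 60.0 * (m + 1)]
        a, d, i = _bin_stats(sub)
        minutes.append(
            {
                "minute": m,
                "count": len(sub),
                "mean_amplitude": a,
                "mean_duration_ms": d,
                "mean_interval_s": i,
            }
        )
    per_minute = pd.DataFrame(minutes)

    summary = SwrSummary(
        count=len(kept),
        mean_amplitude=mean_amp,
        mean_duration_ms=mean_dur,
        mean_interval_s=mean_int,
        event_frequency=freq,
        immobility_time_s=immobility_time,
        per_minute=per_minute,
    )
    if baseline is not None:
        for name in _RATIO_MEASURES:
            base = getattr(baseline, name)
            val = getattr(summary, name)
            if base and np.isfinite(base) and base != 0:
                summary.baseline_ratio[name] = float(val) / float(base)
            else:
                summary.baseline_ratio[name] = float("nan")
    return summary


def match_events(
    detected: list[SwrEvent], truth: list[tuple[float, float, float]]
) -> tuple[int, int, int]:
    """Match detected events to ground-truth intervals by overlap.

    Each truth interval may claim at most one detected event and vice
    versa; a match requires the half-open intervals to intersect.
    Returns (true_positives, false_positives, false_negatives).
    """
    used = [False] * len(detected)
    tp = 0
    for onset, offset, _ in truth:
        for i, ev in enumerate(detected):
            if used[i]:
                continue
            if ev.onset < offset and onset < ev.offset:
                used[i] = True
                tp += 1
                break
    fp = used.count(False)
    fn = len(truth) - tp
    return tp, fp, fn
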