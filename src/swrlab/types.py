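"""Core domain containers shared across the analysis stages.

Conventions: time is seconds from trial start (0-based); event intervals
are half-open ``[onset, offset)``; voltages are microvolts; the mobility
track is a per-sample boolean series where ``True`` means *immobile*
(quiet wakefulness), the state in which sharp-wave ripples occur.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

RIPPLE_BAND = (150.0, 250.0)
THETA_BAND = (4.0, 12.0)
LOW_GAMMA_BAND = (30.0, 55.0)

#: minimum sampling rate able to represent the ripple band (2 x 250 Hz)
MIN_SAMPLING_RATE = 2.0 * RIPPLE_BAND[1]

VALID_TRIALS = frozenset({"baseline", "novel", "familiar"})


@dataclass
class LfpTrace:
    """One electrode's voltage series with its recording metadata.

    Parameters
    ----------
    samples : ndarray
        LFP voltage in microvolts, one value per sample.
    sampling_rate : float
        Samples per second; must exceed twice the ripple-band upper edge
        (500 Hz) so that 150–250 Hz events are representable.
    mouse_id, electrode_id, trial
        Recording identity; mice carry up to three electrodes and trials
        are 3-min baseline or 5-min social exposures.
    mobility_track : ndarray or None
        Per-sample boolean, ``True`` = immobile.  Must cover the full
        trace when present.
    """

    samples: np.ndarray
    sampling_rate: float
    mouse_id: str = "m0"
    electrode_id: int = 1
    trial: str = "baseline"
    mobility_track: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1-D series")
        if self.sampling_rate <= MIN_SAMPLING_RATE:
            raise ValueError(
                f"sampling_rate {self.sampling_rate} Hz cannot represent the "
                f"ripple band; need > {MIN_SAMPLING_RATE} Hz"
            )
        if self.trial not in VALID_TRIALS:
            raise ValueError(f"trial must be one of {sorted(VALID_TRIALS)}")
        if self.mobility_track is not None:
            self.mobility_track = np.asarray(self.mobility_track, dtype=bool)
            if self.mobility_track.shape != self.samples.shape:
                raise ValueError("mobility track must cover the full trace")

    @property
    def duration(self) -> float:
        """Trace length in seconds."""
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate

    def immobility_time(self) -> float:
        """Total immobile time in seconds (0 if no track)."""
        if self.mobility_track is None:
            return 0.0
        return float(self.mobility_track.sum()) / self.sampling_rate


@dataclass
class GroundTruth:
    """Known ripple events and mobility state of a simulated trace.

    ``events`` is a list of ``(onset_s, offset_s, peak_uv)`` tuples,
    sorted and non-overlapping; every event lies entirely inside an
    immobile epoch of ``mobility_track``.
    """

    events: list[tuple[float, float, float]]
    mobility_track: np.ndarray

    def __post_init__(self) -> None:
        self.mobility_track = np.asarray(self.mobility_track, dtype=bool)
        last_off = -np.inf
        for onset, offset, _ in self.events:
            if offset <= onset:
                raise ValueError("event offset must exceed onset")
            if onset < last_off:
                raise ValueError("events must be sorted and non-overlapping")
            last_off = offset


@dataclass(frozen=True)
class SwrEvent:
    """A detected sharp-wave ripple.

    ``peak_z`` is the maximum of the z-scored ripple-band envelope within
    the event; ``immobile`` records whether the peak fell in an immobile
    epoch (SWRs are an immobility phenomenon, so mobile-peak events are
    normally excluded from summaries).
    """

    onset: float
    offset: float
    peak_z: float
    peak_time: float
    peak_uv: float = float("nan")
    immobile: bool = True

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError("offset must exceed onset")

    @property
    def duration_ms(self) -> float:
        return (self.offset - self.onset) * 1000.0


@dataclass
class SwrSummary:
    """Per-trial SWR statistics.

    ``event_frequency`` is the count divided by immobility time (events
    per immobility-second).  ``mean_interval`` is the mean onset-to-onset
    gap between consecutive events, NaN with fewer than two events.
    ``per_minute`` holds one row per 60-s bin of the trial with the same
    measures computed within the bin.  ``baseline_ratio`` maps measure
    name -> value divided by the baseline trial's value.
    """

    count: int
    mean_amplitude: float
    mean_duration_ms: float
    mean_interval_s: float
    event_frequency: float
    immobility_time_s: float
    per_minute: "object" = None  # pandas DataFrame
    baseline_ratio: dict[str, float] = field(default_factory=dict)


@dataclass
class PowerSpectrum:
    """Normalized power spectral density on the 0–100 Hz grid.

    Power values are dimensionless and sum to 1 over the grid.
    """

    frequencies: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=np.float64)
        self.power = np.asarray(self.power, dtype=np.float64)
        if self.frequencies.shape != self.power.shape:
            raise ValueError("frequency and power grids must align")
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")
        if abs(self.power.sum() - 1.0) > 1e-9:
            raise ValueError("normalized spectrum must sum to 1 over 0-100 Hz")


@dataclass(frozen=True)
class BandPower:
    """Integrated normalized power in a frequency band."""

    label: str
    lo: float
    hi: float
    power: float
    baseline_ratio: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.power <= 1.0 + 1e-9):
            raise ValueError("normalized band power must lie in [0, 1]")
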