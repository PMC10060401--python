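"""Synthetic data generators with known ground truth.

Three generators emulate the three input classes of the study:

* :func:`simulate_lfp` — a vCA1 LFP trace: theta (4–12 Hz) and low-gamma
  (30–55 Hz) oscillations over 1/f ("pink") noise with 60 Hz line
  contamination, plus transient 150–250 Hz ripple bursts restricted to
  immobility epochs.  Returns the trace together with the ground-truth
  event list, which serves as the oracle for the ripple detector.
* :func:`simulate_behavior` — a factorial interaction-time table over
  genotype × virus × drug × trial with a per-mouse random intercept.
* :func:`simulate_image_stack` — a fluorescence z-stack with named ROI
  signals over a background, the oracle for the histology pipeline.

Every generator is fully determined by its seed: identical configs yield
bit-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from swrlab.types import GroundTruth, LfpTrace

log = logging.getLogger(__name__)

GENOTYPES = ("WT", "KO")
VIRUSES = ("control", "DREADD")
DRUGS = ("VEH", "CNO")
TRIALS = ("N1", "F", "N2")


class InvalidConfigError(ValueError):
    """A simulation config violates its invariants."""


# ---------------------------------------------------------------------------
# LFP


@dataclass
class LfpSimConfig:
    """Parameters of the LFP simulator.

    Amplitudes are microvolts; the oscillation carriers sit at the centre
    of their bands (theta 8 Hz, low gamma 40 Hz) with slow sinusoidal
    amplitude modulation so the spectral mass stays inside the band.
    ``ripple_rate`` is events per immobility-second; ripples are
    Hann-windowed sinusoid bursts placed by a Poisson process thinned to
    immobile epochs.  ``immobility_fraction`` is the target fraction of
    time spent immobile; bouts alternate with exponential lengths.
    """

    sampling_rate: float = 1000.0
    duration: float = 300.0
    theta_amp: float = 40.0
    gamma_amp: float = 10.0
    pink_noise_sd: float = 15.0
    pink_exponent: float = 1.0
    line_noise_amp: float = 5.0
    ripple_rate: float = 0.2
    ripple_amp_range: tuple[float, float] = (25.0, 50.0)
    ripple_dur_range: tuple[float, float] = (25.0, 80.0)
    ripple_freq_range: tuple[float, float] = (150.0, 250.0)
    immobility_fraction: float = 0.5
    mean_immobile_bout_s: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.duration <= 0:
            raise InvalidConfigError("duration must be positive")
        if self.sampling_rate <= 500.0:
            raise InvalidConfigError("sampling rate must exceed 500 Hz")
        if self.ripple_rate < 0:
            raise InvalidConfigError("ripple_rate must be nonnegative")
        lo, hi = self.ripple_dur_range
        if not (0 < lo <= hi <= 500):
            raise InvalidConfigError("ripple durations must lie in (0, 500] ms")
        flo, fhi = self.ripple_freq_range
        if not (150.0 <= flo <= fhi <= 250.0):
            raise InvalidConfigError("ripple frequencies must lie in [150, 250] Hz")
        if not (0.0 <= self.immobility_fraction <= 1.0):
            raise InvalidConfigError("immobility_fraction must lie in [0, 1]")
        for name in ("theta_amp", "gamma_amp", "pink_noise_sd", "line_noise_amp"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be nonnegative")


def _pink_noise(rng: np.random.Generator, n: int, sd: float, exponent: float) -> np.ndarray:
    """1/f^exponent noise via spectral shaping, scaled to the target SD."""
    if sd == 0.0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC
    shaped = np.fft.irfft(spec * scale, n)
    return shaped * (sd / shaped.std())


def _mobility_track(
    rng: np.random.Generator, n: int, fs: float, frac: float, mean_immobile_s: float
) -> np.ndarray:
    """Alternating immobile/mobile bouts with exponential lengths.

    Mean bout lengths are set so the long-run immobile fraction equals
    ``frac``; the first bout state is drawn with probability ``frac``.
    """
    if frac >= 1.0:
        return np.ones(n, dtype=bool)
    if frac <= 0.0:
        return np.zeros(n, dtype=bool)
    mean_mobile_s = mean_immobile_s * (1.0 - frac) / frac
    track = np.empty(n, dtype=bool)
    state = bool(rng.random() < frac)
    i = 0
    while i < n:
        mean = mean_immobile_s if state else mean_mobile_s
        bout = max(1, int(round(rng.exponential(mean) * fs)))
        track[i : i + bout] = state
        i += bout
        state = not state
    return track


def _oscillation(amp: float, carrier_hz: float, t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Amplitude-modulated sinusoid; AM depth 30% at a slow random rate."""
    if amp == 0.0:
        return np.zeros_like(t)
    phase = rng.uniform(0, 2 * np.pi)
    am_rate = rng.uniform(0.05, 0.2)  # Hz, well below any band edge
    am_phase = rng.uniform(0, 2 * np.pi)
    envelope = 1.0 + 0.3 * np.sin(2 * np.pi * am_rate * t + am_phase)
    return amp * envelope * np.sin(2 * np.pi * carrier_hz * t + phase)


def simulate_lfp(config: LfpSimConfig) -> tuple[LfpTrace, GroundTruth]:
    """Generate one LFP trace plus its ground truth.

    Ripple placement: the number of events is Poisson with mean
    ``ripple_rate × immobile_seconds``.  Each event's centre is drawn
    uniformly over immobile samples; a draw whose full extent would cross
    a mobility boundary or overlap an already-placed event is redrawn (at
    most 100 attempts, after which the event is skipped with a warning).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    n = int(round(config.duration * fs))
    t = np.arange(n) / fs

    track = _mobility_track(rng, n, fs, config.immobility_fraction, config.mean_immobile_bout_s)

    trace = _oscillation(config.theta_amp, 8.0, t, rng)
    trace += _oscillation(config.gamma_amp, 40.0, t, rng)
    if config.line_noise_amp > 0:
        trace += config.line_noise_amp * np.sin(2 * np.pi * 60.0 * t + rng.uniform(0, 2 * np.pi))
    trace += _pink_noise(rng, n, config.pink_noise_sd, config.pink_exponent)

    events: list[tuple[float, float, float]] = []
    immobile_idx = np.flatnonzero(track)
    immobile_s = immobile_idx.size / fs
    n_events = rng.poisson(config.ripple_rate * immobile_s) if immobile_s > 0 else 0
    occupied = np.zeros(n, dtype=bool)
    for _ in range(n_events):
        placed = False
        for _attempt in range(100):
            dur_ms = rng.uniform(*config.ripple_dur_range)
            dur = int(round(dur_ms * fs / 1000.0))
            if dur < 2:
                dur = 2
            centre = int(rng.choice(immobile_idx))
            start = centre - dur // 2
            stop = start + dur
            if start < 0 or stop > n:
                continue
            if not track[start:stop].all():
                continue
            if occupied[start:stop].any():
                continue
            freq = rng.uniform(*config.ripple_freq_range)
            amp = rng.uniform(*config.ripple_amp_range)
            window = np.hanning(dur)
            burst = amp * window * np.sin(2 * np.pi * freq * (np.arange(dur) / fs))
            trace[start:stop] += burst
            occupied[start:stop] = True
            events.append((start / fs, stop / fs, float(amp)))
            placed = True
            break
        if not placed:
            log.warning("could not place a ripple after 100 attempts; skipping")
    events.sort()

    lfp = LfpTrace(
        samples=trace,
        sampling_rate=fs,
        mobility_track=track,
    )
    return lfp, GroundTruth(events=events, mobility_track=track)


# ---------------------------------------------------------------------------
# Behavior


def study_effect_profile() -> dict[tuple[str, str, str, str], float]:
    """Mean interaction seconds per (genotype, virus, drug, trial) cell.

    Encodes the qualitative result structure of the chemogenetic social
    discrimination experiments: wild types prefer novelty regardless of
    virus or drug; knockouts are flat; knockouts with the excitatory
    DREADD recover novelty preference under CNO only.
    """
    profile: dict[tuple[str, str, str, str], float] = {}
    for geno in GENOTYPES:
        for virus in VIRUSES:
            for drug in DRUGS:
                if geno == "WT":
                    n1, f, n2 = 60.0, 30.0, 55.0
                elif virus == "DREADD" and drug == "CNO":
                    n1, f, n2 = 55.0, 30.0, 50.0  # rescued KO
                else:
                    n1, f, n2 = 35.0, 33.0, 34.0  # flat KO
                profile[(geno, virus, drug, "N1")] = n1
                profile[(geno, virus, drug, "F")] = f
                profile[(geno, virus, drug, "N2")] = n2
    return profile


@dataclass
class BehaviorSimConfig:
    """Parameters of the behavioral-table simulator.

    ``effect_profile`` maps (genotype, virus, drug, trial) to the mean
    interaction time in seconds.  ``within_mouse_corr`` is the intraclass
    correlation induced by a Gaussian per-mouse random intercept; the
    total variance across rows is ``noise_sd**2``, split between the
    intercept and residual according to the correlation.  Times are
    truncated at zero.
    """

    n_per_group: int = 14
    effect_profile: dict[tuple[str, str, str, str], float] = field(
        default_factory=study_effect_profile
    )
    within_mouse_corr: float = 0.5
    noise_sd: float = 15.0
    trials: tuple[str, ...] = TRIALS
    drugs: tuple[str, ...] = DRUGS
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise InvalidConfigError("n_per_group must be at least 2")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be nonnegative")
        if not (0.0 <= self.within_mouse_corr < 1.0):
            raise InvalidConfigError("within_mouse_corr must lie in [0, 1)")
        if any(v < 0 for v in self.effect_profile.values()):
            raise InvalidConfigError("all mean interaction times must be nonnegative")


def simulate_behavior(config: BehaviorSimConfig) -> pd.DataFrame:
    """Generate a behavior table: one row per mouse × drug × trial.

    Columns: mouse_id, genotype, virus, drug, trial, interaction_time.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    icc = config.within_mouse_corr
    intercept_sd = config.noise_sd * np.sqrt(icc)
    resid_sd = config.noise_sd * np.sqrt(1.0 - icc)

    groups = sorted({(g, v) for (g, v, _, _) in config.effect_profile})
    rows = []
    for geno, virus in groups:
        for k in range(config.n_per_group):
            mouse = f"{geno}_{virus}_{k:02d}"
            intercept = rng.normal(0.0, intercept_sd)
            for drug in config.drugs:
                for trial in config.trials:
                    mean = config.effect_profile[(geno, virus, drug, trial)]
                    val = mean + intercept + rng.normal(0.0, resid_sd)
                    rows.append(
                        {
                            "mouse_id": mouse,
                            "genotype": geno,
                            "virus": virus,
                            "drug": drug,
                            "trial": trial,
                            "interaction_time": max(0.0, val),
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Image stacks


def simulate_image_stack(
    shape: tuple[int, int, int],
    background_profile: float | np.ndarray,
    roi_signal_levels: dict[str, np.ndarray | list[float] | float],
    noise_sd: float = 0.0,
    seed: int = 0,
    roi_boxes: dict[str, tuple[int, int, int, int]] | None = None,
) -> tuple[np.ndarray, dict[str, np.ndarray], dict[str, float]]:
    """Generate a z-stack with named ROI signals over a background.

    Parameters
    ----------
    shape : (n_slices, height, width)
    background_profile : scalar or (height, width) array added to every slice.
    roi_signal_levels : mapping ROI name -> per-slice signal level (scalar
        broadcast to all slices, or one value per slice).
    noise_sd : Gaussian pixel noise SD.
    seed : RNG seed.
    roi_boxes : optional mapping name -> (r0, c0, r1, c1) rectangles; when
        omitted, non-overlapping rectangles are laid out left to right.

    Returns
    -------
    stack : float ndarray, clipped at 0.
    rois : mapping name -> boolean mask (height, width).
    truth : diagnostics including the true per-ROI per-slice maxima and,
        when both "CA2" and "corpus_callosum" ROIs are present, the true
        normalized ratio ``true_ratio``.
    """
    nz, h, w = shape
    if nz < 1:
        raise InvalidConfigError("stack needs at least one slice")
    if noise_sd < 0:
        raise InvalidConfigError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    names = list(roi_signal_levels)

    if roi_boxes is None:
        # narrow interior boxes: structures much smaller than the default
        # rolling-ball radius survive background subtraction undistorted
        roi_boxes = {}
        box_w = min(12, max(2, (w - 8) // (2 * len(names))))
        gap = (w - 8 - len(names) * box_w) // max(1, len(names) - 1) if len(names) > 1 else 0
        for i, name in enumerate(names):
            c0 = 4 + i * (box_w + gap)
            roi_boxes[name] = (h // 3, c0, 2 * h // 3, c0 + box_w)

    rois: dict[str, np.ndarray] = {}
    occupied = np.zeros((h, w), dtype=bool)
    for name in names:
        r0, c0, r1, c1 = roi_boxes[name]
        mask = np.zeros((h, w), dtype=bool)
        mask[r0:r1, c0:c1] = True
        if not mask.any():
            raise InvalidConfigError(f"ROI {name!r} is empty")
        if (mask & occupied).any():
            raise InvalidConfigError(f"ROI {name!r} overlaps another ROI")
        occupied |= mask
        rois[name] = mask

    levels = {
        name: np.broadcast_to(np.asarray(lv, dtype=np.float64), (nz,)).copy()
        for name, lv in roi_signal_levels.items()
    }

    stack = np.empty((nz, h, w), dtype=np.float64)
    for z in range(nz):
        img = np.zeros((h, w)) + np.asarray(background_profile, dtype=np.float64)
        for name in names:
            img[rois[name]] += levels[name][z]
        if noise_sd > 0:
            img += rng.normal(0.0, noise_sd, size=(h, w))
        stack[z] = img
    np.clip(stack, 0.0, None, out=stack)

    truth: dict[str, float] = {f"{n}_max_level": float(levels[n].max()) for n in names}
    if "CA2" in levels and "corpus_callosum" in levels:
        cc = levels["corpus_callosum"].max()
        if cc > 0:
            truth["true_ratio"] = float(levels["CA2"].max() / cc)
    return stack, rois, truth
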