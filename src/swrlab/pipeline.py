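"""End-to-end orchestration: simulate → detect/measure → summarize → statistics.

A single :class:`RunConfig` drives the whole analysis with one global
seed.  The global seed fans out to per-stage child seeds through
``numpy.random.SeedSequence(seed).spawn``: stage *k* uses the first
32-bit word of child *k*'s state, so any stage can be re-run in
isolation from the logged effective config.  Two runs with the same
config are byte-identical on disk; the run log records every parameter
actually used (and deliberately no wall-clock timestamps).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from swrlab import behavior as beh
from swrlab import group_stats, io, spectral, swr
from swrlab.synthetic import BehaviorSimConfig, LfpSimConfig, simulate_behavior, simulate_lfp
from swrlab.types import LOW_GAMMA_BAND, THETA_BAND

#: analysis defaults, matching the study's stated constants
BASELINE_DURATION_S = 180.0  # 3-min baseline trial
SOCIAL_DURATION_S = 300.0  # 5-min social trials
FAMILIAR_WINDOW_S = 60.0  # first minute of the familiar trial


@dataclass
class RunConfig:
    """Effective configuration of one pipeline run."""

    seed: int = 0
    out_dir: str = "run_out"
    lfp: dict = field(default_factory=dict)
    behavior: dict = field(default_factory=dict)
    threshold_sd: float = swr.DEFAULT_THRESHOLD_SD
    min_duration_ms: float = swr.DEFAULT_MIN_DURATION_MS
    familiar_window_s: float = FAMILIAR_WINDOW_S
    theta_band: tuple[float, float] = THETA_BAND
    low_gamma_band: tuple[float, float] = LOW_GAMMA_BAND

    def __post_init__(self) -> None:
        # JSON round-trips lists; normalize so replayed configs log identically
        self.theta_band = tuple(self.theta_band)
        self.low_gamma_band = tuple(self.low_gamma_band)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)


def _stage_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-stage child seeds below 2**31."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % 2**31) for c in children]


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the JSON-ready summary dict.

    Outputs in ``config.out_dir``: events.csv, spectra.csv,
    swr_summary.csv, behavior.csv, behavior_scores.csv, stats.csv,
    summary.json, effective_config.json, run.log.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    seeds = _stage_seeds(config.seed, 3)
    log(f"global seed {config.seed}; stage seeds {seeds}")

    try:
        # --- stage 1: LFP simulation + SWR detection -------------------
        base_cfg = LfpSimConfig(duration=BASELINE_DURATION_S, seed=seeds[0], **config.lfp)
        fam_cfg = LfpSimConfig(duration=SOCIAL_DURATION_S, seed=seeds[1], **config.lfp)
        base_trace, _ = simulate_lfp(base_cfg)
        fam_trace, _ = simulate_lfp(fam_cfg)
        fam_trace = dataclasses.replace(fam_trace, trial="familiar")
        log(f"lfp config: {dataclasses.asdict(base_cfg)}")

        detect_kw = dict(
            threshold_sd=config.threshold_sd, min_duration_ms=config.min_duration_ms
        )
        base_events = swr.detect_swr_trace(base_trace, **detect_kw)
        fam_events = swr.detect_swr_trace(fam_trace, **detect_kw)
        io.write_events(fam_events, out / "events.csv")
        log(
            f"swr detection: threshold_sd={config.threshold_sd} "
            f"min_duration_ms={config.min_duration_ms}; "
            f"{len(base_events)} baseline events, {len(fam_events)} familiar events"
        )

        base_summary = swr.summarize_swr(
            base_events, base_trace.mobility_track, base_trace.sampling_rate,
            base_trace.duration,
        )
        fam_window = swr.window_slice(fam_events, 0.0, config.familiar_window_s)
        win_samples = int(config.familiar_window_s * fam_trace.sampling_rate)
        fam_summary = swr.summarize_swr(
            fam_window,
            fam_trace.mobility_track[:win_samples],
            fam_trace.sampling_rate,
            config.familiar_window_s,
            baseline=base_summary,
        )
        swr_rows = []
        for name, s in (("baseline", base_summary), ("familiar_min1", fam_summary)):
            swr_rows.append(
                {
                    "trial": name,
                    "count": s.count,
                    "mean_amplitude": s.mean_amplitude,
                    "mean_duration_ms": s.mean_duration_ms,
                    "mean_interval_s": s.mean_interval_s,
                    "event_frequency": s.event_frequency,
                    "immobility_time_s": s.immobility_time_s,
                    **{f"ratio_{k}": v for k, v in s.baseline_ratio.items()},
                }
            )
        pd.DataFrame(swr_rows).to_csv(out / "swr_summary.csv", index=False)

        # --- stage 2: spectra + band powers ----------------------------
        base_spec = spectral.normalized_spectrum(spectral.preprocess(base_trace))
        fam_spec = spectral.normalized_spectrum(spectral.preprocess(fam_trace))
        io.write_spectrum(fam_spec, out / "spectra.csv")
        band_rows = []
        for label, (lo, hi) in (
            ("theta", config.theta_band),
            ("low_gamma", config.low_gamma_band),
        ):
            bp_base = spectral.band_power(base_spec, lo, hi, label)
            bp_fam = spectral.band_power(fam_spec, lo, hi, label)
            band_rows.append(
                {
                    "band": label,
                    "lo_hz": lo,
                    "hi_hz": hi,
                    "baseline_power": bp_base.power,
                    "session_power": bp_fam.power,
                    "baseline_ratio": spectral.baseline_normalize(bp_fam, bp_base),
                }
            )
        band_df = pd.DataFrame(band_rows)
        band_df.to_csv(out / "band_power.csv", index=False)
        log(f"bands: theta={config.theta_band} low_gamma={config.low_gamma_band}")

        # --- stage 3: behavior + statistics ----------------------------
        beh_cfg = BehaviorSimConfig(seed=seeds[2], **config.behavior)
        table = simulate_behavior(beh_cfg)
        io.write_behavior(table, out / "behavior.csv")
        scores = beh.difference_scores(table)
        scores.to_csv(out / "behavior_scores.csv", index=False)
        nf = table[table["trial"].isin(["N1", "F"])]
        stats = group_stats.fit_factorial(
            nf,
            "interaction_time",
            between=["genotype", "virus", "drug"],
            within=["trial"],
            subject="mouse_id",
        )
        stats.to_csv(out / "stats.csv", index=False)
        log(f"behavior config: n_per_group={beh_cfg.n_per_group} noise_sd={beh_cfg.noise_sd}")
    except Exception as exc:  # attribute the failing stage
        raise RuntimeError(f"pipeline aborted: {exc}") from exc

    summary = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "swr": swr_rows,
        "band_power": band_rows,
        "behavior_groups": scores.groupby(["genotype", "virus", "drug"])  # noqa: PD008
        ["novelty_score"].mean().round(6).to_dict(),
    }
    summary["behavior_groups"] = {
        "/".join(k): v for k, v in summary["behavior_groups"].items()
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    eff = dataclasses.asdict(config)
    (out / "effective_config.json").write_text(json.dumps(eff, indent=1, sort_keys=True))
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary
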