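"""End-to-end validation studies run against the synthetic-data oracles.

Each function here executes one self-contained recovery study — detector
precision/recall against ground truth, behavioral effect-sign recovery,
type-I calibration and power of the factorial engine, histology ratio
recovery, pipeline determinism — and returns plain numbers.  They are
used both by the test suite and by ``scripts/acceptance.py``.

All randomness is derived from the ``seed`` argument via
``numpy.random.SeedSequence`` so studies are reproducible and mutually
independent.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from swrlab import behavior as beh
from swrlab import group_stats as gs
from swrlab import histology, spectral, swr
from swrlab.synthetic import (
    BehaviorSimConfig,
    LfpSimConfig,
    simulate_behavior,
    simulate_image_stack,
    simulate_lfp,
    study_effect_profile,
)
from swrlab.types import LfpTrace


def _child_seeds(seed: int, n: int) -> list[int]:
    return [
        int(s.generate_state(1)[0] % 2**31)
        for s in np.random.SeedSequence(seed).spawn(n)
    ]


# ---------------------------------------------------------------------------
# printed-summary statistics


def immobility_t() -> gs.TestResult:
    """Pooled t from the published immobility summaries (WT vs KO).

    Means 100.8 / 184.8 s, SEMs 10.18 / 10.29, n = 10 + 9.
    """
    wt = gs.GroupSummary(mean=100.8, sem=10.18, n=10)
    ko = gs.GroupSummary(mean=184.8, sem=10.29, n=9)
    return gs.t_from_summaries(wt, ko, variant="pooled")


def colabel_check() -> tuple[float, float]:
    """Co-label percentages for a 2:1 PCP4:mCherry population at 91% overlap.

    With 100 mCherry+ cells of which 91 are PCP4+ in a 182-cell PCP4
    population, 91% of mCherry+ cells are PCP4+ and 50% of PCP4+ cells
    are mCherry+.
    """
    pct_mcherry_among_pcp4, pct_pcp4_among_mcherry = histology.colabel_fractions(
        100, 182, 91
    )
    return pct_pcp4_among_mcherry, pct_mcherry_among_pcp4


# ---------------------------------------------------------------------------
# spectral normalization


def spectral_normalization_study(n_traces: int = 100, seed: int = 0) -> dict[str, float]:
    """Unit-sum check over fuzzed traces plus noiseless theta purity.

    Returns the worst |sum - 1| over ``n_traces`` random traces and the
    theta (4-12 Hz) band power of a noiseless theta-only simulation.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_traces):
        n = int(rng.integers(2_000, 10_000))
        fs = float(rng.choice([1000.0, 1250.0, 2000.0]))
        x = rng.normal(scale=rng.uniform(0.5, 200.0), size=n)
        if rng.random() < 0.5:
            f0 = rng.uniform(1.0, 90.0)
            x += rng.uniform(5, 100) * np.sin(2 * np.pi * f0 * np.arange(n) / fs)
        spec = spectral.normalized_spectrum(
            spectral.preprocess(LfpTrace(samples=x, sampling_rate=fs))
        )
        worst = max(worst, abs(spec.power.sum() - 1.0))

    theta_cfg = LfpSimConfig(
        duration=60.0, theta_amp=40.0, gamma_amp=0.0, pink_noise_sd=0.0,
        line_noise_amp=0.0, ripple_rate=0.0, seed=seed,
    )
    trace, _ = simulate_lfp(theta_cfg)
    spec = spectral.normalized_spectrum(spectral.preprocess(trace))
    theta_power = spectral.band_power(spec, 4.0, 12.0).power
    return {"max_sum_deviation": worst, "theta_only_band_power": theta_power}


# ---------------------------------------------------------------------------
# ripple detector oracle


def envelope_noise_sd_uv(config: LfpSimConfig) -> float:
    """Ripple-band envelope SD (µV) of the config's ripple-free noise floor."""
    quiet = dataclasses.replace(config, ripple_rate=0.0)
    trace, _ = simulate_lfp(quiet)
    filtered = spectral.band_filter(spectral.notch_60(trace), 150.0, 250.0)
    from scipy.signal import hilbert

    return float(np.abs(hilbert(filtered.samples)).std())


def swr_detection_study(n_trials: int = 20, seed: int = 0) -> dict[str, float]:
    """Detector precision/recall over simulated 5-min trials.

    Trials use the generator defaults: ripple durations 25-80 ms, rate
    0.2 events per immobility-second, amplitudes 25-50 µV over a noise
    floor whose ripple-band envelope SD is ~2 µV, i.e. every ripple is
    at least 5x the envelope noise SD.  Also verifies that 10 ms bursts
    injected at 10x the envelope noise SD are never detected (the
    duration gate; see the methods note for the amplitude regime where
    band-limit stretching bounds this check), and that raising the
    threshold never raises the count.
    """
    seeds = _child_seeds(seed, n_trials)
    tp = fp = fn = 0
    short_detected = 0
    monotone_ok = True
    min_amp_ratio = np.inf
    for k, s in enumerate(seeds):
        cfg = LfpSimConfig(duration=300.0, seed=s)
        trace, truth = simulate_lfp(cfg)
        if k == 0:
            noise_sd = envelope_noise_sd_uv(cfg)
            min_amp_ratio = cfg.ripple_amp_range[0] / noise_sd
        events = swr.detect_swr_trace(trace)
        a, b, c = swr.match_events(events, truth.events)
        tp, fp, fn = tp + a, fp + b, fn + c

        if k < 5:
            # same noise, only sub-duration bursts: none may survive the gate
            quiet_cfg = dataclasses.replace(cfg, ripple_rate=0.0)
            qtrace, _ = simulate_lfp(quiet_cfg)
            x = qtrace.samples.copy()
            rng = np.random.default_rng(s)
            fs = qtrace.sampling_rate
            immobile = np.flatnonzero(qtrace.mobility_track)
            centers = rng.choice(immobile[(immobile > 1000) & (immobile < x.size - 1000)], 5)
            bursts = []
            for c0 in centers:
                dur = int(0.010 * fs)
                t = np.arange(dur) / fs
                amp = 10.0 * noise_sd
                x[c0 : c0 + dur] += amp * np.hanning(dur) * np.sin(2 * np.pi * 200.0 * t)
                bursts.append((c0 / fs, (c0 + dur) / fs, amp))
            found = swr.detect_swr_trace(dataclasses.replace(qtrace, samples=x))
            hit, _, _ = swr.match_events(found, bursts)
            short_detected += hit
        if k == 0:
            env = swr.ripple_envelope(trace)
            counts = [
                len(swr.detect_swr(env, trace.sampling_rate, threshold_sd=t))
                for t in (2.0, 3.0, 4.0, 5.0)
            ]
            monotone_ok = counts == sorted(counts, reverse=True)
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    return {
        "precision": precision,
        "recall": recall,
        "n_true_events": tp + fn,
        "short_burst_detections": short_detected,
        "threshold_monotone": float(monotone_ok),
        "min_amp_over_noise_sd": float(min_amp_ratio),
    }


# ---------------------------------------------------------------------------
# behavioral effect recovery


def behavior_sign_recovery(
    n_reps: int = 200, n_per_group: int = 14, seed: int = 0
) -> float:
    """Fraction of replicates with sign-correct group mean difference scores.

    The designed profile has wild types preferring novelty under every
    virus/drug, knockouts flat, and DREADD-injected knockouts rescued by
    CNO.  A replicate counts as sign-correct when every WT cell and the
    rescued KO cell have positive mean novelty scores, and the
    (untreated) KO control cell scores below the WT control cell.
    """
    seeds = _child_seeds(seed, n_reps)
    ok = 0
    for s in seeds:
        cfg = BehaviorSimConfig(n_per_group=n_per_group, seed=s)
        scores = beh.difference_scores(simulate_behavior(cfg))
        cell = scores.groupby(["genotype", "virus", "drug"])["novelty_score"].mean()
        wt_pos = all(
            cell[("WT", v, d)] > 0 for v in ("control", "DREADD") for d in ("VEH", "CNO")
        )
        rescue_pos = cell[("KO", "DREADD", "CNO")] > 0
        ko_below_wt = cell[("KO", "control", "VEH")] < cell[("WT", "control", "VEH")]
        ok += wt_pos and rescue_pos and ko_below_wt
    return ok / n_reps


def _null_profile(value: float = 40.0) -> dict:
    return {k: value for k in study_effect_profile()}


def factorial_type_i_study(n_reps: int = 1000, n_per_group: int = 10, seed: int = 0) -> dict[str, float]:
    """Term-wise type-I error of the mixed-design engine under the null.

    Genotype (between) x trial (within) with no true effects; returns the
    rejection rate at alpha = 0.05 for each term.
    """
    seeds = _child_seeds(seed, n_reps)
    rates: dict[str, int] = {}
    for s in seeds:
        cfg = BehaviorSimConfig(
            n_per_group=n_per_group, effect_profile=_null_profile(),
            noise_sd=15.0, trials=("N1", "F"), drugs=("VEH",), seed=s,
        )
        table = simulate_behavior(cfg)
        sub = table[table.virus == "control"]
        res = gs.fit_factorial(
            sub, "interaction_time", between=["genotype"], within=["trial"],
            subject="mouse_id",
        )
        for row in res.itertuples():
            rates[row.term] = rates.get(row.term, 0) + (row.p < 0.05)
    return {term: count / n_reps for term, count in rates.items()}


def interaction_power_study(
    n_reps: int = 200, n_per_group: int = 13, effect_s: float = 40.0,
    noise_sd: float = 20.0, seed: int = 0,
) -> float:
    """Power to detect a genotype x trial interaction of ``effect_s`` seconds.

    Wild types drop by ``effect_s`` from novel to familiar; knockouts are
    flat.  Returns the fraction of replicates with interaction p < 0.05.
    """
    profile = {}
    for v in ("control", "DREADD"):
        for d in ("VEH", "CNO"):
            profile[("WT", v, d, "N1")], profile[("WT", v, d, "F")] = 60.0, 60.0 - effect_s
            profile[("KO", v, d, "N1")], profile[("KO", v, d, "F")] = 40.0, 40.0
    seeds = _child_seeds(seed, n_reps)
    hits = 0
    for s in seeds:
        cfg = BehaviorSimConfig(
            n_per_group=n_per_group, effect_profile=profile, noise_sd=noise_sd,
            trials=("N1", "F"), drugs=("VEH",), seed=s,
        )
        table = simulate_behavior(cfg)
        sub = table[table.virus == "control"]
        res = gs.fit_factorial(
            sub, "interaction_time", between=["genotype"], within=["trial"],
            subject="mouse_id",
        )
        p = res.loc[res.term == "genotype:trial", "p"].iloc[0]
        hits += p < 0.05
    return hits / n_reps


# ---------------------------------------------------------------------------
# histology recovery


def histology_recovery_study(n_seeds: int = 20, seed: int = 0) -> dict[str, float]:
    """CA2/corpus-callosum ratio recovery at SNR 10, true ratio 2.0.

    Peak slice signal 40 over a flat background of 10 with pixel noise
    SD 4 (SNR 10); reference at half the signal.  Returns the worst
    relative error and the mean recovered ratio over ``n_seeds`` stacks.
    """
    levels = {"CA2": [36.0, 40.0, 38.0], "corpus_callosum": [18.0, 20.0, 19.0]}
    seeds = _child_seeds(seed, n_seeds)
    ratios = []
    for s in seeds:
        stack, rois, truth = simulate_image_stack(
            (3, 96, 96), 10.0, levels, noise_sd=4.0, seed=s
        )
        sub = histology.rolling_ball_subtract(stack, 50.0)
        ca2 = histology.roi_stack_intensity(sub, rois["CA2"])
        cc = histology.roi_stack_intensity(sub, rois["corpus_callosum"])
        ratios.append(ca2 / cc)
    ratios = np.asarray(ratios)
    return {
        "max_rel_error": float(np.abs(ratios / 2.0 - 1.0).max()),
        "mean_ratio": float(ratios.mean()),
    }


# ---------------------------------------------------------------------------
# pipeline determinism


def pipeline_determinism_study(out_dir, seed: int = 0) -> bool:
    """Run the full pipeline twice with one seed; True if byte-identical."""
    from pathlib import Path

    from swrlab.pipeline import RunConfig, run

    out = Path(out_dir)
    cfg = RunConfig(seed=seed, out_dir=str(out))
    run(cfg)
    first = {p.name: p.read_bytes() for p in out.iterdir() if p.is_file()}
    run(cfg)
    second = {p.name: p.read_bytes() for p in out.iterdir() if p.is_file()}
    return first == second
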