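"""Synthetic experiments with known ground truth.

Generates complete cursor-perturbation reaching datasets — model-driven
2-D kinematics upsampled to 1 kHz plus EMG-like signals — shaped like the
experiments the analysis pipeline expects: the same trial types and counts
(400 trials per participant in the experiment-1 layout, 250 in
experiment 2), per-trial display latencies (43.4 +/- 0.9 ms total), tonic
background-load-dependent muscle activity with planted disturbance-response
kernels at known latencies and amplitudes, and planted outlier trials for
the exclusion rules.  Every generated trial carries a complete
ground-truth record, so parameter recovery by the pipeline can be checked
exactly.

EMG synthesis is deliberately phenomenological, not biophysical: a
band-limited (25-250 Hz) Gaussian carrier is amplitude-modulated by
``tonic x (1 + response kernel)``, which exercises the band-pass /
rectify / low-pass chain the pipeline assumes.  The response kernel is a
log-normal-shaped burst (~20 ms rise, ~60 ms decay by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

from .conditions import sigmoid_offset
from .emg import AGONIST_LOAD, CHANNELS, DISPLAY_REFRESH_S, EmgTrial

__all__ = ["SynthConfig", "EXPERIMENT_COUNTS", "gen_kinematics", "gen_emg",
           "gen_trial", "gen_experiment", "onset_recovery_study",
           "exclusion_recovery_study"]

# per-participant trial counts per condition
EXPERIMENT_COUNTS = {
    1: {"baseline_v": 150, "baseline_nov": 100, "P_nov": 50,
        "V_shift": 50, "PV_align": 50},
    2: {"baseline_v": 150, "PV_align": 50, "PV_conflict": 50},
}


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults mirror the experimental protocol."""

    n_participants: int = 13
    experiment: int = 1
    counts: dict | None = None          # override EXPERIMENT_COUNTS
    fs: float = 1000.0
    prep_duration_s: float = 0.100      # hold period before movement onset

    # planted response kernel (log-normal burst, peak normalized to 1)
    prop_latency_s: float = 0.050
    vis_latency_s: float = 0.090
    # log-normal burst rising over ~20 ms (peak at 30 ms) and decaying
    # over ~60 ms (half-amplitude ~57 ms)
    kernel_peak_s: float = 0.030
    kernel_width: float = 0.55
    mech_amplitude: float = 3.0         # normalized units, agonist excitation
    vis_amplitude: float = 0.8
    inhibition_fraction: float = 0.5    # antagonist response = -frac * amplitude

    tonic_agonist: float = 1.0          # arbitrary raw units before normalization
    tonic_antagonist: float = 0.3
    emg_floor: float = 0.05             # envelope floor (full inhibition > 0)

    kin_noise_m: float = 0.0003         # kinematic measurement noise SD

    # display latency: logged video-card latency + fixed 17 ms refresh
    latency_mean_s: float = 0.04339 - DISPLAY_REFRESH_S
    latency_sd_s: float = 0.00086

    # planted outliers per participant (drawn over all trials)
    n_prep_outliers: int = 2
    prep_outlier_factor: float = 3.0
    n_spike_outliers: int = 2
    spike_factor: float = 20.0

    def __post_init__(self):
        if self.n_participants < 0:
            raise ValueError("n_participants must be >= 0")
        if self.experiment not in EXPERIMENT_COUNTS and self.counts is None:
            raise ValueError("experiment must be 1 or 2 (or counts given)")
        for name in ("prop_latency_s", "vis_latency_s", "latency_mean_s",
                     "latency_sd_s", "kernel_peak_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def condition_counts(self) -> dict:
        return dict(self.counts or EXPERIMENT_COUNTS[self.experiment])


def _kernel(t: np.ndarray, cfg: SynthConfig) -> np.ndarray:
    """Log-normal burst, zero for t <= 0, unit peak at ``kernel_peak_s``."""
    out = np.zeros_like(t)
    pos = t > 0
    out[pos] = np.exp(
        -0.5 * (np.log(t[pos] / cfg.kernel_peak_s) / cfg.kernel_width) ** 2
    )
    return out


def _bandlimited_carrier(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    sos = signal.butter(3, [25.0 / (fs / 2), 250.0 / (fs / 2)],
                        btype="bandpass", output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def gen_kinematics(results, condition, cfg: SynthConfig, seed, *,
                   dynamics_noise: bool = True) -> dict:
    """One trial's 1 kHz 2-D kinematics from the model simulator.

    Simulates the lateral and forward axes at the model's 10 ms grid (with
    the condition's disturbance/override on the lateral axis), interpolates
    to 1 kHz with a cubic spline, prepends the hold period, and adds
    measurement noise.  The cursor follows the hand except for the
    condition's cursor manipulation (sigmoid shift, or removal from the
    3 cm event).  Returns the kinematic arrays plus event times.
    """
    rng = np.random.default_rng(seed)
    fac = results.conditions()
    if isinstance(condition, str):
        condition = fac.make(condition)
    pcfg = results.model.config
    fwd = fac.forward_results

    lat = results.simulate(condition, n_trials=1,
                           seed=int(rng.integers(2 ** 31)),
                           noise=dynamics_noise)
    fsim = fwd.simulate(n_trials=1, seed=int(rng.integers(2 ** 31)),
                        noise=dynamics_noise)

    t_model = lat["time"]
    n_prep = int(round(cfg.prep_duration_s * cfg.fs))
    t_fine = np.arange(0.0, t_model[-1] + 0.5 / cfg.fs, 1.0 / cfg.fs)

    def up(series):
        return CubicSpline(t_model, series[:, 0])(t_fine)

    hand_x, hand_y = up(lat["h"]), up(fsim["h"])
    onset_s = cfg.prep_duration_s + condition.onset_step * pcfg.dt
    latency = float(rng.normal(cfg.latency_mean_s, cfg.latency_sd_s))
    vis_onset_s = onset_s + latency + DISPLAY_REFRESH_S

    # displayed cursor on the fine grid
    cursor_x, cursor_y = hand_x.copy(), hand_y.copy()
    cursor_off_s = None
    tt = t_fine - (onset_s - cfg.prep_duration_s)  # time since disturbance
    if condition.trial_type in ("baseline_nov", "P_nov"):
        cursor_off_s = onset_s
        off_i = np.searchsorted(t_fine, condition.onset_step * pcfg.dt)
        cursor_x[off_i:] = cursor_x[max(off_i - 1, 0)]
        cursor_y[off_i:] = cursor_y[max(off_i - 1, 0)]
    elif condition.trial_type == "V_shift":
        params = fac.sigmoid_params
        if condition.direction != 1:
            params = replace(params, a=condition.direction * params.a)
        cursor_x = hand_x + np.where(tt >= 0, sigmoid_offset(tt, params), 0.0)
    elif condition.trial_type == "PV_conflict":
        params = fac.sigmoid_params
        if condition.direction != 1:
            params = replace(params, a=condition.direction * params.a)
        cursor_x = hand_x + np.where(
            tt >= 0, sigmoid_offset(tt, params, conflict=True), 0.0)

    def with_prep(x):
        full = np.concatenate([np.full(n_prep, x[0]), x])
        return full + cfg.kin_noise_m * rng.standard_normal(full.size)

    time = np.arange(n_prep + t_fine.size) / cfg.fs
    events = {
        "onset_s": onset_s,
        "latency_s": latency,
        "visual_onset_s": vis_onset_s,
    }
    if cursor_off_s is not None:
        events["cursor_off_s"] = cursor_off_s
    return {
        "time": time,
        "hand_x": with_prep(hand_x), "hand_y": with_prep(hand_y),
        "cursor_x": with_prep(cursor_x), "cursor_y": with_prep(cursor_y),
        "events": events,
    }


def gen_emg(cfg: SynthConfig, truth: dict, n: int, seed) -> dict:
    """Four-channel raw EMG from a ground-truth record.

    Each channel is an amplitude-modulated band-limited carrier:
    ``tonic x (1 + response)`` where the response is the planted kernel at
    the trial's ground-truth onset, excitatory for agonist channels and
    inhibitory (clipped at the envelope floor) for antagonists.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(n) / cfg.fs
    emg = {}
    for ch in CHANNELS:
        agonist = AGONIST_LOAD[ch] == truth["load_sign"]
        tonic = cfg.tonic_agonist if agonist else cfg.tonic_antagonist
        response = np.zeros(n)
        if truth.get("response_onset_s") is not None:
            amp = truth["response_amplitude"]
            sign = 1.0 if agonist else -cfg.inhibition_fraction
            response = sign * amp * _kernel(t - truth["response_onset_s"], cfg)
        envelope = np.maximum(tonic * (1.0 + response), cfg.emg_floor * tonic)
        if truth.get("prep_outlier"):
            envelope = envelope * cfg.prep_outlier_factor
        x = envelope * np.abs(_bandlimited_carrier(n, cfg.fs, rng))
        if truth.get("spike_outlier"):
            j = int(round(truth["onset_s"] * cfg.fs))
            x[j:j + 3] += cfg.spike_factor * tonic
        emg[ch] = x
    return emg


def gen_trial(results, cfg: SynthConfig, participant: str, trial_type: str,
              direction: int, seed) -> tuple[EmgTrial, dict]:
    """One synthetic trial plus its ground-truth record."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    kin_seed, emg_seed = ss.spawn(2)
    spec = results.conditions().make(trial_type, direction=direction)
    kin = gen_kinematics(results, spec, cfg, kin_seed)
    events = kin.pop("events")
    load_sign = "flexor" if direction > 0 else "extensor"

    if trial_type in ("P_nov", "PV_align", "PV_conflict"):
        onset = events["onset_s"] + cfg.prop_latency_s
        amp = cfg.mech_amplitude
    elif trial_type == "V_shift":
        onset = events["visual_onset_s"] + cfg.vis_latency_s
        amp = cfg.vis_amplitude
    else:
        onset, amp = None, 0.0

    truth = {
        "participant": participant,
        "condition": trial_type,
        "load_sign": load_sign,
        "direction": direction,
        "onset_s": events["onset_s"],
        "latency_s": events["latency_s"],
        "visual_onset_s": events["visual_onset_s"],
        "response_onset_s": onset,
        "response_amplitude": amp,
        "prep_outlier": False,
        "spike_outlier": False,
        "excluded": False,
    }
    time = kin.pop("time")
    emg = gen_emg(cfg, truth, time.size, emg_seed)
    trial = EmgTrial(
        participant=participant, condition=trial_type, load_sign=load_sign,
        time=time, emg=emg, kin=kin, events=events,
    )
    return trial, truth


def gen_experiment(results, cfg: SynthConfig, seed: int,
                   out_dir=None) -> tuple[list[EmgTrial], list[dict]]:
    """Full synthetic experiment: all trial types, counts, outliers.

    Trial counts follow the experiment layout (split evenly between flexor
    and extensor background loads); planted outliers are assigned to
    randomly chosen trials per participant.  With ``out_dir`` the dataset
    is also written to text files (see :mod:`dynreach.io`).
    """
    root = np.random.SeedSequence(seed)
    counts = cfg.condition_counts()
    trials: list[EmgTrial] = []
    truths: list[dict] = []
    part_seeds = root.spawn(max(cfg.n_participants, 1))
    for pi in range(cfg.n_participants):
        pseq = part_seeds[pi]
        prng = np.random.default_rng(pseq)
        plan = []
        for trial_type, count in counts.items():
            for j in range(count):
                direction = 1 if j % 2 == 0 else -1
                plan.append((trial_type, direction))
        trial_seeds = pseq.spawn(len(plan))
        p_trials, p_truths = [], []
        for (trial_type, direction), tseed in zip(plan, trial_seeds):
            tr, truth = gen_trial(results, cfg, f"S{pi + 1:02d}",
                                  trial_type, direction, tseed)
            p_trials.append(tr)
            p_truths.append(truth)
        n_tr = len(p_trials)
        n_out = min(cfg.n_prep_outliers + cfg.n_spike_outliers, n_tr)
        chosen = prng.choice(n_tr, size=n_out, replace=False) if n_out else []
        for k, idx in enumerate(chosen):
            key = "prep_outlier" if k < cfg.n_prep_outliers else "spike_outlier"
            truth = dict(p_truths[idx], **{key: True, "excluded": True})
            tr = p_trials[idx]
            regen_seed = pseq.spawn(1)[0]
            emg = gen_emg(cfg, truth, tr.time.size, regen_seed)
            p_trials[idx] = replace(tr, emg=emg)
            p_truths[idx] = truth
        trials.extend(p_trials)
        truths.extend(p_truths)
    if out_dir is not None:
        from .io import write_experiment

        write_experiment(trials, truths, out_dir)
    return trials, truths


# ---------------------------------------------------------------------------
# recovery studies: the generator's ground truth against the pipeline

def _study_group(cfg: SynthConfig, load_sign: str, channel: str,
                 n_trials: int, n: int, onset_s: float | None,
                 amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Raw EMG matrix (n_trials, n) for one load group (vectorized)."""
    from scipy import signal as sig

    t = np.arange(n) / cfg.fs
    agonist = AGONIST_LOAD[channel] == load_sign
    tonic = cfg.tonic_agonist if agonist else cfg.tonic_antagonist
    response = np.zeros(n)
    if onset_s is not None:
        sign = 1.0 if agonist else -cfg.inhibition_fraction
        response = sign * amplitude * _kernel(t - onset_s, cfg)
    envelope = np.maximum(tonic * (1.0 + response), cfg.emg_floor * tonic)
    sos = sig.butter(3, [25.0 / (cfg.fs / 2), 250.0 / (cfg.fs / 2)],
                     btype="bandpass", output="sos")
    carrier = sig.sosfilt(sos, rng.standard_normal((n_trials, n)), axis=-1)
    carrier /= carrier.std(axis=-1, keepdims=True)
    return envelope[None, :] * np.abs(carrier)


def onset_recovery_study(
    *,
    n_seeds: int = 50,
    n_participants: int = 13,
    trials_per_group: int = 25,
    baselines_per_load: int = 25,
    onset_range_s: tuple[float, float] = (0.080, 0.150),
    amplitude: float = 3.0,
    channel: str = "DP",
    cfg: SynthConfig | None = None,
    seed: int = 0,
):
    """End-to-end planted-onset recovery through the EMG analysis chain.

    For each seed, a response kernel with a known onset (drawn uniformly
    over ``onset_range_s`` after the disturbance) is planted under both
    background loads at the experimental trial counts (25 disturbance
    trials per direction); the trials run through the zero-lag filter
    chain, preparation-window normalization and baseline subtraction, and
    the ROC onset detector operates on per-participant average traces.
    Generation and filtering are vectorized across trials (the filters are
    applied along the time axis exactly as in the per-trial pipeline).
    Returns a DataFrame of planted and detected onsets (ms, relative to
    the disturbance).
    """
    import pandas as pd

    from .emg import detect_onset, filter_emg, roc_series

    cfg = cfg or SynthConfig()
    n = 500  # 100 ms pre + 400 ms post disturbance at 1 kHz
    prep = slice(0, int(round(0.100 * cfg.fs)))
    rows = []
    root = np.random.SeedSequence(seed)
    for s, seq in enumerate(root.spawn(n_seeds)):
        rng = np.random.default_rng(seq)
        planted = rng.uniform(*onset_range_s)
        group_means = {"flexor": [], "extensor": []}
        for _ in range(n_participants):
            base = {load: filter_emg(_study_group(
                cfg, load, channel, baselines_per_load, n, None, 0.0, rng))
                for load in ("flexor", "extensor")}
            # normalize by the agonist-load preparatory activity, as the
            # pipeline does, for trials under both loads
            const = base[AGONIST_LOAD[channel]][:, prep].mean()
            for load in ("flexor", "extensor"):
                dist = filter_emg(_study_group(
                    cfg, load, channel, trials_per_group, n,
                    0.100 + planted, amplitude, rng))
                delta = (dist - base[load].mean(axis=0)[None, :]) / const
                group_means[load].append(delta.mean(axis=0))
        group_means = {k: np.vstack(v) for k, v in group_means.items()}
        auc = roc_series(group_means["flexor"], group_means["extensor"])
        res = detect_onset(auc, fs=cfg.fs)
        detected = (res.onset_time - 0.100) * 1000.0 if res.detected else np.nan
        rows.append({
            "seed": s,
            "planted_ms": planted * 1000.0,
            "detected_ms": detected,
            "error_ms": detected - planted * 1000.0,
            "detected": res.detected,
        })
    return pd.DataFrame(rows)


def exclusion_recovery_study(
    results,
    *,
    n_participants: int = 4,
    cfg: SynthConfig | None = None,
    seed: int = 0,
) -> dict:
    """Planted-outlier recovery: sensitivity and false-flag rate.

    Generates a scaled synthetic experiment with planted preparatory and
    onset-spike outliers, runs the exclusion rules, and scores trial-level
    detection (a trial counts as excluded if any channel flags it).
    """
    from .emg import exclude_trials, preprocess_trial

    cfg = cfg or SynthConfig(
        n_participants=n_participants,
        counts={"baseline_v": 16, "baseline_nov": 8, "P_nov": 8,
                "V_shift": 8, "PV_align": 8},
        n_prep_outliers=2, n_spike_outliers=2,
    )
    trials, truths = gen_experiment(results, cfg, seed)
    flags = exclude_trials([preprocess_trial(t) for t in trials])
    flagged = flags[flags.excluded].groupby("trial").size().index
    flagged_trials = set(int(i) for i in flagged)
    planted = {i for i, t in enumerate(truths) if t["excluded"]}
    clean = set(range(len(trials))) - planted
    tp = len(planted & flagged_trials)
    fp = len(flagged_trials - planted)
    return {
        "n_trials": len(trials),
        "n_planted": len(planted),
        "sensitivity": tp / len(planted) if planted else float("nan"),
        "false_flag_rate": fp / len(clean) if clean else float("nan"),
    }
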