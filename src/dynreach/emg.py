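"""EMG/kinematics preprocessing and response quantification.

Implements the experimental analysis chain for 1 kHz recordings from four
upper-limb muscles (posterior deltoid DP, pectoralis major PM, lateral
triceps TLAT, brachioradialis BR):

1. zero-lag Butterworth filtering (EMG: 25-250 Hz band-pass, full-wave
   rectification, 50 Hz low-pass; kinematics: 20 Hz low-pass);
2. normalization of each muscle to its mean activity over a 100 ms
   preparation window on trials where it counters the background load;
3. baseline subtraction (dEMG) against the vision- and load-matched
   baseline average;
4. trial exclusion (abnormal preparatory activity; onset motion artifacts);
5. display-latency correction for visual-alignment analyses;
6. scaling of visual-only responses by the PV/V cursor-shift ratio;
7. ROC-based onset detection on per-participant average traces.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.metrics import roc_auc_score

__all__ = [
    "CHANNELS",
    "AGONIST_LOAD",
    "FS",
    "DISPLAY_REFRESH_S",
    "EmgTrial",
    "OnsetResult",
    "filter_emg",
    "filter_kinematics",
    "preprocess_trial",
    "normalization_constants",
    "normalize_and_delta",
    "exclude_trials",
    "align_visual",
    "scale_visual_response",
    "roc_series",
    "detect_onset",
    "aligned_matrix",
    "participant_means",
    "emg_epoch_table",
    "direction_onset",
]

FS = 1000.0
CHANNELS = ("DP", "PM", "TLAT", "BR")
# Background-load sign under which each muscle is the agonist (it actively
# counters the load): shoulder/elbow extensor loads pre-load DP and TLAT,
# flexor loads pre-load PM and BR.
AGONIST_LOAD = {"DP": "extensor", "TLAT": "extensor", "PM": "flexor", "BR": "flexor"}
DISPLAY_REFRESH_S = 0.017  # fixed refresh-cycle contribution to display latency

_EMG_BAND = (25.0, 250.0)
_EMG_LOWPASS = 50.0
_KIN_LOWPASS = 20.0
_FILTER_ORDER = 6
_PREP_WINDOW = (0.0, 0.100)  # s, preparation period at the start of the record


@dataclass
class EmgTrial:
    """One trial's 1 kHz EMG channels, kinematics and event metadata.

    ``events`` must carry ``onset_s`` (mechanical-disturbance command time
    on the trial clock) and, for visual-alignment analyses, ``latency_s``
    (logged display latency).
    """

    participant: str
    condition: str
    load_sign: str
    time: np.ndarray
    emg: dict = field(default_factory=dict)
    kin: dict = field(default_factory=dict)
    events: dict = field(default_factory=dict)

    def __post_init__(self):
        lengths = {len(v) for v in self.emg.values()}
        lengths |= {len(v) for v in self.kin.values()}
        lengths.add(len(self.time))
        if len(lengths) > 1:
            raise ValueError("all trial series must share one length")

    @property
    def fs(self) -> float:
        if len(self.time) > 1:
            return 1.0 / float(self.time[1] - self.time[0])
        return FS

    @property
    def has_vision(self) -> bool:
        return self.condition not in ("baseline_nov", "P_nov")


def _zero_lag_sosfiltfilt(sos: np.ndarray, x: np.ndarray, order: int) -> np.ndarray:
    # reflective padding of 3x the filter order before forward-backward pass
    padlen = min(3 * order, x.shape[-1] - 1)
    return signal.sosfiltfilt(sos, x, padtype="even", padlen=padlen)


def filter_emg(raw: np.ndarray, fs: float = FS) -> np.ndarray:
    """Band-pass (25-250 Hz), rectify, low-pass (50 Hz), all zero-lag.

    Both filters are 6th-order Butterworth applied forward-backward.  The
    final low-pass can introduce small negative values around sharp
    transients; these are retained (baseline subtraction follows).
    """
    raw = np.asarray(raw, dtype=float)
    if raw.shape[-1] <= 3 * _FILTER_ORDER:
        raise ValueError("series shorter than the filter warm-up requirement")
    nyq = fs / 2.0
    sos_bp = signal.butter(_FILTER_ORDER // 2,
                           [_EMG_BAND[0] / nyq, _EMG_BAND[1] / nyq],
                           btype="bandpass", output="sos")
    sos_lp = signal.butter(_FILTER_ORDER, _EMG_LOWPASS / nyq,
                           btype="lowpass", output="sos")
    x = _zero_lag_sosfiltfilt(sos_bp, raw, _FILTER_ORDER)
    x = np.abs(x)
    return _zero_lag_sosfiltfilt(sos_lp, x, _FILTER_ORDER)


def filter_kinematics(raw: np.ndarray, fs: float = FS) -> np.ndarray:
    """Zero-lag 6th-order 20 Hz Butterworth low-pass."""
    raw = np.asarray(raw, dtype=float)
    if raw.shape[-1] <= 3 * _FILTER_ORDER:
        raise ValueError("series shorter than the filter warm-up requirement")
    sos = signal.butter(_FILTER_ORDER, _KIN_LOWPASS / (fs / 2.0),
                        btype="lowpass", output="sos")
    return _zero_lag_sosfiltfilt(sos, raw, _FILTER_ORDER)


def preprocess_trial(trial: EmgTrial) -> EmgTrial:
    """Filtered copy of a trial (EMG chain on channels, low-pass on kinematics)."""
    return replace(
        trial,
        emg={ch: filter_emg(x, trial.fs) for ch, x in trial.emg.items()},
        kin={k: filter_kinematics(x, trial.fs) for k, x in trial.kin.items()},
    )


def _prep_slice(trial: EmgTrial, window=_PREP_WINDOW) -> slice:
    fs = trial.fs
    return slice(int(round(window[0] * fs)), int(round(window[1] * fs)))


def normalization_constants(trials: list[EmgTrial], window=_PREP_WINDOW) -> dict:
    """Per (participant, channel) normalization constants.

    Each muscle is normalized to its mean activity over the 100 ms
    preparation window, averaged across the trials in which it actively
    counters the background load (its agonist load sign).
    """
    sums: dict[tuple, list] = {}
    for tr in trials:
        for ch, x in tr.emg.items():
            if tr.load_sign == AGONIST_LOAD[ch]:
                sums.setdefault((tr.participant, ch), []).append(
                    float(np.mean(x[_prep_slice(tr, window)]))
                )
    consts = {key: float(np.mean(v)) for key, v in sums.items()}
    for key, c in consts.items():
        if not c > 0:
            raise ValueError(f"non-positive normalization constant for {key}")
    return consts


def normalize_and_delta(
    trials: list[EmgTrial],
    baselines: list[EmgTrial],
    *,
    window=_PREP_WINDOW,
) -> list[EmgTrial]:
    """Normalize channels and subtract the matched baseline average (dEMG).

    Normalization constants come from the baseline set.  For each trial the
    baseline average matched on background-load sign *and* vision
    availability is subtracted (no-vision disturbance trials use the
    no-vision baselines).
    """
    consts = normalization_constants(baselines, window)

    def norm(tr: EmgTrial) -> EmgTrial:
        out = {}
        for ch, x in tr.emg.items():
            key = (tr.participant, ch)
            if key not in consts:
                raise ValueError(f"no normalization constant for {key}")
            out[ch] = x / consts[key]
        return replace(tr, emg=out)

    baselines_n = [norm(b) for b in baselines]
    base_means: dict[tuple, dict] = {}
    counts: dict[tuple, int] = {}
    for b in baselines_n:
        key = (b.participant, b.load_sign, b.has_vision)
        if key not in base_means:
            base_means[key] = {ch: np.zeros_like(x) for ch, x in b.emg.items()}
            counts[key] = 0
        for ch, x in b.emg.items():
            base_means[key][ch] = base_means[key][ch] + x
        counts[key] += 1
    for key in base_means:
        for ch in base_means[key]:
            base_means[key][ch] = base_means[key][ch] / counts[key]

    out = []
    for tr in trials:
        trn = norm(tr)
        key = (tr.participant, tr.load_sign, tr.has_vision)
        if key not in base_means:
            raise ValueError(
                f"no matched baseline (participant={tr.participant}, "
                f"load={tr.load_sign}, vision={tr.has_vision})"
            )
        delta = {ch: x - base_means[key][ch] for ch, x in trn.emg.items()}
        out.append(replace(trn, emg=delta))
    return out


def exclude_trials(
    trials: list[EmgTrial],
    *,
    window=_PREP_WINDOW,
    prep_sd: float = 3.0,
    spike_mad: float = 10.0,
    spike_halfwidth_s: float = 0.010,
    min_trials: int = 10,
) -> pd.DataFrame:
    """Flag outlier trials per participant and channel.

    Two rules: (1) preparatory-period mean amplitude exceeding the
    across-trial mean by more than ``prep_sd`` SDs; (2) a motion-artifact
    spike, a sample within +/-10 ms of the disturbance onset deviating from
    the trial median by more than ``spike_mad`` times the trial's median
    absolute deviation.  With fewer than ``min_trials`` trials for a
    participant/channel the SD rule is withheld with a warning.
    """
    rows = []
    groups: dict[tuple, list] = {}
    for i, tr in enumerate(trials):
        for ch in tr.emg:
            groups.setdefault((tr.participant, ch), []).append(i)

    for (participant, ch), idxs in groups.items():
        prep = np.array([
            float(np.mean(trials[i].emg[ch][_prep_slice(trials[i], window)]))
            for i in idxs
        ])
        sd_ok = prep.size >= min_trials
        if not sd_ok:
            warnings.warn(
                f"fewer than {min_trials} trials for ({participant}, {ch}); "
                "preparatory-outlier flags withheld", stacklevel=2,
            )
        mu, sd = prep.mean(), prep.std(ddof=1) if prep.size > 1 else 0.0
        for i, prep_i in zip(idxs, prep):
            tr = trials[i]
            prep_flag = bool(sd_ok and sd > 0 and prep_i > mu + prep_sd * sd)
            spike_flag = False
            onset = tr.events.get("onset_s")
            if onset is not None:
                fs = tr.fs
                j = int(round(onset * fs))
                half = int(round(spike_halfwidth_s * fs))
                x = tr.emg[ch]
                seg = x[max(j - half, 0): j + half + 1]
                med = np.median(x)
                mad = np.median(np.abs(x - med))
                if mad > 0 and seg.size:
                    spike_flag = bool(np.max(np.abs(seg - med)) > spike_mad * mad)
            reason = "prep_outlier" if prep_flag else (
                "onset_artifact" if spike_flag else "")
            rows.append({
                "trial": i, "participant": participant, "channel": ch,
                "excluded": prep_flag or spike_flag, "reason": reason,
            })
    return pd.DataFrame(rows).sort_values(["trial", "channel"]).reset_index(drop=True)


def align_visual(trials: list[EmgTrial]) -> list[EmgTrial]:
    """Attach visualization-onset times corrected for display latency.

    The visualization onset is the disturbance command time plus the
    trial's logged display latency plus a fixed 17 ms refresh-cycle
    contribution.  Trials without a logged latency are dropped from
    visual-aligned analyses with a warning.
    """
    out = []
    for tr in trials:
        latency = tr.events.get("latency_s")
        if latency is None:
            warnings.warn(
                f"trial of {tr.participant}/{tr.condition} has no logged display "
                "latency; dropped from visual-aligned analyses", stacklevel=2,
            )
            continue
        onset = tr.events.get("onset_s", 0.0)
        ev = dict(tr.events)
        ev["visual_onset_s"] = onset + latency + DISPLAY_REFRESH_S
        out.append(replace(tr, events=ev))
    return out


def scale_visual_response(
    pv_cursor: np.ndarray,
    v_cursor: np.ndarray,
    *,
    fs: float = FS,
    window: tuple[float, float] = (0.0, 0.090),
    min_shift: float = 1e-6,
) -> float:
    """PV/V cursor-shift ratio over the first 90 ms after visualization onset.

    Both series are lateral cursor shifts aligned on the visualization
    onset at sample 0.  The returned ratio r scales down visual-only dEMG
    responses (multiply by r) so they are comparable with the visual
    component of mechanical-disturbance trials.
    """
    i0, i1 = int(round(window[0] * fs)), int(round(window[1] * fs))
    pv = float(np.mean(np.abs(pv_cursor[i0:i1])))
    v = float(np.mean(np.abs(v_cursor[i0:i1])))
    if v < min_shift:
        raise ValueError("visual-only cursor shift is ~zero in the ratio window")
    return pv / v


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    kernel = np.ones(width) / width
    pad = width // 2
    xp = np.pad(x, pad_width=((0, 0),) * (x.ndim - 1) + ((pad, pad),), mode="edge")
    out = np.apply_along_axis(lambda v: np.convolve(v, kernel, mode="valid"), -1, xp)
    return out


def roc_series(group_a: np.ndarray, group_b: np.ndarray,
               *, smooth_ms: int = 5) -> np.ndarray:
    """Per-millisecond ROC AUC between two groups of participant traces.

    ``group_a`` and ``group_b`` are (n_participants, n_time) arrays of
    per-participant trial-averaged traces; both are smoothed with a
    zero-lag ``smooth_ms``-wide moving average first.  The AUC at each
    time step is the probability of discriminating group_b from group_a
    (0.5 = indistinguishable; 1 or 0 = perfect discrimination).
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 traces per group")
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must share a time base")
    if smooth_ms > 1:
        a = _moving_average(a, smooth_ms)
        b = _moving_average(b, smooth_ms)
    labels = np.r_[np.zeros(a.shape[0]), np.ones(b.shape[0])]
    auc = np.empty(a.shape[1])
    for t in range(a.shape[1]):
        auc[t] = roc_auc_score(labels, np.r_[a[:, t], b[:, t]])
    return auc


@dataclass
class OnsetResult:
    """ROC onset-detection output.

    ``threshold_time`` is the start of the first 10 ms run beyond the 0.75
    (or 0.25) discrimination threshold; ``onset_time`` walks back from
    there to the last 0.50 crossing and refines it to the nearest
    preceding local extremum of the AUC series.  Times are in seconds on
    the series' own grid; ``detected`` is False when the threshold is
    never sustained.
    """

    auc: np.ndarray
    detected: bool
    side: str = ""
    threshold_time: float | None = None
    onset_time: float | None = None
    slope: float | None = None


def detect_onset(
    auc: np.ndarray,
    *,
    fs: float = FS,
    threshold: float = 0.75,
    duration_s: float = 0.010,
    midline: float = 0.50,
    persistence_s: float = 0.050,
    max_rise_s: float = 0.030,
    refine_s: float = 0.010,
) -> OnsetResult:
    """Sustained-threshold ROC onset with knee regression back to 0.50.

    Searches both sides (AUC >= threshold, AUC <= 1 - threshold).  A
    candidate threshold crossing must be sustained for ``duration_s`` and
    must persist: the mean AUC over the following ``persistence_s`` must
    remain beyond the threshold, which rejects the transient chance runs a
    rank statistic over ~13 participants produces pre-onset.  The knee is
    then found by regressing back to the 0.50 crossing: an OLS line is fit
    to the rise segment (from the crossing up to at most ``max_rise_s``
    before the sustained run) and extrapolated to the midline, and the
    result is refined to the nearest preceding local minimum of the AUC
    (maximum for the low side) within ``refine_s``, ties broken toward
    the later time.
    """
    auc = np.asarray(auc, dtype=float)
    need = max(int(round(duration_s * fs)), 1)
    persist = max(int(round(persistence_s * fs)), 1)

    def first_sustained(centered: np.ndarray) -> int | None:
        gap = threshold - midline
        run = 0
        for i, v in enumerate(centered):
            run = run + 1 if v >= gap else 0
            if run >= need:
                start = i - need + 1
                tail = centered[i + 1:i + 1 + persist]
                if tail.size == 0 or tail.mean() >= gap:
                    return start
                run = 0  # transient excursion: keep searching
        return None

    hi = first_sustained(auc - midline)
    lo = first_sustained(midline - auc)
    if hi is None and lo is None:
        return OnsetResult(auc=auc, detected=False)
    if lo is None or (hi is not None and hi <= lo):
        idx, side, sgn = hi, "above", 1.0
    else:
        idx, side, sgn = lo, "below", -1.0

    centered = sgn * (auc - midline)  # positive past the midline

    def is_local_min(j: int) -> bool:
        left = centered[j - 1] if j - 1 >= 0 else np.inf
        right = centered[j + 1] if j + 1 < centered.size else np.inf
        return centered[j] <= left and centered[j] <= right

    # last timepoint before the sustained run at which the AUC was at or
    # past the midline in the opposite direction
    crossing = None
    for j in range(idx, -1, -1):
        if centered[j] <= 0.0:
            crossing = j
            break

    # OLS over the rise segment ending at the run (slope is a diagnostic;
    # the extrapolated midline crossing of the line stands in for the
    # observed crossing when the AUC hovered past the midline throughout)
    max_back = int(round(max_rise_s * fs))
    seg_lo = max(crossing if crossing is not None else 0, idx - max_back)
    seg = np.arange(seg_lo, idx + 1)
    slope = None
    root = None
    if seg.size >= 2:
        coef = np.polyfit(seg.astype(float), centered[seg], 1)
        slope = float(coef[0] * fs * sgn)
        if coef[0] > 0:
            root = -coef[1] / coef[0]

    if crossing is not None:
        knee = crossing
    elif root is not None:
        knee = int(round(np.clip(root, 0, idx)))
    else:
        knee = 0

    # refine to the nearest local extremum at or before the knee
    r = max(int(round(refine_s * fs)), 0)
    for j in range(knee, max(knee - r, 0) - 1, -1):
        if is_local_min(j):
            knee = j
            break

    knee = min(max(knee, 0), idx)
    return OnsetResult(
        auc=auc, detected=True, side=side,
        threshold_time=idx / fs, onset_time=knee / fs, slope=slope,
    )


# ---------------------------------------------------------------------------
# experiment-level drivers

def aligned_matrix(
    trials: list[EmgTrial],
    channel: str,
    *,
    align_event: str = "onset_s",
    pre_s: float = 0.100,
    post_s: float = 0.400,
) -> tuple[np.ndarray, list[str]]:
    """Stack one channel across trials aligned on an event.

    Returns a (n_trials, n_samples) matrix whose sample 0 sits ``pre_s``
    before the alignment event, plus the participant label of each row.
    """
    rows, labels = [], []
    for tr in trials:
        onset = tr.events.get(align_event)
        if onset is None:
            continue
        fs = tr.fs
        j = int(round(onset * fs))
        i0, i1 = j - int(round(pre_s * fs)), j + int(round(post_s * fs))
        x = tr.emg[channel]
        if i0 < 0 or i1 > x.size:
            continue
        rows.append(x[i0:i1])
        labels.append(tr.participant)
    if not rows:
        raise ValueError(f"no trials with event {align_event!r} cover the window")
    return np.vstack(rows), labels


def participant_means(matrix: np.ndarray, labels: list[str]) -> np.ndarray:
    """Per-participant trial-averaged traces (rows sorted by participant)."""
    labels = np.asarray(labels)
    return np.vstack([
        matrix[labels == p].mean(axis=0) for p in sorted(set(labels))
    ])


def emg_epoch_table(
    trials: list[EmgTrial],
    *,
    epochs: dict | None = None,
    apply_exclusion: bool = True,
) -> pd.DataFrame:
    """Per-trial baseline-subtracted epoch means for all channels.

    Splits the trial set into baselines and disturbance trials, applies the
    exclusion rules, normalizes and baseline-subtracts, aligns mechanical
    disturbances on the disturbance onset and visual-only disturbances on
    the visualization onset, and tabulates the V1/V2 epoch means of the
    dEMG per participant, condition, channel and load sign.
    """
    if epochs is None:
        epochs = {"V1": (0.090, 0.130), "V2": (0.140, 0.180)}
    baselines = [t for t in trials if t.condition.startswith("baseline")]
    disturbed = [t for t in trials if not t.condition.startswith("baseline")]
    if not baselines or not disturbed:
        raise ValueError("need both baseline and disturbance trials")

    excluded: set[tuple[int, str]] = set()
    if apply_exclusion:
        flags = exclude_trials([preprocess_trial(t) for t in trials])
        all_trials = trials
        for _, row in flags[flags.excluded].iterrows():
            excluded.add((id(all_trials[int(row.trial)]), row.channel))

    base_f = [preprocess_trial(t) for t in baselines]
    dist_f = [preprocess_trial(t) for t in disturbed]
    delta = normalize_and_delta(dist_f, base_f)

    rows = []
    for orig, tr in zip(disturbed, delta):
        if tr.condition == "V_shift":
            if "visual_onset_s" not in tr.events:
                aligned = align_visual([tr])
                if not aligned:
                    continue
                tr = aligned[0]
            align = tr.events["visual_onset_s"]
        else:
            align = tr.events["onset_s"]
        fs = tr.fs
        for ch, x in tr.emg.items():
            if (id(orig), ch) in excluded:
                continue
            for name, (lo, hi) in epochs.items():
                i0 = int(round((align + lo) * fs))
                i1 = int(round((align + hi) * fs))
                if i0 < 0 or i1 > x.size:
                    continue
                agonist = AGONIST_LOAD[ch] == tr.load_sign
                rows.append({
                    "participant": tr.participant,
                    "condition": tr.condition,
                    "channel": ch,
                    "load_sign": tr.load_sign,
                    "role": "agonist" if agonist else "antagonist",
                    "epoch": name,
                    "mean": float(np.mean(x[i0:i1])),
                })
    return pd.DataFrame(rows)


def direction_onset(
    trials_delta: list[EmgTrial],
    channel: str,
    *,
    align_event: str = "onset_s",
    pre_s: float = 0.100,
    post_s: float = 0.400,
    trial_level: bool = False,
) -> OnsetResult:
    """ROC onset for the flexor- vs extensor-load discrimination.

    The sampling units entering the ROC are per-participant trial-averaged
    traces (set ``trial_level`` to use single trials instead, e.g. for
    synthetic power studies).  The returned times are relative to the start
    of the analysis window, ``pre_s`` before the alignment event.
    """
    flex = [t for t in trials_delta if t.load_sign == "flexor"]
    ext = [t for t in trials_delta if t.load_sign == "extensor"]
    if not flex or not ext:
        raise ValueError("need trials under both background loads")
    ma, la = aligned_matrix(flex, channel, align_event=align_event,
                            pre_s=pre_s, post_s=post_s)
    mb, lb = aligned_matrix(ext, channel, align_event=align_event,
                            pre_s=pre_s, post_s=post_s)
    if not trial_level:
        ma, mb = participant_means(ma, la), participant_means(mb, lb)
    fs = trials_delta[0].fs
    auc = roc_series(ma, mb)
    return detect_onset(auc, fs=fs)
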