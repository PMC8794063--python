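"""Filtering, normalization, exclusion, alignment, ROC onset detection."""

import numpy as np
import pytest

from dynreach.emg import (
    AGONIST_LOAD,
    CHANNELS,
    DISPLAY_REFRESH_S,
    EmgTrial,
    align_visual,
    detect_onset,
    exclude_trials,
    filter_emg,
    filter_kinematics,
    normalize_and_delta,
    preprocess_trial,
    roc_series,
    scale_visual_response,
)

FS = 1000.0


def make_trial(emg=None, *, participant="S01", condition="baseline_v",
               load_sign="extensor", n=800, events=None, rng=None):
    rng = rng or np.random.default_rng(0)
    time = np.arange(n) / FS
    if emg is None:
        emg = {ch: 1.0 + 0.1 * np.abs(rng.standard_normal(n)) for ch in CHANNELS}
    return EmgTrial(participant=participant, condition=condition,
                    load_sign=load_sign, time=time, emg=emg, kin={},
                    events=dict(events or {"onset_s": 0.3}))


class TestFilters:
    def test_zero_input_zero_output(self):
        np.testing.assert_allclose(filter_emg(np.zeros(500)), 0.0, atol=1e-12)

    def test_band_pass_attenuates_out_of_band_tone(self):
        t = np.arange(2000) / FS
        in_band = filter_emg(np.sin(2 * np.pi * 100 * t))
        out_band = filter_emg(np.sin(2 * np.pi * 400 * t))
        core = slice(200, 1800)  # avoid edges
        p_in = np.mean(in_band[core] ** 2)
        p_out = np.mean(out_band[core] ** 2)
        assert p_out < 0.01 * p_in

    def test_zero_lag_symmetry(self):
        # forward-backward filtering is direction-symmetric away from the
        # padded edges (the rectifier passes edge transients differently)
        rng = np.random.default_rng(4)
        x = rng.standard_normal(1200)
        fwd = filter_emg(x)
        rev = filter_emg(x[::-1])[::-1]
        core = slice(100, -100)
        scale = np.abs(fwd[core]).max()
        np.testing.assert_allclose(fwd[core], rev[core], atol=0.01 * scale)

    def test_kinematic_dc_gain_is_unity(self):
        np.testing.assert_allclose(filter_kinematics(np.full(600, 0.13)),
                                   0.13, atol=1e-9)

    def test_jittered_ramp_recovered(self):
        t = np.arange(1500) / FS
        ramp = 0.2 * t
        jitter = 0.002 * np.sin(2 * np.pi * 50 * t)
        out = filter_kinematics(ramp + jitter)
        core = slice(100, 1400)
        rms = np.sqrt(np.mean((out[core] - ramp[core]) ** 2))
        assert rms < 0.01 * np.sqrt(np.mean(ramp[core] ** 2))

    def test_symmetric_bump_peak_preserved(self):
        t = np.arange(1000) / FS
        bump = np.exp(-0.5 * ((t - 0.5) / 0.05) ** 2)
        out = filter_kinematics(bump)
        assert abs(int(np.argmax(out)) - int(np.argmax(bump))) <= 1

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            filter_emg(np.zeros(10))


def _carrier(n, rng):
    from scipy import signal as sig
    sos = sig.butter(3, [25 / 500.0, 250 / 500.0], btype="bandpass", output="sos")
    x = sig.sosfilt(sos, rng.standard_normal(n))
    return x / x.std()


def _mini_experiment(rng, response=3.0, n=900, n_base=8, n_dist=6,
                     scale=1.0):
    """Carrier-modulated baselines and disturbance trials with a planted
    box response on the envelope (agonist channels only)."""
    onset = 0.4
    baselines, disturbed = [], []
    for load in ("flexor", "extensor"):
        for i in range(n_base):
            emg = {ch: scale * (1.0 if AGONIST_LOAD[ch] == load else 0.4)
                   * np.abs(_carrier(n, rng))
                   for ch in CHANNELS}
            baselines.append(make_trial(emg, condition="baseline_v",
                                        load_sign=load,
                                        n=n, events={"onset_s": onset}))
    for i in range(n_dist):
        emg = {}
        for ch in CHANNELS:
            tonic = scale * (1.0 if AGONIST_LOAD[ch] == "extensor" else 0.4)
            envelope = np.full(n, tonic)
            if AGONIST_LOAD[ch] == "extensor":
                j = int((onset + 0.1) * FS)
                envelope[j:j + 150] *= 1.0 + response
            emg[ch] = envelope * np.abs(_carrier(n, rng))
        disturbed.append(make_trial(emg, condition="PV_align",
                                    load_sign="extensor", n=n,
                                    events={"onset_s": onset}))
    return baselines, disturbed


class TestNormalization:
    def test_trial_equal_to_baseline_average_gives_zero_delta(self):
        n = 700
        emg = {ch: np.full(n, 2.0) for ch in CHANNELS}
        base = [make_trial({ch: v.copy() for ch, v in emg.items()},
                           load_sign=load, n=n)
                for load in ("flexor", "extensor") for _ in range(2)]
        trial = make_trial({ch: v.copy() for ch, v in emg.items()},
                           condition="PV_align", load_sign="extensor", n=n)
        out = normalize_and_delta([trial], base)
        for ch in CHANNELS:
            np.testing.assert_allclose(out[0].emg[ch], 0.0, atol=1e-12)

    def test_scale_invariance_of_normalized_output(self):
        rng1 = np.random.default_rng(11)
        rng2 = np.random.default_rng(11)
        b1, d1 = _mini_experiment(rng1, scale=1.0)
        b2, d2 = _mini_experiment(rng2, scale=7.3)
        out1 = normalize_and_delta([preprocess_trial(t) for t in d1],
                                   [preprocess_trial(t) for t in b1])
        out2 = normalize_and_delta([preprocess_trial(t) for t in d2],
                                   [preprocess_trial(t) for t in b2])
        for a, b in zip(out1, out2):
            for ch in CHANNELS:
                np.testing.assert_allclose(a.emg[ch], b.emg[ch], atol=1e-9)

    def test_planted_amplitude_recovered(self):
        rng = np.random.default_rng(21)
        base, dist = _mini_experiment(rng, response=3.0, n_dist=12)
        out = normalize_and_delta([preprocess_trial(t) for t in dist],
                                  [preprocess_trial(t) for t in base])
        onset = 0.4
        j = int((onset + 0.1) * FS)
        window = slice(j + 40, j + 110)  # interior of the planted box
        recovered = np.mean([np.mean(tr.emg["DP"][window]) for tr in out])
        assert recovered == pytest.approx(3.0, rel=0.1)

    def test_missing_matched_baseline_rejected(self):
        base = [make_trial(load_sign="flexor") for _ in range(2)]
        trial = make_trial(condition="P_nov", load_sign="flexor")  # no-vision
        with pytest.raises(ValueError):
            normalize_and_delta([trial], base)


class TestExclusion:
    def test_planted_preparatory_outlier_flagged(self):
        rng = np.random.default_rng(31)
        trials = [make_trial(rng=rng) for _ in range(24)]
        big = {ch: 6.0 * x for ch, x in trials[5].emg.items()}
        trials[5] = make_trial(big, rng=rng)
        flags = exclude_trials(trials)
        flagged = set(flags[flags.excluded].trial)
        assert flagged == {5}

    def test_homogeneous_set_unflagged(self):
        rng = np.random.default_rng(33)
        trials = [make_trial(rng=rng) for _ in range(24)]
        flags = exclude_trials(trials)
        assert not flags.excluded.any()

    def test_planted_onset_spike_flagged(self):
        rng = np.random.default_rng(33)
        trials = [make_trial(rng=rng) for _ in range(24)]
        x = trials[7].emg["PM"]
        x[int(0.3 * FS)] += 20.0 * np.median(x)
        flags = exclude_trials(trials)
        bad = flags[flags.excluded]
        assert set(bad.trial) == {7}
        assert set(bad.reason) == {"onset_artifact"}

    def test_too_few_trials_withholds_sd_rule(self):
        rng = np.random.default_rng(34)
        trials = [make_trial(rng=rng) for _ in range(4)]
        with pytest.warns(UserWarning, match="withheld"):
            flags = exclude_trials(trials)
        assert not flags[flags.reason == "prep_outlier"].excluded.any()


class TestAlignment:
    def test_logged_latency_plus_refresh(self):
        tr = make_trial(events={"onset_s": 0.3, "latency_s": 0.02639})
        out = align_visual([tr])[0]
        assert out.events["visual_onset_s"] == pytest.approx(0.3 + 0.04339)

    def test_zero_latency_shifts_by_refresh_only(self):
        tr = make_trial(events={"onset_s": 0.3, "latency_s": 0.0})
        out = align_visual([tr])[0]
        assert out.events["visual_onset_s"] == pytest.approx(0.3 + DISPLAY_REFRESH_S)

    def test_clock_translation_invariance(self):
        a = make_trial(events={"onset_s": 0.3, "latency_s": 0.03})
        b = make_trial(events={"onset_s": 0.45, "latency_s": 0.03})
        oa = align_visual([a])[0].events
        ob = align_visual([b])[0].events
        assert ob["visual_onset_s"] - oa["visual_onset_s"] == pytest.approx(0.15)

    def test_missing_latency_dropped_with_warning(self):
        tr = make_trial(events={"onset_s": 0.3})
        with pytest.warns(UserWarning, match="latency"):
            assert align_visual([tr]) == []


class TestVisualScaling:
    def test_identical_profiles_give_unity(self):
        x = np.abs(np.sin(np.linspace(0, 1, 200)))
        assert scale_visual_response(x, x.copy()) == pytest.approx(1.0)

    def test_double_shift_gives_half(self):
        x = np.linspace(0, 0.04, 200)
        assert scale_visual_response(x, 2 * x) == pytest.approx(0.5)

    def test_near_zero_shift_rejected(self):
        x = np.linspace(0, 0.04, 200)
        with pytest.raises(ValueError):
            scale_visual_response(x, np.zeros_like(x))


class TestRoc:
    def test_identical_groups_give_half(self):
        rng = np.random.default_rng(41)
        g = rng.standard_normal((6, 300))
        auc = roc_series(g, g.copy())
        np.testing.assert_allclose(auc, 0.5, atol=1e-12)

    def test_label_swap_antisymmetry(self):
        rng = np.random.default_rng(42)
        a = rng.standard_normal((8, 250))
        b = rng.standard_normal((8, 250)) + 0.5
        np.testing.assert_allclose(roc_series(a, b), 1.0 - roc_series(b, a),
                                   atol=1e-12)

    def test_bounds_and_planted_separation(self):
        rng = np.random.default_rng(43)
        a = rng.standard_normal((10, 400))
        b = rng.standard_normal((10, 400))
        b[:, 200:] += 10.0  # 10 SD separation from 200 ms on
        auc = roc_series(a, b)
        assert np.all((auc >= 0.0) & (auc <= 1.0))
        np.testing.assert_allclose(auc[220:], 1.0, atol=1e-12)
        res = detect_onset(auc)
        assert res.detected and res.side == "above"
        assert res.threshold_time == pytest.approx(0.200, abs=0.010)
        assert abs(np.mean(auc[:180]) - 0.5) < 0.1

    def test_group_size_guard(self):
        with pytest.raises(ValueError):
            roc_series(np.zeros((1, 100)), np.zeros((5, 100)))


class TestOnsetDetection:
    def test_linear_ramp_knee_recovered(self):
        auc = np.full(400, 0.5)
        auc[100:] = 0.5 + 0.5 * np.arange(300) / 299.0
        res = detect_onset(auc)
        assert res.detected and res.side == "above"
        assert res.onset_time == pytest.approx(0.100, abs=0.003)
        assert res.onset_time <= res.threshold_time

    def test_flat_series_has_no_onset(self):
        res = detect_onset(np.full(300, 0.5))
        assert not res.detected
        assert res.onset_time is None

    def test_low_side_detected_symmetrically(self):
        auc = np.full(400, 0.5)
        auc[150:] = 0.5 - 0.5 * np.arange(250) / 249.0
        res = detect_onset(auc)
        assert res.detected and res.side == "below"
        assert res.onset_time == pytest.approx(0.150, abs=0.003)

    def test_brief_excursion_not_sustained(self):
        auc = np.full(300, 0.5)
        auc[100:105] = 0.9  # only 5 ms above threshold
        res = detect_onset(auc)
        assert not res.detected

    def test_noisy_knee_refined_to_local_minimum(self):
        rng = np.random.default_rng(44)
        auc = 0.5 + 0.01 * rng.standard_normal(400)
        auc[120:] += 0.5 * np.minimum(np.arange(280) / 80.0, 1.0)
        res = detect_onset(auc)
        assert res.detected
        assert 0.095 <= res.onset_time <= 0.130
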