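"""Trial types, sigmoid cursor shifts, and observation overrides.

Five trial types are modelled, mirroring the cursor-perturbation reaching
paradigm:

* ``baseline_v`` — unperturbed reach, cursor visible throughout.
* ``baseline_nov`` — unperturbed reach, cursor removed from the 3 cm event.
* ``P_nov`` — step force on the limb, cursor removed at force onset
  (proprioceptive disturbance only).
* ``V_shift`` — no force; the visual feedback of cursor position and
  velocity is replaced by the across-trial average of the mechanically
  perturbed (PV) simulations, so the visual error mimics the kinematics of
  a real disturbance without any proprioceptive error.
* ``PV_align`` — step force with veridical cursor feedback.
* ``PV_conflict`` — step force plus a sigmoid cursor shift of amplitude
  -2a on the lateral axis, so visual and proprioceptive errors point in
  opposite directions.

The gradual cursor shift is a logistic function of time since disturbance
onset, ``offset(t) = a / (1 + exp(-(t + t_s)/tau_s))`` (coefficient ``-2a``
in the conflict case), with parameters calibrated per axis and per
disturbance direction by least squares on perturbed minus unperturbed
trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .config import IDX_H, IDX_V, ConfigurationError, PlantConfig
from .lqg import simulate_batch

__all__ = [
    "TRIAL_TYPES",
    "SigmoidParams",
    "SigmoidFitError",
    "ConditionSpec",
    "sigmoid_offset",
    "sigmoid_offset_derivative",
    "fit_sigmoid",
    "CursorShiftModel",
    "CursorShiftResults",
    "ConditionFactory",
]

TRIAL_TYPES = (
    "baseline_v",
    "baseline_nov",
    "P_nov",
    "V_shift",
    "PV_align",
    "PV_conflict",
)

FIT_WINDOW = (-0.100, 0.250)  # s relative to disturbance onset


@dataclass(frozen=True)
class SigmoidParams:
    """Parameters of the gradual cursor shift.

    ``a`` is the shift amplitude (m, signed by direction), ``t_s`` the
    abscissa offset so that the inflection sits at ``t = -t_s`` (s), and
    ``tau_s`` the slope constant (s).
    """

    a: float
    t_s: float
    tau_s: float
    axis: str = "x"
    direction: str = "extensor"

    def __post_init__(self):
        if self.tau_s == 0:
            raise ConfigurationError("tau_s must be nonzero")


class SigmoidFitError(RuntimeError):
    """Sigmoid calibration failed to converge; carries best-so-far values."""

    def __init__(self, params: SigmoidParams, resid_rms: float):
        self.params = params
        self.resid_rms = resid_rms
        super().__init__(
            f"sigmoid fit did not converge (best resid RMS {resid_rms:.3g})"
        )


def sigmoid_offset(t, params: SigmoidParams, conflict: bool = False):
    """Cursor offset at time ``t`` since disturbance onset.

    The coefficient is ``a`` normally and ``-2 a`` in the conflict
    condition (opposite direction, doubled amplitude).
    """
    coef = -2.0 * params.a if conflict else params.a
    return coef / (1.0 + np.exp(-(np.asarray(t, dtype=float) + params.t_s) / params.tau_s))


def sigmoid_offset_derivative(t, params: SigmoidParams, conflict: bool = False):
    """Time derivative of :func:`sigmoid_offset` (m/s)."""
    coef = -2.0 * params.a if conflict else params.a
    s = 1.0 / (1.0 + np.exp(-(np.asarray(t, dtype=float) + params.t_s) / params.tau_s))
    return coef * s * (1.0 - s) / params.tau_s


def fit_sigmoid(
    t: np.ndarray,
    hand_traces: np.ndarray,
    perturbed_traces: np.ndarray,
    window: tuple[float, float] = FIT_WINDOW,
    axis: str = "x",
    direction: str = "extensor",
) -> tuple[SigmoidParams, float]:
    """Least-squares calibration of (a, t_s, tau_s) from trajectories.

    ``t`` is time relative to disturbance onset (s); traces may be 1-D
    (already averaged) or 2-D (trials x time) and are averaged across
    trials.  The residual between ``perturbed - hand`` and the sigmoid is
    minimized over the fit window.  Returns the parameters and the fit
    residual RMS.
    """
    t = np.asarray(t, dtype=float)
    hand = np.atleast_2d(np.asarray(hand_traces, dtype=float)).mean(axis=0)
    pert = np.atleast_2d(np.asarray(perturbed_traces, dtype=float)).mean(axis=0)
    sel = (t >= window[0]) & (t <= window[1])
    if sel.sum() < 4:
        raise ValueError("fit window must contain at least 4 samples")
    tw = t[sel]
    disp = (pert - hand)[sel]

    a0 = disp[-1]
    if a0 == 0.0:
        a0 = 1e-6
    half = np.abs(disp) >= 0.5 * abs(a0)
    t_half = tw[half][0] if half.any() else 0.5 * (tw[0] + tw[-1])
    x0 = np.array([a0, -t_half, 0.030])

    def resid(theta):
        a, ts, tau = theta
        return a / (1.0 + np.exp(-(tw + ts) / tau)) - disp

    res = least_squares(
        resid,
        x0,
        bounds=([-1.0, -1.0, 1e-4], [1.0, 1.0, 1.0]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    params = SigmoidParams(
        a=float(res.x[0]), t_s=float(res.x[1]), tau_s=float(res.x[2]),
        axis=axis, direction=direction,
    )
    rms = float(np.sqrt(np.mean(res.fun ** 2)))
    if not res.success:
        raise SigmoidFitError(params, rms)
    return params, rms


class CursorShiftModel:
    """Sigmoid cursor-shift calibration as a model/fit pair.

    Wraps :func:`fit_sigmoid`: construct from a time base and unperturbed /
    perturbed traces, call :meth:`fit` to estimate the shift parameters.
    """

    def __init__(self, t, hand_traces, perturbed_traces,
                 window: tuple[float, float] = FIT_WINDOW,
                 axis: str = "x", direction: str = "extensor"):
        self.t = np.asarray(t, dtype=float)
        self.hand_traces = np.asarray(hand_traces, dtype=float)
        self.perturbed_traces = np.asarray(perturbed_traces, dtype=float)
        self.window = window
        self.axis = axis
        self.direction = direction

    def fit(self) -> "CursorShiftResults":
        params, rms = fit_sigmoid(
            self.t, self.hand_traces, self.perturbed_traces,
            window=self.window, axis=self.axis, direction=self.direction,
        )
        return CursorShiftResults(model=self, params=params, resid_rms=rms)


@dataclass
class CursorShiftResults:
    model: CursorShiftModel
    params: SigmoidParams
    resid_rms: float

    def predict(self, t, conflict: bool = False):
        return sigmoid_offset(t, self.params, conflict=conflict)

    def summary(self) -> str:
        p = self.params
        lines = [
            "Cursor shift calibration (logistic)",
            f"  axis={p.axis}  direction={p.direction}",
            f"  amplitude a      {p.a * 100:8.3f} cm",
            f"  inflection -t_s  {-p.t_s * 1000:8.1f} ms",
            f"  slope tau_s      {p.tau_s * 1000:8.1f} ms",
            f"  residual RMS     {self.resid_rms * 1000:8.4f} mm",
        ]
        return "\n".join(lines)


@dataclass(frozen=True)
class ConditionSpec:
    """Fully resolved simulation inputs for one trial type.

    ``direction`` is the sign of the mechanical (or mimicked visual)
    disturbance along the lateral axis; ``response_sign`` orients the
    corrective control so that responses are positive.
    """

    trial_type: str
    f_e: np.ndarray
    vision_mask: np.ndarray
    onset_step: int
    direction: int = 1
    visual_override: object = None
    baseline_type: str = "baseline_v"
    align_step: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.align_step is None:
            object.__setattr__(self, "align_step", self.onset_step)

    @property
    def response_sign(self) -> float:
        return -float(self.direction)

    def simulate_kwargs(self) -> dict:
        return {
            "f_e": self.f_e,
            "vision_mask": self.vision_mask,
            "visual_override": self.visual_override,
        }


class ConditionFactory:
    """Builds :class:`ConditionSpec` objects for a fitted lateral-axis model.

    The factory resolves, once per model: the disturbance onset step (the
    mean step at which the noise-free forward-axis hand crosses 3 cm), the
    step-force amplitude (calibrated so the noise-free perturbed peak
    lateral hand deviation matches the configured target, 4.9 cm by
    default), the PV-average cursor trajectory used as the V_shift visual
    override, and the sigmoid parameters used by PV_conflict.  Identical
    inputs always yield identical specs.
    """

    def __init__(self, results, forward_results=None, *,
                 bank_trials: int | None = None, bank_seed: int = 12345):
        # `results` is a fitted lateral-axis ReachingControlResults
        self.results = results
        self.forward_results = forward_results
        self.bank_trials = bank_trials
        self.bank_seed = bank_seed
        self._onset_step = None
        self._amplitude = None
        self._pv_average = None
        self._sigmoid = None

    @property
    def cfg(self) -> PlantConfig:
        return self.results.model.config

    # -- calibrations ------------------------------------------------------

    @property
    def onset_step(self) -> int:
        """Step at which the noise-free forward hand crosses 3 cm travelled."""
        if self._onset_step is None:
            fwd = self.forward_results
            if fwd is None:
                fwd = self.results.model.forward_axis().fit()
                self.forward_results = fwd
            sim = simulate_batch(fwd.system, fwd.gains, n_trials=1, noise=False)
            h = sim["h"][:, 0]
            crossed = np.nonzero(h >= 0.03)[0]
            if crossed.size == 0:
                raise ConfigurationError(
                    "noise-free forward reach never crosses 3 cm; check config"
                )
            self._onset_step = int(crossed[0])
        return self._onset_step

    @property
    def f_e_amplitude(self) -> float:
        """Step-force amplitude (N), calibrated unless fixed in the config."""
        if self._amplitude is None:
            if self.cfg.f_e_amplitude is not None:
                self._amplitude = float(self.cfg.f_e_amplitude)
            else:
                # the noise-free closed loop is linear, so peak deviation
                # scales with amplitude: one unit probe suffices
                f_e = self._step_force(1.0)
                sim = simulate_batch(
                    self.results.system, self.results.gains,
                    n_trials=1, noise=False, f_e=f_e,
                )
                peak = float(np.max(np.abs(sim["h"][:, 0])))
                self._amplitude = self.cfg.target_peak_deviation / peak
        return self._amplitude

    def _step_force(self, amplitude: float) -> np.ndarray:
        f_e = np.zeros(self.cfg.N)
        f_e[self.onset_step:] = amplitude
        return f_e

    def _mask_from_onset(self) -> np.ndarray:
        mask = np.ones(self.cfg.N, dtype=bool)
        mask[self.onset_step:] = False
        return mask

    @property
    def pv_average(self) -> tuple[np.ndarray, np.ndarray]:
        """Across-trial average lateral (p, v) cursor trajectory of PV_align.

        The closed loop is linear with zero-mean noise, so the across-trial
        mean equals the noise-free trajectory; by default the average is
        therefore computed exactly from a noise-free rollout.  Set
        ``bank_trials`` to average a finite noisy bank instead (the exact
        mean plus Monte-Carlo error).
        """
        if self._pv_average is None:
            spec = self.make("PV_align")
            if self.bank_trials is None:
                sim = simulate_batch(
                    self.results.system, self.results.gains,
                    n_trials=1, noise=False, **spec.simulate_kwargs(),
                )
            else:
                sim = simulate_batch(
                    self.results.system, self.results.gains,
                    n_trials=self.bank_trials, seed=self.bank_seed, noise=True,
                    **spec.simulate_kwargs(),
                )
            self._pv_average = (sim["p"].mean(axis=1), sim["v"].mean(axis=1))
        return self._pv_average

    @property
    def sigmoid_params(self) -> SigmoidParams:
        """Sigmoid calibrated on the PV-average lateral cursor excursion."""
        if self._sigmoid is None:
            pbar, _ = self.pv_average
            t = (np.arange(self.cfg.N) - self.onset_step) * self.cfg.dt
            base = np.zeros_like(pbar)  # noise-free baseline stays on axis
            params, _ = fit_sigmoid(t, base, pbar, axis="x",
                                    direction="flexor" if pbar[-1] > 0 else "extensor")
            self._sigmoid = params
        return self._sigmoid

    # -- factory -----------------------------------------------------------

    def make(self, trial_type: str, direction: int = 1) -> ConditionSpec:
        """Resolve one trial type into simulator inputs."""
        if trial_type not in TRIAL_TYPES:
            raise ConfigurationError(
                f"unknown trial type {trial_type!r}; expected one of {TRIAL_TYPES}"
            )
        N = self.cfg.N
        onset = self.onset_step
        full = np.ones(N, dtype=bool)
        zero = np.zeros(N)

        if trial_type == "baseline_v":
            return ConditionSpec("baseline_v", zero, full, onset, direction,
                                 baseline_type="baseline_v")
        if trial_type == "baseline_nov":
            return ConditionSpec("baseline_nov", zero, self._mask_from_onset(),
                                 onset, direction, baseline_type="baseline_nov")
        if trial_type == "P_nov":
            return ConditionSpec(
                "P_nov", self._step_force(direction * self.f_e_amplitude),
                self._mask_from_onset(), onset, direction,
                baseline_type="baseline_nov",
            )
        if trial_type == "PV_align":
            return ConditionSpec(
                "PV_align", self._step_force(direction * self.f_e_amplitude),
                full, onset, direction, baseline_type="baseline_v",
            )
        if trial_type == "V_shift":
            pbar, vbar = self.pv_average
            if direction != 1:
                pbar, vbar = direction * pbar, direction * vbar
            delta_v = self.cfg.delta_v
            # visualization onset: first frame at which the planted cursor
            # trajectory departs from rest (position or velocity)
            moving = np.nonzero((np.abs(pbar) > 1e-12) | (np.abs(vbar) > 1e-12))[0]
            vis_onset = int(moving[0]) if moving.size else onset

            def override(t, x_lag_v, _p=pbar, _v=vbar, _d=delta_v):
                f = max(t - _d, 0)
                return _p[f], _v[f]

            return ConditionSpec(
                "V_shift", zero, full, onset, direction,
                visual_override=override, baseline_type="baseline_v",
                align_step=vis_onset,
                meta={"override": "pv_average", "visualization_onset": vis_onset},
            )
        # PV_conflict
        params = self.sigmoid_params
        if direction != 1:
            params = replace(params, a=direction * params.a)
        delta_v, dt = self.cfg.delta_v, self.cfg.dt

        def override(t, x_lag_v, _pr=params, _d=delta_v, _dt=dt, _on=onset):
            t_rel = (t - _d - _on) * _dt
            if t_rel < 0:
                return x_lag_v[IDX_H], x_lag_v[IDX_V]
            off = sigmoid_offset(t_rel, _pr, conflict=True)
            doff = sigmoid_offset_derivative(t_rel, _pr, conflict=True)
            return x_lag_v[IDX_H] + off, x_lag_v[IDX_V] + doff

        return ConditionSpec(
            "PV_conflict", self._step_force(direction * self.f_e_amplitude),
            full, onset, direction,
            visual_override=override, baseline_type="baseline_v",
            meta={"override": "sigmoid_conflict", "a": params.a,
                  "t_s": params.t_s, "tau_s": params.tau_s},
        )
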