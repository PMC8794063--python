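"""Delay-augmented LQG core: plant, observation model, gains, simulation.

The per-axis plant has six states ``[p, h, v, F_MC, F_E, p*]`` (cursor
position, hand position, velocity, controlled muscle force, external force,
target).  Feedback delays are handled by augmenting the state with past
copies of itself (a shift register), so that the delayed proprioceptive and
visual observations become linear read-outs of the augmented state at the
appropriate lag.  The optimal feedback gains L and Kalman gains K are
computed offline by a coupled fixed-point iteration that handles
signal-dependent motor noise and partial observability; the forward
simulation then runs estimator and controller in closed loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import (
    IDX_FE,
    IDX_FMC,
    IDX_H,
    IDX_P,
    IDX_PSTAR,
    IDX_V,
    N_CORE,
    ConfigurationError,
    PlantConfig,
)

__all__ = [
    "H_P",
    "H_V",
    "AugmentedSystem",
    "GainSchedule",
    "TrialRecord",
    "SimulationError",
    "build_core_system",
    "augment_delays",
    "compute_gains",
    "kalman_step",
    "simulate_trial",
    "simulate_batch",
]


class SimulationError(RuntimeError):
    """State diverged (NaN/Inf) during a closed-loop rollout."""

    def __init__(self, step: int, message: str | None = None):
        self.step = step
        super().__init__(message or f"state diverged at step {step}")


# Observation submatrices.  Proprioception directly observes hand position,
# velocity, muscle force, external force and the target; vision directly
# observes cursor position, velocity and the target.  Each block is 6x6 with
# zero rows for unobserved coordinates; the corresponding observation
# components are pure sensor noise and receive ~zero Kalman weight.
H_P = np.array(
    [
        [0, 0, 0, 0, 0, 0],
        [0, 1, 0, 0, 0, 0],
        [0, 0, 1, 0, 0, 0],
        [0, 0, 0, 1, 0, 0],
        [0, 0, 0, 0, 1, 0],
        [0, 0, 0, 0, 0, 1],
    ],
    dtype=float,
)
H_V = np.array(
    [
        [1, 0, 0, 0, 0, 0],
        [0, 0, 0, 0, 0, 0],
        [0, 0, 1, 0, 0, 0],
        [0, 0, 0, 0, 0, 0],
        [0, 0, 0, 0, 0, 0],
        [0, 0, 0, 0, 0, 1],
    ],
    dtype=float,
)

# Rows of the visual observation block that carry cursor position / velocity.
VIS_ROW_P = 0
VIS_ROW_V = 2


def build_core_system(cfg: PlantConfig) -> tuple[np.ndarray, np.ndarray]:
    """Discrete six-state dynamics (A6, B6) by Euler integration.

    Cursor and hand both integrate the velocity; the velocity row carries the
    viscous damping ``1 - G dt / m`` and couples ``dt/m`` to both the muscle
    and the external force; the muscle force is a first-order low-pass of the
    control with time constant ``tau_muscle``; the external force and target
    are constants from the plant's point of view.
    """
    dt, m, G, tau = cfg.dt, cfg.m, cfg.G, cfg.tau_muscle
    A = np.eye(N_CORE)
    A[IDX_P, IDX_V] = dt
    A[IDX_H, IDX_V] = dt
    A[IDX_V, IDX_V] = 1.0 - G * dt / m
    A[IDX_V, IDX_FMC] = dt / m
    A[IDX_V, IDX_FE] = dt / m
    A[IDX_FMC, IDX_FMC] = 1.0 - dt / tau
    B = np.zeros((N_CORE, 1))
    B[IDX_FMC, 0] = dt / tau
    return A, B


@dataclass
class AugmentedSystem:
    """Delay-augmented discrete system with split observation blocks."""

    A: np.ndarray           # (n_aug, n_aug)
    B: np.ndarray           # (n_aug, 1)
    C_noise: np.ndarray     # (n_aug, 1): signal-dependent noise direction/scale
    H: np.ndarray           # (12, n_aug): [H_p block; H_v block]
    Sigma_xi: np.ndarray    # (n_aug, n_aug) additive plant noise covariance
    Sigma_omega: np.ndarray  # (12, 12) observation noise covariance
    Sigma_internal: np.ndarray  # (n_aug, n_aug) prediction noise covariance
    cfg: PlantConfig
    n_core: int = N_CORE

    @property
    def n_aug(self) -> int:
        return self.A.shape[0]

    @property
    def H_prop(self) -> np.ndarray:
        return self.H[:N_CORE]

    @property
    def H_vis(self) -> np.ndarray:
        return self.H[N_CORE:]

    def lag_block(self, x: np.ndarray, lag: int) -> np.ndarray:
        """Core-state block of an augmented vector at the given lag."""
        return x[lag * N_CORE:(lag + 1) * N_CORE]


def augment_delays(core: tuple[np.ndarray, np.ndarray], cfg: PlantConfig) -> AugmentedSystem:
    """Stack ``delta_v + 1`` past core states into a shift-register system.

    The top block row advances the current state; block k copies block k-1,
    so after one step the lag-k block equals the previous step's lag-(k-1)
    block.  The proprioceptive observation reads the block at lag
    ``delta_p``, the visual observation the block at lag ``delta_v``.
    """
    if cfg.delta_p > cfg.delta_v:
        raise ConfigurationError("delta_p must not exceed delta_v")
    A6, B6 = core
    n_lags = cfg.delta_v + 1
    n = N_CORE * n_lags
    A = np.zeros((n, n))
    A[:N_CORE, :N_CORE] = A6
    for k in range(1, n_lags):
        A[k * N_CORE:(k + 1) * N_CORE, (k - 1) * N_CORE:k * N_CORE] = np.eye(N_CORE)
    B = np.zeros((n, 1))
    B[:N_CORE] = B6

    H = np.zeros((2 * N_CORE, n))
    H[:N_CORE, cfg.delta_p * N_CORE:(cfg.delta_p + 1) * N_CORE] = H_P
    H[N_CORE:, cfg.delta_v * N_CORE:(cfg.delta_v + 1) * N_CORE] = H_V

    Sigma_xi = np.zeros((n, n))
    Sigma_xi[:N_CORE, :N_CORE] = cfg.sigma_additive ** 2 * (B6 @ B6.T)

    Sigma_omega = np.diag(
        np.concatenate(
            [
                np.full(N_CORE, cfg.Sigma_p_scale),
                np.full(N_CORE, cfg.Sigma_v_scale),
            ]
        )
    )
    Sigma_internal = cfg.Sigma_internal * np.eye(n)
    C_noise = cfg.c_parallel * B
    return AugmentedSystem(
        A=A,
        B=B,
        C_noise=C_noise,
        H=H,
        Sigma_xi=Sigma_xi,
        Sigma_omega=Sigma_omega,
        Sigma_internal=Sigma_internal,
        cfg=cfg,
    )


def _cost_matrix(sys: AugmentedSystem) -> np.ndarray:
    """Quadratic cursor-position error (p_t - p*)^2 on the current core block."""
    n = sys.n_aug
    q = np.zeros(n)
    q[IDX_P] = 1.0
    q[IDX_PSTAR] = -1.0
    return np.outer(q, q)


def _cost_schedule(sys: AugmentedSystem) -> np.ndarray:
    """Per-step weights of the position penalty.

    With ``cost_hold_start`` set, the penalty is active from that step
    (clamped so the terminal step is always penalized) through the horizon,
    pacing the reach to arrive by the task's movement-time limit and hold;
    with ``None`` it is active at every step.
    """
    cfg = sys.cfg
    w = np.ones(cfg.N)
    if cfg.cost_hold_start is not None:
        start = min(cfg.cost_hold_start, cfg.N - 1)
        w[:start] = 0.0
    return w


@dataclass
class GainSchedule:
    """Per-step feedback and Kalman gains (u_t = L_t x_hat_t)."""

    L: np.ndarray        # (N, n_aug): control row vectors, u = L[t] @ x_hat
    K: np.ndarray        # (N, n_aug, 12)
    converged: bool
    iterations: int
    max_delta: float

    @property
    def K_p(self) -> np.ndarray:
        return self.K[:, :, :N_CORE]

    @property
    def K_v(self) -> np.ndarray:
        return self.K[:, :, N_CORE:]


def _initial_state(sys: AugmentedSystem) -> np.ndarray:
    """Pre-trial augmented state: all lag blocks at rest at the start point."""
    x0_core = np.zeros(N_CORE)
    x0_core[IDX_PSTAR] = sys.cfg.p_star
    return np.tile(x0_core, sys.cfg.delta_v + 1)


def compute_gains(
    sys: AugmentedSystem,
    cfg: PlantConfig | None = None,
    *,
    tol: float = 1e-12,
    max_iter: int = 500,
) -> GainSchedule:
    """Coupled estimator/controller fixed-point iteration.

    Alternates a backward controller pass (given the Kalman gains) and a
    forward estimator pass (given the feedback gains) until the largest gain
    change falls below ``tol``.  The controller pass propagates cost-to-go
    matrices on the true state and on the estimation error; the estimator
    pass propagates unconditional second moments of the estimation error,
    the estimate, and their cross term, so that signal-dependent motor noise
    (variance growing with the control) and the internal prediction noise
    both shape the gains.  With zero signal-dependent noise and zero internal
    noise, the iteration terminates at the classical decoupled LQG solution.
    """
    cfg = cfg or sys.cfg
    n = sys.n_aug
    N = cfg.N
    A, B, H = sys.A, sys.B, sys.H
    C = sys.C_noise
    Q = _cost_matrix(sys)
    q_w = _cost_schedule(sys)
    R = np.atleast_2d(cfg.R)
    Sigma_xi = sys.Sigma_xi + sys.Sigma_internal  # plant + prediction noise
    Sigma_omega = sys.Sigma_omega
    Sigma_eta = sys.Sigma_internal

    x0 = _initial_state(sys)
    K = np.zeros((N, n, 2 * N_CORE))
    L = np.zeros((N, n))
    prev_L = L.copy()
    prev_K = K.copy()
    converged = False
    it = 0
    max_delta = np.inf

    for it in range(1, max_iter + 1):
        # --- controller pass (backward), given K ---
        Sx = q_w[N - 1] * Q
        Se = np.zeros((n, n))
        for t in range(N - 2, -1, -1):
            BtSx = B.T @ Sx
            D = R + BtSx @ B + C.T @ (Sx + Se) @ C
            Lt = np.linalg.solve(D, BtSx @ A)  # (1, n), u = -Lt x_hat
            AmKH = A - K[t] @ H
            Se = A.T @ Sx @ (B @ Lt) + AmKH.T @ Se @ AmKH
            Sx = q_w[t] * Q + A.T @ Sx @ (A - B @ Lt)
            L[t] = -Lt[0]
        L[N - 1] = 0.0

        # --- estimator pass (forward), given L ---
        Sig_e = np.zeros((n, n))          # E[e e'],    e = x - x_hat
        Sig_xh = np.outer(x0, x0)         # E[x_hat x_hat'] (second moment)
        Sig_exh = np.zeros((n, n))        # E[e x_hat']
        for t in range(N - 1):
            Lt = -L[t][None, :]           # internal sign convention
            S = H @ Sig_e @ H.T + Sigma_omega
            Kt = np.linalg.solve(S.T, (A @ Sig_e @ H.T).T).T
            K[t] = Kt
            AmKH = A - Kt @ H
            AmBL = A - B @ Lt
            u_moment = Lt @ Sig_xh @ Lt.T          # E[u^2]
            Sig_cu = C @ u_moment @ C.T
            new_e = Sigma_xi + AmKH @ Sig_e @ A.T + Sig_cu
            new_xh = (
                AmBL @ Sig_xh @ AmBL.T
                + Kt @ S @ Kt.T
                + Sigma_eta
                + AmBL @ Sig_exh.T @ H.T @ Kt.T
                + Kt @ H @ Sig_exh @ AmBL.T
            )
            new_exh = (
                AmKH @ (Sig_exh @ AmBL.T + Sig_e @ H.T @ Kt.T)
                - Kt @ Sigma_omega @ Kt.T
                - Sigma_eta
            )
            Sig_e, Sig_xh, Sig_exh = new_e, new_xh, new_exh
        K[N - 1] = K[N - 2]

        max_delta = max(np.max(np.abs(L - prev_L)), np.max(np.abs(K - prev_K)))
        if max_delta < tol:
            converged = True
            break
        prev_L = L.copy()
        prev_K = K.copy()

    return GainSchedule(L=L, K=K, converged=converged, iterations=it, max_delta=max_delta)


def kalman_step(
    x_hat_prev: np.ndarray,
    u_prev: float | np.ndarray,
    y_t: np.ndarray,
    gains_t: np.ndarray,
    sys: AugmentedSystem,
    *,
    vision: bool = True,
    internal_noise: np.ndarray | None = None,
) -> np.ndarray:
    """One estimator update: prior propagation plus per-modality innovations.

    ``y_t`` stacks the proprioceptive block (first 6 entries) and, when
    ``vision`` is true, the visual block (last 6).  The innovation for each
    modality compares its observation against the prior's block at that
    modality's lag (which, in the shift-register state, is exactly
    ``H x_hat``).  On no-vision steps the visual term is omitted entirely.
    """
    x_hat_prev = np.asarray(x_hat_prev, dtype=float)
    if x_hat_prev.shape[0] != sys.n_aug:
        raise ValueError("x_hat_prev has wrong dimension for this system")
    prior = sys.A @ x_hat_prev + (sys.B @ np.atleast_2d(u_prev)).ravel()
    if internal_noise is not None:
        prior = prior + internal_noise
    K_p = gains_t[:, :N_CORE]
    innov_p = y_t[:N_CORE] - sys.H_prop @ x_hat_prev
    x_hat = prior + K_p @ innov_p
    if vision:
        if y_t.shape[0] < 2 * N_CORE:
            raise ValueError("visual observation block missing")
        K_v = gains_t[:, N_CORE:]
        innov_v = y_t[N_CORE:] - sys.H_vis @ x_hat_prev
        x_hat = x_hat + K_v @ innov_v
    return x_hat


@dataclass
class TrialRecord:
    """Time series of one simulated trial (true, estimated, control, observed)."""

    time: np.ndarray                 # (N,)
    x_true: np.ndarray               # (N, n_aug)
    x_hat: np.ndarray                # (N, n_aug)
    u: np.ndarray                    # (N,)
    y: np.ndarray                    # (N, 12); visual block NaN when masked
    vision_mask: np.ndarray          # (N,) bool, vision available at step t
    events: dict = field(default_factory=dict)

    def core(self, name_idx: int) -> np.ndarray:
        return self.x_true[:, name_idx]


def _draw_visual_noise(rng, sigma_v, shape):
    return np.sqrt(sigma_v) * rng.standard_normal(shape)


def simulate_batch(
    sys: AugmentedSystem,
    gains: GainSchedule,
    *,
    n_trials: int = 1,
    seed: int | np.random.Generator | None = None,
    noise: bool = True,
    f_e: np.ndarray | None = None,
    vision_mask: np.ndarray | None = None,
    visual_override=None,
    store_full: bool = False,
) -> dict:
    """Closed-loop rollout of ``n_trials`` trials, vectorized over trials.

    Parameters
    ----------
    f_e : per-step external force (length N), or None for no disturbance.
    vision_mask : per-step availability of the visual feedback channel
        (length N bool); None means vision available throughout.
    visual_override : optional callable ``(t, x_lag_v) -> (p_vis, v_vis)``
        replacing the cursor position and velocity components of the visual
        observation (before sensor noise); ``x_lag_v`` is the (6, n_trials)
        core block at the visual lag.
    noise : draw additive, signal-dependent, observation and internal noise;
        False runs the deterministic mean system.
    store_full : additionally record the full augmented true/estimated states
        and observations (memory-heavy; intended for single trials).

    Returns a dict of arrays keyed ``time, p, h, v, F_MC, F_E, u`` (time is
    (N,), the rest (N, n_trials)) plus, with ``store_full``, ``x_true,
    x_hat, y``.
    """
    cfg = sys.cfg
    N, n = cfg.N, sys.n_aug
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if f_e is None:
        f_e = np.zeros(N)
    if vision_mask is None:
        vision_mask = np.ones(N, dtype=bool)
    f_e = np.asarray(f_e, dtype=float)
    vision_mask = np.asarray(vision_mask, dtype=bool)
    if f_e.shape[0] != N or vision_mask.shape[0] != N:
        raise ValueError("f_e and vision_mask must have length N")

    A, B, H = sys.A, sys.B, sys.H
    sqrt_int = np.sqrt(cfg.Sigma_internal)
    sigma_p, sigma_v = cfg.Sigma_p_scale, cfg.Sigma_v_scale

    x0 = _initial_state(sys)
    X = np.tile(x0[:, None], (1, n_trials))
    Xh = X.copy()
    X[IDX_FE] = f_e[0]

    out = {k: np.zeros((N, n_trials)) for k in ("p", "h", "v", "F_MC", "F_E", "u")}
    if store_full:
        full = {
            "x_true": np.zeros((N, n, n_trials)),
            "x_hat": np.zeros((N, n, n_trials)),
            "y": np.full((N, 2 * N_CORE, n_trials), np.nan),
        }

    Hp, Hv = sys.H_prop, sys.H_vis
    for t in range(N):
        for key, idx in (("p", IDX_P), ("h", IDX_H), ("v", IDX_V),
                         ("F_MC", IDX_FMC), ("F_E", IDX_FE)):
            out[key][t] = X[idx]
        with np.errstate(over="ignore", invalid="ignore"):
            u = gains.L[t] @ Xh  # (n_trials,)
        out["u"][t] = u
        if store_full:
            full["x_true"][t] = X
            full["x_hat"][t] = Xh

        # observation of the current augmented state (delivered at step t)
        y_prop = Hp @ X
        if noise:
            y_prop = y_prop + np.sqrt(sigma_p) * rng.standard_normal(y_prop.shape)
        see = vision_mask[t]
        y_vis = None
        if see:
            y_vis = Hv @ X
            if visual_override is not None:
                lag = cfg.delta_v * N_CORE
                x_lag_v = X[lag:lag + N_CORE]
                p_vis, v_vis = visual_override(t, x_lag_v)
                y_vis[VIS_ROW_P] = p_vis
                y_vis[VIS_ROW_V] = v_vis
            if noise:
                y_vis = y_vis + _draw_visual_noise(rng, sigma_v, y_vis.shape)
        if store_full:
            full["y"][t, :N_CORE] = y_prop
            if see:
                full["y"][t, N_CORE:] = y_vis

        if t == N - 1:
            break

        # --- plant update ---
        with np.errstate(over="ignore", invalid="ignore"):
            Xn = A @ X + B @ u[None, :]
            if noise:
                xi = cfg.sigma_additive * rng.standard_normal((1, n_trials))
                eps = rng.standard_normal((1, n_trials))
                Xn = Xn + B @ xi + sys.C_noise @ (eps * u[None, :])
            Xn[IDX_FE] = f_e[t + 1]

            # --- estimator update (prior + per-modality innovations) ---
            prior = A @ Xh + B @ u[None, :]
            if noise:
                prior = prior + sqrt_int * rng.standard_normal((n, n_trials))
            Xhn = prior + gains.K_p[t] @ (y_prop - Hp @ Xh)
            if see:
                Xhn = Xhn + gains.K_v[t] @ (y_vis - Hv @ Xh)

        if not (np.all(np.isfinite(Xn)) and np.all(np.isfinite(Xhn))):
            raise SimulationError(t + 1)
        X, Xh = Xn, Xhn

    out["time"] = np.arange(N) * cfg.dt
    if store_full:
        out.update(full)
    out["vision_mask"] = vision_mask
    return out


def simulate_trial(
    sys: AugmentedSystem,
    gains: GainSchedule,
    *,
    seed: int | None = None,
    noise: bool = True,
    f_e: np.ndarray | None = None,
    vision_mask: np.ndarray | None = None,
    visual_override=None,
    events: dict | None = None,
) -> TrialRecord:
    """Single-trial rollout returning the full :class:`TrialRecord`."""
    res = simulate_batch(
        sys,
        gains,
        n_trials=1,
        seed=seed,
        noise=noise,
        f_e=f_e,
        vision_mask=vision_mask,
        visual_override=visual_override,
        store_full=True,
    )
    ev = dict(events or {})
    ev.setdefault("seed", seed)
    return TrialRecord(
        time=res["time"],
        x_true=res["x_true"][:, :, 0],
        x_hat=res["x_hat"][:, :, 0],
        u=res["u"][:, 0],
        y=res["y"][:, :, 0],
        vision_mask=res["vision_mask"],
        events=ev,
    )
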