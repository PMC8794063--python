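"""Model / results objects for the delay-augmented LQG reaching controller.

``ReachingModel`` holds one lateral (or forward) axis of the reaching plant;
``fit`` computes the optimal feedback and Kalman gains and returns a
``ReachingControlResults`` from which trials are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import PlantConfig
from .conditions import ConditionFactory, ConditionSpec
from .lqg import (
    AugmentedSystem,
    GainSchedule,
    TrialRecord,
    augment_delays,
    build_core_system,
    compute_gains,
    simulate_batch,
    simulate_trial,
)

__all__ = ["ReachingModel", "ReachingControlResults"]


class ReachingModel:
    """One axis of the reaching plant, ready to be solved.

    Parameters
    ----------
    config : plant/delay/noise/cost parameters; defaults to the published
        parameter set with the perturbed-trial horizon.
    """

    def __init__(self, config: PlantConfig | None = None):
        self.config = config or PlantConfig()
        self.core = build_core_system(self.config)
        self.system: AugmentedSystem = augment_delays(self.core, self.config)

    def forward_axis(self, p_star: float = 0.20) -> "ReachingModel":
        """Companion model for the forward axis (20 cm reach)."""
        return ReachingModel(self.config.replace(p_star=p_star))

    def fit(self, tol: float = 1e-12, max_iter: int = 500) -> "ReachingControlResults":
        gains = compute_gains(self.system, self.config, tol=tol, max_iter=max_iter)
        return ReachingControlResults(model=self, system=self.system, gains=gains)


@dataclass
class ReachingControlResults:
    """Fitted gains plus simulation entry points."""

    model: ReachingModel
    system: AugmentedSystem
    gains: GainSchedule

    @property
    def L(self) -> np.ndarray:
        return self.gains.L

    @property
    def K_p(self) -> np.ndarray:
        return self.gains.K_p

    @property
    def K_v(self) -> np.ndarray:
        return self.gains.K_v

    @property
    def converged(self) -> bool:
        return self.gains.converged

    def conditions(self, **kwargs) -> ConditionFactory:
        if not hasattr(self, "_factory"):
            self._factory = ConditionFactory(self, **kwargs)
        return self._factory

    def _resolve(self, condition) -> dict:
        if condition is None:
            return {}
        if isinstance(condition, str):
            condition = self.conditions().make(condition)
        if isinstance(condition, ConditionSpec):
            return condition.simulate_kwargs()
        raise TypeError("condition must be None, a trial-type name, or a ConditionSpec")

    def simulate(self, condition=None, *, n_trials: int = 1, seed=None,
                 noise: bool = True, store_full: bool = False) -> dict:
        """Vectorized closed-loop rollout; see :func:`dynreach.lqg.simulate_batch`."""
        return simulate_batch(
            self.system, self.gains, n_trials=n_trials, seed=seed,
            noise=noise, store_full=store_full, **self._resolve(condition),
        )

    def simulate_trial(self, condition=None, *, seed=None, noise: bool = True) -> TrialRecord:
        events = {}
        if isinstance(condition, str):
            condition = self.conditions().make(condition)
        if isinstance(condition, ConditionSpec):
            events = {"condition": condition.trial_type,
                      "onset_step": condition.onset_step,
                      "direction": condition.direction}
        return simulate_trial(
            self.system, self.gains, seed=seed, noise=noise,
            events=events, **self._resolve(condition),
        )

    def summary(self) -> str:
        cfg = self.model.config
        g = self.gains
        lines = [
            "Delay-augmented LQG reaching controller",
            "=" * 44,
            f"horizon N            {cfg.N:6d} steps ({cfg.N * cfg.dt * 1000:.0f} ms)",
            f"augmented dimension  {self.system.n_aug:6d}",
            f"prop. delay          {cfg.delta_p:6d} steps ({cfg.delta_p_ms:.0f} ms)",
            f"visual delay         {cfg.delta_v:6d} steps ({cfg.delta_v_ms:.0f} ms)",
            f"noise ratio Sp/Sv    {cfg.vision_ratio:8.2f}",
            f"converged            {g.converged!s:>6} in {g.iterations} iterations "
            f"(max gain delta {g.max_delta:.2e})",
            f"peak |L|             {np.max(np.abs(g.L)):10.4g}",
            f"peak |K|             {np.max(np.abs(g.K)):10.4g}",
        ]
        return "\n".join(lines)
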