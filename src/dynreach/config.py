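"""Model configuration.

All quantities are SI (m, s, N).  Sensory delays are stored as integer
simulation steps; the millisecond value is derived from ``dt``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


# State ordering of the per-axis plant: cursor position, hand position,
# velocity, controlled muscle force, external force, target coordinate.
STATE_NAMES = ("p", "h", "v", "F_MC", "F_E", "p_star")
N_CORE = len(STATE_NAMES)

IDX_P = 0
IDX_H = 1
IDX_V = 2
IDX_FMC = 3
IDX_FE = 4
IDX_PSTAR = 5


@dataclass(frozen=True)
class PlantConfig:
    """Physical, delay, noise and cost parameters of the reaching plant.

    Defaults are the published parameter set: a 1 kg point mass with elbow-like
    viscous damping G = 0.15 N s/m, first-order muscle dynamics with a 66 ms
    time constant, 10 ms discretization, 50 ms proprioceptive and 90 ms visual
    feedback delays, additive motor noise sigma = 0.066, signal-dependent motor
    noise 0.015 (parallel) / 0.005 (orthogonal), proprioceptive observation
    noise 1e-5 with a proprioceptive/visual variance ratio of 2.3 (vision
    weighted ~70%), internal prediction noise 0.8e-6, and control cost R = 1e-6.

    Parameters
    ----------
    m : mass (kg).
    G : viscous damping (N s/m).
    tau_muscle : muscle low-pass time constant (s).
    dt : discretization step (s).
    delta_p, delta_v : proprioceptive / visual delay (integer steps).
    N : simulation horizon (steps).
    p_star : target coordinate (m) for this axis.
    sigma_additive : scale of the additive motor noise (covariance sigma^2 B B').
    c_parallel, c_orthogonal : signal-dependent noise scales.  The per-axis
        plant has a scalar control, so only the parallel component acts;
        the orthogonal component is retained for completeness.
    Sigma_p_scale : proprioceptive observation noise variance (per coordinate).
    vision_ratio : Sigma_p / Sigma_v variance ratio.
    Sigma_internal : internal (prediction) noise variance per coordinate.
    R : quadratic control cost weight.
    cost_hold_start : first step at which the quadratic position penalty
        applies (clamped to the horizon; the terminal step is always
        penalized).  The default, 70 steps (700 ms), is the unperturbed
        movement-time limit of the task: penalizing position only from
        there on paces the reach like the human movements (~700 ms to
        target, then stabilization), whereas ``None`` penalizes every step
        and produces unrealistically fast reaches at the published R.
    f_e_amplitude : external step-force amplitude (N).  ``None`` means
        "calibrate so that the noise-free perturbed peak lateral hand
        deviation matches ``target_peak_deviation``".
    target_peak_deviation : peak lateral hand deviation (m) used by the
        amplitude calibration (human PV mean, 4.9 cm).
    """

    m: float = 1.0
    G: float = 0.15
    tau_muscle: float = 0.066
    dt: float = 0.010
    delta_p: int = 5
    delta_v: int = 9
    N: int = 110
    p_star: float = 0.0
    sigma_additive: float = 0.066
    c_parallel: float = 0.015
    c_orthogonal: float = 0.005
    Sigma_p_scale: float = 1e-5
    vision_ratio: float = 2.3
    Sigma_internal: float = 0.8e-6
    R: float = 1e-6
    cost_hold_start: int | None = 70
    f_e_amplitude: float | None = None
    target_peak_deviation: float = 0.049

    def __post_init__(self) -> None:
        if self.m <= 0 or self.tau_muscle <= 0 or self.dt <= 0:
            raise ConfigurationError("m, tau_muscle and dt must be positive")
        if self.G < 0:
            raise ConfigurationError("G must be non-negative")
        if not (0 <= self.delta_p <= self.delta_v):
            raise ConfigurationError("need 0 <= delta_p <= delta_v")
        if self.N <= self.delta_v:
            raise ConfigurationError("horizon N must exceed delta_v")
        for name in ("sigma_additive", "c_parallel", "c_orthogonal",
                     "Sigma_p_scale", "Sigma_internal", "R"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.vision_ratio <= 0:
            raise ConfigurationError("vision_ratio must be positive")

    # -- derived quantities ------------------------------------------------

    @property
    def delta_p_ms(self) -> float:
        return self.delta_p * self.dt * 1000.0

    @property
    def delta_v_ms(self) -> float:
        return self.delta_v * self.dt * 1000.0

    @property
    def Sigma_v_scale(self) -> float:
        """Visual observation noise variance, Sigma_p / vision_ratio."""
        return self.Sigma_p_scale / self.vision_ratio

    @property
    def n_aug(self) -> int:
        return N_CORE * (self.delta_v + 1)

    def replace(self, **kwargs) -> "PlantConfig":
        return dataclasses.replace(self, **kwargs)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PlantConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def baseline_config(**overrides) -> PlantConfig:
    """Published parameter set with the unperturbed 700 ms horizon (70 steps)."""
    overrides.setdefault("N", 70)
    return PlantConfig(**overrides)


def perturbed_config(**overrides) -> PlantConfig:
    """Published parameter set with the perturbed 1100 ms horizon (110 steps)."""
    overrides.setdefault("N", 110)
    return PlantConfig(**overrides)
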