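"""Epoch quantification, additivity comparison, variability, onsets, sweep.

Model outputs are quantified the way the experimental muscle data are:
baseline-subtracted means of the lateral control signal in two
post-disturbance epochs (V1, 90-130 ms; V2, 140-180 ms), comparison of the
bimodal (PV) response against the additive sum of the unimodal (P, V)
responses, per-timepoint lateral-position SD over repeated cycles of
simulated trajectories, threshold-based control-response onsets, and a
sensitivity sweep over the visual noise ratio and visual delay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PlantConfig

__all__ = [
    "EpochDef",
    "EpochSummary",
    "VariabilityCurve",
    "V1",
    "V2",
    "EPOCHS",
    "epoch_mean",
    "epoch_table",
    "additive_comparison",
    "endpoint_variability",
    "control_onset",
    "sensitivity_sweep",
    "winsorize_trim",
]


@dataclass(frozen=True)
class EpochDef:
    """Half-open response window [start, end) relative to the alignment onset."""

    name: str
    start: float
    end: float

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("epoch start must precede end")

    def slice(self, align_step: int, dt: float, n_steps: int) -> slice:
        i0 = align_step + int(round(self.start / dt))
        i1 = align_step + int(round(self.end / dt))
        if i0 < 0 or i1 > n_steps:
            raise IndexError(
                f"epoch {self.name} [{self.start},{self.end}) outside series support"
            )
        return slice(i0, i1)


V1 = EpochDef("V1", 0.090, 0.130)
V2 = EpochDef("V2", 0.140, 0.180)
EPOCHS = (V1, V2)


@dataclass(frozen=True)
class EpochSummary:
    """Baseline-subtracted epoch mean of the lateral control signal."""

    condition: str
    epoch: str
    mean: float
    se: float
    n_trials: int


def epoch_mean(
    control: np.ndarray,
    baseline: np.ndarray,
    epoch: EpochDef,
    align_step: int,
    dt: float,
    *,
    response_sign: float = 1.0,
    condition: str = "",
) -> EpochSummary:
    """Mean baseline-subtracted control over an epoch.

    ``control`` and ``baseline`` are (n_steps, n_trials) series on a common
    time base; the epoch window is taken relative to ``align_step`` (the
    disturbance or visualization onset) in both, and the across-trial
    baseline average is subtracted.  ``response_sign`` orients corrective
    responses positive.  The SE combines the Monte-Carlo error of both
    condition and baseline means.
    """
    control = np.atleast_2d(np.asarray(control, dtype=float))
    baseline = np.atleast_2d(np.asarray(baseline, dtype=float))
    if control.ndim != 2:
        raise ValueError("control must be (n_steps, n_trials)")
    sl = epoch.slice(align_step, dt, control.shape[0])
    epoch.slice(align_step, dt, baseline.shape[0])
    per_trial = control[sl].mean(axis=0) * response_sign
    base_trial = baseline[sl].mean(axis=0) * response_sign
    n_c, n_b = per_trial.size, base_trial.size
    mean = float(per_trial.mean() - base_trial.mean())
    se = float(
        math.sqrt(
            per_trial.var(ddof=1) / n_c + base_trial.var(ddof=1) / n_b
        )
        if n_c > 1 and n_b > 1
        else 0.0
    )
    return EpochSummary(condition=condition, epoch=epoch.name,
                        mean=mean, se=se, n_trials=n_c)


def additive_comparison(pv: EpochSummary, p: EpochSummary, v: EpochSummary) -> dict:
    """Bimodal response versus the additive sum of the unimodal responses.

    Returns the additive sum p + v, the difference (additive - pv), the
    percent excess of the additive model over the observed bimodal
    response, and a Monte-Carlo SE for the difference.  ``percent_excess``
    is flagged undefined (NaN) when the bimodal mean is zero.
    """
    if not (pv.epoch == p.epoch == v.epoch):
        raise ValueError("epoch summaries must come from the same epoch")
    additive = p.mean + v.mean
    diff = additive - pv.mean
    diff_se = math.sqrt(pv.se ** 2 + p.se ** 2 + v.se ** 2)
    if pv.mean == 0.0:
        pct = float("nan")
        undefined = True
    else:
        pct = 100.0 * diff / pv.mean
        undefined = False
    return {
        "epoch": pv.epoch,
        "pv": pv.mean,
        "additive_sum": additive,
        "difference": diff,
        "difference_se": diff_se,
        "percent_excess": pct,
        "percent_undefined": undefined,
    }


def epoch_table(results, *, n_trials: int = 1000, seed: int = 0,
                conditions=("PV_align", "P_nov", "V_shift"),
                epochs=EPOCHS) -> pd.DataFrame:
    """Tidy per-condition, per-epoch summary of baseline-subtracted control.

    Simulates each requested condition and its matching baseline (same
    background-load context and vision availability) with ``n_trials``
    noisy trials and tabulates epoch means and Monte-Carlo SEs.
    """
    fac = results.conditions()
    cfg = results.model.config
    rng = np.random.default_rng(seed)
    specs = {name: fac.make(name) for name in conditions}
    needed_baselines = {s.baseline_type for s in specs.values()}
    base_sims = {
        b: results.simulate(fac.make(b), n_trials=n_trials,
                            seed=int(rng.integers(2 ** 31)))
        for b in sorted(needed_baselines)
    }
    rows = []
    for name, spec in specs.items():
        sim = results.simulate(spec, n_trials=n_trials,
                               seed=int(rng.integers(2 ** 31)))
        for epoch in epochs:
            summ = epoch_mean(
                sim["u"], base_sims[spec.baseline_type]["u"], epoch,
                spec.align_step, cfg.dt,
                response_sign=spec.response_sign, condition=name,
            )
            rows.append({
                "condition": name, "epoch": epoch.name,
                "mean": summ.mean, "se": summ.se, "n_trials": summ.n_trials,
            })
    return pd.DataFrame(rows)


@dataclass
class VariabilityCurve:
    """Per-timepoint SD of lateral position (mean of per-cycle SDs)."""

    time: np.ndarray
    sd: np.ndarray
    sd_se: np.ndarray
    condition: str
    n_per_cycle: int
    n_cycles: int


def endpoint_variability(
    results,
    condition,
    *,
    n_per_cycle: int = 25,
    n_cycles: int = 1000,
    seed=None,
) -> VariabilityCurve:
    """Lateral-position variability protocol.

    Simulates ``n_per_cycle`` trajectories per cycle, takes the SD of
    lateral hand position at each timepoint within the cycle, and averages
    the per-cycle SD curves over ``n_cycles`` cycles.
    """
    if n_per_cycle < 2:
        raise ValueError("need at least 2 trajectories per cycle to form an SD")
    if isinstance(condition, str):
        condition = results.conditions().make(condition)
    sim = results.simulate(condition, n_trials=n_per_cycle * n_cycles, seed=seed)
    h = sim["h"].reshape(sim["h"].shape[0], n_cycles, n_per_cycle)
    per_cycle_sd = h.std(axis=2, ddof=1)           # (n_steps, n_cycles)
    sd = per_cycle_sd.mean(axis=1)
    sd_se = per_cycle_sd.std(axis=1, ddof=1) / math.sqrt(n_cycles) if n_cycles > 1 \
        else np.zeros_like(sd)
    return VariabilityCurve(
        time=sim["time"], sd=sd, sd_se=sd_se,
        condition=getattr(condition, "trial_type", str(condition)),
        n_per_cycle=n_per_cycle, n_cycles=n_cycles,
    )


def control_onset(
    mean_control: np.ndarray,
    mean_baseline: np.ndarray,
    *,
    align_step: int,
    dt: float,
    tol: float = 3.0,
    min_duration: float = 0.010,
    atol: float = 1e-9,
) -> float | None:
    """First sustained departure of the control signal from baseline.

    The threshold is ``tol`` times the pre-disturbance SD of the
    condition-baseline difference (with an absolute floor ``atol`` for
    noise-free series); the excursion must persist for ``min_duration``.
    Returns the onset time in seconds relative to the alignment step, or
    ``None`` if the difference never sustainedly exceeds the threshold.
    """
    diff = np.abs(np.asarray(mean_control, float) - np.asarray(mean_baseline, float))
    pre = diff[:align_step]
    thr = max(tol * (pre.std(ddof=1) if pre.size > 1 else 0.0), atol)
    need = max(int(round(min_duration / dt)), 1)
    above = diff[align_step:] > thr
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= need:
            return (i - need + 1) * dt
    return None


def sensitivity_sweep(
    base_cfg: PlantConfig,
    *,
    ratios=(1.15, 2.3, 4.6),
    delays=(8, 9, 10),
    n_trials: int = 500,
    seed: int = 0,
    epochs=EPOCHS,
) -> pd.DataFrame:
    """Grid sweep over visual-noise ratio and visual delay.

    Recomputes gains at every grid point and tabulates, per epoch, the
    percent change of the bimodal (PV) response relative to the no-vision
    (P) response and the percent excess of the additive model over PV.
    Rows that fail gain convergence are flagged.
    """
    from .model import ReachingModel

    rows = []
    rng = np.random.default_rng(seed)
    for ratio in ratios:
        for delay in delays:
            cfg = base_cfg.replace(vision_ratio=ratio, delta_v=delay)
            res = ReachingModel(cfg).fit()
            cell_seed = int(rng.integers(2 ** 31))
            table = epoch_table(res, n_trials=n_trials, seed=cell_seed,
                                epochs=epochs)
            for epoch in epochs:
                sub = table[table.epoch == epoch.name].set_index("condition")
                pv = sub.loc["PV_align", "mean"]
                p = sub.loc["P_nov", "mean"]
                v = sub.loc["V_shift", "mean"]
                rows.append({
                    "vision_ratio": ratio,
                    "delta_v": delay,
                    "delay_ms": delay * cfg.dt * 1000.0,
                    "epoch": epoch.name,
                    "pv": pv, "p": p, "v": v,
                    "pct_vision_increase": 100.0 * (pv - p) / p,
                    "pct_additive_excess": 100.0 * ((p + v) - pv) / pv,
                    "converged": bool(res.converged),
                })
    return pd.DataFrame(rows)


def winsorize_trim(values, trim_fraction: float = 0.10) -> tuple[np.ndarray, float]:
    """Winsorize the lowest/highest ``ceil(trim * n)`` values.

    Trimmed values are not discarded but set to the smallest/largest
    retained value; returns the winsorized vector (original order) and its
    mean.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("need at least 3 values to winsorize")
    if not 0.0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must be in [0, 0.5)")
    k = math.ceil(trim_fraction * values.size)
    out = values.copy()
    if k > 0:
        order = np.argsort(values, kind="stable")
        lo_val = values[order[k]]
        hi_val = values[order[-k - 1]]
        out[order[:k]] = lo_val
        out[order[-k:]] = hi_val
    return out, float(out.mean())
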