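"""Monte-Carlo evaluation: replicate-averaged error curves and the metrics
read off them (threshold crossings, speedup factors, variance calibration,
plateau levels, stagnation diagnosis).

Curves are conventionally read on double-logarithmic axes, so threshold
crossings are refined by log-log interpolation and plateau levels are
geometric means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import _engine
from .core import JointBelief, run_filter
from .generative import (
    ControlSpec,
    SystemParams,
    gen_gaussian_control,
    gen_sinusoidal_control,
    sample_phase,
    simulate_trajectory,
)

__all__ = [
    "MseCurves",
    "ExperimentConfig",
    "mse_curves",
    "first_crossing",
    "speedup_factor",
    "variance_calibration",
    "detect_stagnation",
    "plateau_mse",
    "NOT_REACHED",
]

#: Sentinel for "the curve never crosses the threshold".
NOT_REACHED = float("nan")


class ExperimentConfig(BaseModel):
    """One named experiment: a method, a control regime, noise levels,
    priors, replicate count and horizon.

    Defaults are the stock simulation settings: sensor-noise standard
    deviation 2, true weight 1, command period 50 steps, and the vague
    priors (mu_z=0, Sigma_zz=1e4, mu_w=0, Sigma_ww=1, Sigma_zw=0).
    """

    model_config = ConfigDict(extra="forbid")

    method: Literal[
        "piaf", "kalman", "rls", "rls_to_kalman", "kalman_rls_loop"
    ] = "piaf"
    control: Literal["sinusoidal", "gaussian"] = "sinusoidal"
    sigma_s: float = Field(default=2.0, ge=0)
    sigma_p: float = Field(default=0.0, ge=0)
    w: float = 1.0
    T: int = Field(default=50, ge=2)
    N: int = Field(default=10_000, ge=1)
    n_runs: int = Field(default=1000, ge=1)
    seed: int = 0
    thresholds: list[float] = Field(default_factory=list)
    mu_z0: float = 0.0
    Sigma_zz0: float = Field(default=1.0e4, ge=0)
    mu_w0: float = 0.0
    Sigma_ww0: float = Field(default=1.0, ge=0)
    Sigma_zw0: float = 0.0
    jitter: float = Field(default=0.0, ge=0)

    @property
    def priors_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.mu_z0, self.Sigma_zz0, self.mu_w0, self.Sigma_ww0, self.Sigma_zw0)

    def system_params(self) -> SystemParams:
        return SystemParams(w=np.array([self.w]), sigma_s=self.sigma_s,
                            sigma_p=self.sigma_p)

    def prior_belief(self) -> JointBelief:
        return JointBelief(
            mu_z=self.mu_z0,
            mu_w=np.array([self.mu_w0]),
            Sigma_zz=self.Sigma_zz0,
            Sigma_ww=np.array([[self.Sigma_ww0]]),
            Sigma_zw=np.array([self.Sigma_zw0]),
        )


@dataclass
class MseCurves:
    """Replicate-averaged per-iteration squared errors and reported variances."""

    iteration: np.ndarray
    mse_w: np.ndarray
    mse_z: np.ndarray
    est_var_w: np.ndarray
    est_var_z: np.ndarray
    n_runs: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": self.iteration,
                "mse_w": self.mse_w,
                "mse_z": self.mse_z,
                "est_var_w": self.est_var_w,
                "est_var_z": self.est_var_z,
                "n_runs": self.n_runs,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def mse_curves(
    config: ExperimentConfig, return_per_run: bool = False
) -> MseCurves | tuple[MseCurves, _engine.BatchRun]:
    """Run seeded replicates of one method on freshly simulated episodes and
    average squared errors and reported variances per iteration.

    Every replicate draws its own phase, noise realization and (for the
    random regime) command sequence from a substream of the master seed.
    """
    params = config.system_params()
    batch = _engine.simulate_batch(
        params, config.control, config.N, config.n_runs, config.seed, T=config.T
    )
    run = _engine.run_batch(
        config.method, batch, params, config.priors_tuple, jitter=config.jitter
    )
    curves = MseCurves(
        iteration=np.arange(1, config.N + 1),
        mse_w=run.se_w.mean(axis=1),
        mse_z=run.se_z.mean(axis=1),
        est_var_w=run.var_w.mean(axis=1),
        est_var_z=run.var_z.mean(axis=1),
        n_runs=config.n_runs,
    )
    if return_per_run:
        return curves, run
    return curves


def single_run(config: ExperimentConfig):
    """One reference (non-vectorized) replicate; used for inspection/export."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    phi = sample_phase(rng)
    spec = ControlSpec(regime=config.control, T=config.T, phi=phi)
    if config.control == "sinusoidal":
        controls = gen_sinusoidal_control(spec, config.N)
    else:
        controls = gen_gaussian_control(spec, config.N, rng)
    params = config.system_params()
    traj = simulate_trajectory(params, controls, z0=np.sin(phi), rng=rng)
    if config.method == "piaf":
        return traj, run_filter(params, traj, config.prior_belief(),
                                jitter=config.jitter)
    from . import baselines

    if config.method == "rls_to_kalman":
        return traj, baselines.run_rls_to_kalman(params, traj, config.prior_belief())
    if config.method == "kalman_rls_loop":
        return traj, baselines.run_kalman_rls_loop(params, traj, config.prior_belief())
    raise ValueError(f"single_run does not support method {config.method!r}")


def first_crossing(curve: np.ndarray, threshold: float) -> float:
    """First (fractional) iteration at which the curve falls to the threshold.

    Iterations are 1-based.  The crossing is refined by linear interpolation
    in log-log coordinates between the bracketing iterations, matching how
    the curves are read on double-logarithmic axes.  Returns NaN if the
    curve never reaches the threshold.
    """
    c = np.asarray(curve, dtype=float)
    if c.size == 0:
        raise ValueError("empty curve")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    below = np.nonzero(c <= threshold)[0]
    if below.size == 0:
        return NOT_REACHED
    i = int(below[0])
    if i == 0:
        return 1.0
    v0, v1 = c[i - 1], c[i]
    n0, n1 = float(i), float(i + 1)  # 1-based iterations
    if v0 <= 0 or v1 <= 0 or v0 == v1:
        return n1
    t = (math.log(threshold) - math.log(v0)) / (math.log(v1) - math.log(v0))
    return math.exp(math.log(n0) + t * (math.log(n1) - math.log(n0)))


def speedup_factor(
    curve_slow: np.ndarray, curve_fast: np.ndarray, threshold: float
) -> float:
    """How many times fewer iterations the fast curve needs to reach the
    threshold: first_crossing(slow) / first_crossing(fast).  NaN if either
    curve never crosses."""
    ns = first_crossing(curve_slow, threshold)
    nf = first_crossing(curve_fast, threshold)
    if math.isnan(ns) or math.isnan(nf):
        return NOT_REACHED
    return ns / nf


def variance_calibration(curves: MseCurves) -> pd.DataFrame:
    """Per-iteration ratio of observed squared error to reported variance.

    A well-calibrated filter has ratios near 1; ratios above 1 mean the
    filter under-estimates its error (overconfidence), below 1 that it
    over-estimates it.
    """
    if np.any(curves.est_var_z <= 0) or np.any(curves.est_var_w < 0):
        raise ValueError("non-positive estimated variance")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_w = np.where(
            curves.est_var_w > 0, curves.mse_w / curves.est_var_w, np.nan
        )
    return pd.DataFrame(
        {
            "iteration": curves.iteration,
            "ratio_z": curves.mse_z / curves.est_var_z,
            "ratio_w": ratio_w,
        }
    )


def detect_stagnation(
    curve_w_mse: np.ndarray,
    reference_floor: float,
    factor: float = 10.0,
    window: int = 100,
    eps_slope: float = 1.0e-3,
) -> tuple[bool, float]:
    """Diagnose a run whose error curve has stopped improving above the floor.

    A step counts as stagnant when the log-log slope of the curve over the
    trailing ``window`` iterations is above ``-eps_slope`` (per decade of
    iterations) *and* the curve still sits above ``factor`` times the
    achievable floor.  The run is flagged when the curve ends in a stagnant
    stretch at least ``window`` long; the onset is the first iteration of
    the final stagnant stretch.  Returns (flag, onset_iteration) with onset
    NaN when not flagged.
    """
    c = np.asarray(curve_w_mse, dtype=float)
    if window < 2:
        raise ValueError("window must be >= 2")
    if c.size <= window:
        raise ValueError("window longer than curve")
    n = np.arange(1, c.size + 1, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        logc = np.log10(np.maximum(c, 1e-300))
        slope = (logc[window:] - logc[:-window]) / (
            np.log10(n[window:]) - np.log10(n[:-window])
        )
    stagnant = (slope > -eps_slope) & (c[window:] > factor * reference_floor)
    if not stagnant[-1]:
        return False, float("nan")
    # length of the trailing all-stagnant stretch
    run_len = int(np.argmin(stagnant[::-1])) if not stagnant.all() else stagnant.size
    if run_len < window:
        return False, float("nan")
    onset_idx = stagnant.size - run_len + window  # 0-based curve index
    return True, float(onset_idx + 1)


def plateau_mse(curve: np.ndarray, trailing_fraction: float = 0.2) -> float:
    """Geometric mean of the curve over its trailing fraction of iterations."""
    c = np.asarray(curve, dtype=float)
    if c.size == 0:
        raise ValueError("empty curve")
    if not 0.0 < trailing_fraction <= 1.0:
        raise ValueError("trailing_fraction must be in (0, 1]")
    tail = c[c.size - max(int(round(trailing_fraction * c.size)), 1):]
    if np.any(tail <= 0):
        raise ValueError("plateau undefined for non-positive curve values")
    return float(np.exp(np.mean(np.log(tail))))
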