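"""Vectorized Monte-Carlo kernels for the scalar-command case.

The replicate studies need up to ~10^3 runs of ~10^5 filter iterations.  All
of them use one-dimensional commands, for which every filter in the package
reduces to a handful of scalar recursions; this module runs those recursions
with one numpy operation per quantity across all replicates at once.

These kernels are an optimization, not a second source of truth: the tests
check them step-for-step against the per-step reference implementations in
`piaf.core` and `piaf.baselines`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .baselines import RLS_RIDGE, VARIANCE_SENTINEL
from .generative import (
    ControlSpec,
    SystemParams,
    Trajectory,
    gen_gaussian_control,
    gen_sinusoidal_control,
    sample_phase,
    simulate_trajectory,
)

__all__ = ["BatchTrajectories", "BatchRun", "simulate_batch", "run_batch", "METHODS"]

METHODS = ("piaf", "kalman", "rls", "rls_to_kalman", "kalman_rls_loop")


@dataclass
class BatchTrajectories:
    """Column-per-replicate trajectory arrays: z is (N+1, R), x and qdot (N, R)."""

    z: np.ndarray
    x: np.ndarray
    qdot: np.ndarray
    phi: np.ndarray

    @property
    def N(self) -> int:
        return self.x.shape[0]

    @property
    def n_runs(self) -> int:
        return self.x.shape[1]


@dataclass
class BatchRun:
    """Per-step, per-replicate filter diagnostics, each of shape (N, R).

    ``se_z`` / ``se_w`` are squared errors of the posterior state / weight
    means against the simulated truth; ``var_z`` / ``var_w`` are the
    variances the filter itself reports.
    """

    se_z: np.ndarray
    se_w: np.ndarray
    var_z: np.ndarray
    var_w: np.ndarray


def simulate_batch(
    params: SystemParams,
    regime: str,
    N: int,
    n_runs: int,
    seed: int,
    T: int = 50,
) -> BatchTrajectories:
    """Simulate ``n_runs`` independent episodes.

    Each replicate gets its own RNG substream spawned from the master seed
    (run k is reproducible in isolation), draws its start phase uniformly on
    [0, 2*pi), starts at z_0 = sin(phi), and is simulated by the single-run
    generative code.
    """
    if params.D_q != 1:
        raise ValueError("batch kernels support scalar commands only (D_q = 1)")
    z = np.empty((N + 1, n_runs))
    x = np.empty((N, n_runs))
    q = np.empty((N, n_runs))
    phis = np.empty(n_runs)
    children = np.random.SeedSequence(seed).spawn(n_runs)
    for k, child in enumerate(children):
        rng = np.random.default_rng(child)
        phi = sample_phase(rng)
        spec = ControlSpec(regime=regime, T=T, phi=phi)
        if regime == "sinusoidal":
            controls = gen_sinusoidal_control(spec, N)
        else:
            controls = gen_gaussian_control(spec, N, rng)
        traj = simulate_trajectory(params, controls, z0=np.sin(phi), rng=rng)
        z[:, k] = traj.z
        x[:, k] = traj.x
        q[:, k] = traj.qdot[:, 0]
        phis[k] = phi
    return BatchTrajectories(z=z, x=x, qdot=q, phi=phis)


def trajectory_of(batch: BatchTrajectories, k: int) -> Trajectory:
    """Extract replicate k as a single-run Trajectory."""
    return Trajectory(
        z=batch.z[:, k], x=batch.x[:, k], qdot=batch.qdot[:, k], phi=batch.phi[k]
    )


def _alloc(N: int, R: int) -> BatchRun:
    return BatchRun(
        se_z=np.empty((N, R)),
        se_w=np.empty((N, R)),
        var_z=np.empty((N, R)),
        var_w=np.empty((N, R)),
    )


def _run_joint(
    batch: BatchTrajectories,
    params: SystemParams,
    priors: tuple[float, float, float, float, float],
    decoupled: bool,
    jitter: float,
) -> BatchRun:
    """PIAF (decoupled=False) or the modified-recursion RLS (decoupled=True).

    The RLS variant zeroes the incoming cross-covariance in the prediction
    and fuses with the inflated noise variance 2*sigma_s^2.
    """
    N, R = batch.N, batch.n_runs
    w_true = params.w[0]
    sp2 = params.sigma_p**2
    ss2 = params.sigma_s**2
    ss2_eff = 2.0 * ss2 if decoupled else ss2
    mu_z0, Szz0, mu_w0, Sww0, Szw0 = priors
    mu_z = np.full(R, mu_z0)
    mu_w = np.full(R, mu_w0)
    S_zz = np.full(R, Szz0)
    S_ww = np.full(R, Sww0)
    S_zw = np.full(R, Szw0)
    out = _alloc(N, R)
    for n in range(N):
        q = batch.qdot[n]
        x = batch.x[n]
        # predict
        mu_z = mu_z + q * mu_w
        if decoupled:
            S_zz = S_zz + sp2 + q * q * S_ww + jitter
            S_zw = q * S_ww
        else:
            S_zz = S_zz + sp2 + q * q * S_ww + 2.0 * S_zw * q + jitter
            S_zw = S_zw + q * S_ww
        # update
        S = ss2_eff + S_zz
        r = x - mu_z
        mu_z = mu_z + S_zz / S * r
        mu_w = mu_w + S_zw / S * r
        S_ww = S_ww - S_zw * S_zw / S
        S_zz = ss2_eff * S_zz / S
        S_zw = ss2_eff / S * S_zw
        out.se_z[n] = (mu_z - batch.z[n + 1]) ** 2
        out.se_w[n] = (mu_w - w_true) ** 2
        out.var_z[n] = S_zz
        out.var_w[n] = S_ww
    return out


def _run_kalman_known_w(
    batch: BatchTrajectories,
    params: SystemParams,
    priors: tuple[float, float, float, float, float],
) -> BatchRun:
    """Kalman filter given the true weight (the performance reference)."""
    N, R = batch.N, batch.n_runs
    w_true = params.w[0]
    sp2, ss2 = params.sigma_p**2, params.sigma_s**2
    mu_z = np.full(R, priors[0])
    S_zz = np.full(R, priors[1])
    out = _alloc(N, R)
    for n in range(N):
        q = batch.qdot[n]
        mu_z = mu_z + q * w_true
        S_zz = S_zz + sp2
        S = ss2 + S_zz
        Ssafe = np.where(S > 0.0, S, 1.0)  # S == 0: noiseless, nothing to fuse
        mu_z = mu_z + np.where(S > 0.0, S_zz / Ssafe * (batch.x[n] - mu_z), 0.0)
        S_zz = np.where(S > 0.0, ss2 * S_zz / Ssafe, S_zz)
        out.se_z[n] = (mu_z - batch.z[n + 1]) ** 2
        out.se_w[n] = 0.0
        out.var_z[n] = S_zz
        out.var_w[n] = 0.0
    return out


def _run_coupled(
    batch: BatchTrajectories,
    params: SystemParams,
    priors: tuple[float, float, float, float, float],
    closed_loop: bool,
) -> BatchRun:
    """RLS→Kalman (open) or Kalman↔RLS (closed feedback loop).

    Scalar specialization of `piaf.baselines._run_coupled`: RLS in
    information form with ridge and the OLS standard-error variance;
    the Kalman prediction variance is inflated by q^2 * sigma_w^2.
    """
    N, R = batch.N, batch.n_runs
    w_true = params.w[0]
    sp2, ss2 = params.sigma_p**2, params.sigma_s**2
    mu_z0, Szz0, mu_w0, Sww0, _ = priors
    mu_z = np.full(R, mu_z0)
    S_zz = np.full(R, Szz0)
    mu_w = np.full(R, mu_w0)
    var_w = np.full(R, Sww0)
    A = np.zeros(R)
    b = np.zeros(R)
    Syy = np.zeros(R)
    out = _alloc(N, R)
    prev = None
    for n in range(N):
        q = batch.qdot[n]
        x = batch.x[n]
        mu_z = mu_z + q * mu_w
        S_zz = S_zz + sp2 + q * q * var_w
        # S == 0 only in the noiseless degenerate case; skip the (vacuous) fuse
        S = ss2 + S_zz
        Ssafe = np.where(S > 0.0, S, 1.0)
        mu_z = mu_z + np.where(S > 0.0, S_zz / Ssafe * (x - mu_z), 0.0)
        S_zz = np.where(S > 0.0, ss2 * S_zz / Ssafe, S_zz)
        cur = x if not closed_loop else mu_z
        if prev is not None:
            y = cur - prev
            A = A + q * q
            b = b + q * y
            Syy = Syy + y * y
            mu_w = b / (A + RLS_RIDGE)
            rss = np.maximum(Syy - b * mu_w, 0.0)
            n_obs = n  # pairs seen so far (first pair arrives at n == 1)
            if n_obs >= 2:
                var_w = rss / (n_obs - 1) / (A + RLS_RIDGE)
            else:
                var_w = np.full(R, VARIANCE_SENTINEL)
        prev = cur
        out.se_z[n] = (mu_z - batch.z[n + 1]) ** 2
        out.se_w[n] = (mu_w - w_true) ** 2
        out.var_z[n] = S_zz
        out.var_w[n] = var_w
    return out


def run_batch(
    method: str,
    batch: BatchTrajectories,
    params: SystemParams,
    priors: tuple[float, float, float, float, float] = (0.0, 1.0e4, 0.0, 1.0, 0.0),
    jitter: float = 0.0,
) -> BatchRun:
    """Run one filtering method over all replicates of a batch.

    ``priors`` is (mu_z, Sigma_zz, mu_w, Sigma_ww, Sigma_zw) at step 0.
    """
    if method == "piaf":
        return _run_joint(batch, params, priors, decoupled=False, jitter=jitter)
    if method == "rls":
        return _run_joint(batch, params, priors, decoupled=True, jitter=jitter)
    if method == "kalman":
        return _run_kalman_known_w(batch, params, priors)
    if method == "rls_to_kalman":
        return _run_coupled(batch, params, priors, closed_loop=False)
    if method == "kalman_rls_loop":
        return _run_coupled(batch, params, priors, closed_loop=True)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
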