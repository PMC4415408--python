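"""Comparison systems: known-weight Kalman filter, recursive least squares,
the augmented-state joint Kalman filter, and two ad-hoc filter/learner
couplings.

The couplings wire a classical Kalman filter (which needs a weight estimate)
to a classical RLS learner (which needs observations of state increments):

* ``run_rls_to_kalman`` — RLS regresses on differences of *raw* measurements
  and hands its weight estimate (plus an OLS standard-error variance) to the
  Kalman filter.  Safe but slow: the differenced channel carries doubled
  sensor noise.
* ``run_kalman_rls_loop`` — RLS regresses on differences of the *filtered*
  state estimates, closing a feedback loop.  Initially faster, but the
  filter's own predictions leak into the learner's data, the learner's
  residual variance collapses, and learning freezes before convergence:
  the self-delusional loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import JointBelief, measure_update, predict
from .generative import SystemParams, Trajectory

__all__ = [
    "KalmanBelief",
    "RlsState",
    "kalman_step",
    "rls_modified_piaf_step",
    "classical_rls_step",
    "joint_kalman_step",
    "run_rls_to_kalman",
    "run_kalman_rls_loop",
    "CoupledRun",
]

#: Reported weight variance while the least-squares problem is not yet
#: identifiable (fewer residual degrees of freedom than parameters).
VARIANCE_SENTINEL = 1.0e12

#: Ridge on the information matrix so the normal equations are solvable
#: before D_q independent observations have arrived.
RLS_RIDGE = 1.0e-8


@dataclass
class KalmanBelief:
    """State-only Gaussian belief of the known-weight Kalman filter."""

    mu_z: float
    Sigma_zz: float

    def __post_init__(self) -> None:
        if self.Sigma_zz < 0:
            raise ValueError("Sigma_zz must be >= 0")


def kalman_step(
    belief: KalmanBelief,
    qdot: np.ndarray,
    x: float,
    w_true: np.ndarray,
    sigma_p: float,
    sigma_s: float,
) -> KalmanBelief:
    """One predict/update cycle of the Kalman filter with known weights.

    Prediction: mu_z += qdot^T w, Sigma_zz += sigma_p^2.  Update: standard
    scalar Kalman correction with gain Sigma_zz / (sigma_s^2 + Sigma_zz).
    """
    q = np.atleast_1d(np.asarray(qdot, dtype=float))
    w = np.atleast_1d(np.asarray(w_true, dtype=float))
    if q.size != w.size:
        raise ValueError("command/weight dimension mismatch")
    mu = belief.mu_z + float(q @ w)
    P = belief.Sigma_zz + sigma_p**2
    S = sigma_s**2 + P
    if S <= 0.0:
        raise ValueError("degenerate update: sigma_s^2 + Sigma_zz must be > 0")
    return KalmanBelief(mu_z=mu + P / S * (x - mu), Sigma_zz=sigma_s**2 * P / S)


def rls_modified_piaf_step(
    belief: JointBelief, qdot: np.ndarray, x: float, sigma_p: float, sigma_s: float
) -> JointBelief:
    """RLS on differenced observations, written as a modified joint update.

    Differs from the Bayes-optimal recursion in exactly two places: the
    prediction discards the incoming state-weight cross-covariance
    (consecutive differenced observations are *assumed* independent), and
    the measurement update uses the inflated noise variance 2*sigma_s^2
    (each differenced observation carries two sensor-noise draws).
    """
    decoupled = JointBelief(
        mu_z=belief.mu_z,
        mu_w=belief.mu_w,
        Sigma_zz=belief.Sigma_zz,
        Sigma_ww=belief.Sigma_ww,
        Sigma_zw=np.zeros(belief.D_q),
    )
    prior = predict(decoupled, qdot, sigma_p)
    return measure_update(prior, x, sigma_s, sigma_s_sq=2.0 * sigma_s**2)


@dataclass
class RlsState:
    """Classical recursive least squares in information form.

    Accumulates the normal equations A = sum q q^T, b = sum q y and the
    observation second moment; the weight estimate is A^{-1} b (with a tiny
    ridge) and the residual sum of squares follows from the accumulators.
    """

    D_q: int = 1
    A: np.ndarray = field(default=None)  # type: ignore[assignment]
    b: np.ndarray = field(default=None)  # type: ignore[assignment]
    Syy: float = 0.0
    n_obs: int = 0

    def __post_init__(self) -> None:
        if self.A is None:
            self.A = np.zeros((self.D_q, self.D_q))
        if self.b is None:
            self.b = np.zeros(self.D_q)

    @property
    def mu_w(self) -> np.ndarray:
        """Least-squares weight estimate (ridge-regularized before
        identifiability)."""
        return np.linalg.solve(self.A + RLS_RIDGE * np.eye(self.D_q), self.b)

    @property
    def rss(self) -> float:
        """Residual sum of squares of the current least-squares fit."""
        return max(self.Syy - float(self.b @ self.mu_w), 0.0)

    @property
    def sigma_w2(self) -> np.ndarray:
        """OLS standard-error covariance s^2 (sum q q^T)^{-1} of the weight
        estimate, with s^2 = rss / (n_obs - D_q).  A large sentinel is
        returned while the residual degrees of freedom are <= 0."""
        if self.n_obs <= self.D_q:
            return VARIANCE_SENTINEL * np.eye(self.D_q)
        s2 = self.rss / (self.n_obs - self.D_q)
        return s2 * np.linalg.inv(self.A + RLS_RIDGE * np.eye(self.D_q))


def classical_rls_step(state: RlsState, qdot: np.ndarray, ydot: float) -> RlsState:
    """Feed one (command, differenced-observation) pair to RLS.

    Returns a new state; ``state.mu_w`` then equals the batch least-squares
    solution over all pairs seen so far.
    """
    q = np.atleast_1d(np.asarray(qdot, dtype=float))
    if q.size != state.D_q:
        raise ValueError("command dimension mismatch")
    return RlsState(
        D_q=state.D_q,
        A=state.A + np.outer(q, q),
        b=state.b + q * ydot,
        Syy=state.Syy + ydot**2,
        n_obs=state.n_obs + 1,
    )


def joint_kalman_step(
    aug_mean: np.ndarray,
    aug_cov: np.ndarray,
    qdot: np.ndarray,
    x: float,
    sigma_p: float,
    sigma_s: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Textbook Kalman step on the augmented state (z, w).

    Transition F = [[1, qdot^T], [0, I]], process covariance
    Q = diag(sigma_p^2, 0, ..., 0), observation H = [1, 0, ..., 0],
    measurement noise R = sigma_s^2.  Because the parameter block of Q is
    zero, the weights are carried as dynamics-free hidden states.  This is
    the independent reference recursion the explicit joint-belief updates
    must agree with.
    """
    m = np.asarray(aug_mean, dtype=float)
    P = np.asarray(aug_cov, dtype=float)
    q = np.atleast_1d(np.asarray(qdot, dtype=float))
    D = q.size
    if m.size != 1 + D or P.shape != (1 + D, 1 + D):
        raise ValueError("augmented state must have dimension 1 + D_q")
    F = np.eye(1 + D)
    F[0, 1:] = q
    Q = np.zeros((1 + D, 1 + D))
    Q[0, 0] = sigma_p**2
    H = np.zeros((1, 1 + D))
    H[0, 0] = 1.0
    # predict
    m = F @ m
    P = F @ P @ F.T + Q
    # update
    S = float((H @ P @ H.T).item()) + sigma_s**2
    if S <= 0.0:
        raise ValueError("zero innovation variance")
    K = (P @ H.T) / S
    m = m + K[:, 0] * (x - m[0])
    P = P - K @ H @ P
    P = (P + P.T) / 2.0
    return m, P


@dataclass
class CoupledRun:
    """Per-step records of a coupled filter/learner run."""

    mu_z_prior: np.ndarray
    mu_z_post: np.ndarray
    Sigma_zz_prior: np.ndarray
    Sigma_zz_post: np.ndarray
    mu_w: np.ndarray
    var_w: np.ndarray

    @property
    def N(self) -> int:
        return self.mu_z_post.size

    def to_frame(self, method: str = ""):
        import pandas as pd

        D = self.mu_w.shape[1]
        cols = {
            "step": np.arange(1, self.N + 1),
            "mu_z_prior": self.mu_z_prior,
            "mu_z_post": self.mu_z_post,
            "var_z": self.Sigma_zz_post,
        }
        for d in range(D):
            cols[f"mu_w_{d}"] = self.mu_w[:, d]
        for d in range(D):
            cols[f"var_w_{d}"] = self.var_w[:, d]
        df = pd.DataFrame(cols)
        if method:
            df.insert(0, "method", method)
        return df


def _run_coupled(
    params: SystemParams,
    trajectory: Trajectory,
    priors: JointBelief,
    learner_input: str,
) -> CoupledRun:
    """Shared loop of the two ad-hoc architectures.

    Per step: the Kalman side predicts with the learner's current weight
    estimate, inflating its prediction variance by qdot^T sigma_w^2 qdot (no
    cross-covariance is tracked); it then updates on x_n; finally RLS
    consumes one differenced pair — of raw measurements
    (``learner_input="measurements"``) or of consecutive Kalman posterior
    means (``learner_input="estimates"``).  Differencing needs two samples,
    so the learner receives nothing at n = 1 and the Kalman side starts from
    the learner's prior.
    """
    N, D = trajectory.N, params.D_q
    rls = RlsState(D_q=D)
    mu_w, cov_w = priors.mu_w.copy(), priors.Sigma_ww.copy()
    mu_z, Szz = priors.mu_z, priors.Sigma_zz
    ss2 = params.sigma_s**2
    out = CoupledRun(
        mu_z_prior=np.empty(N),
        mu_z_post=np.empty(N),
        Sigma_zz_prior=np.empty(N),
        Sigma_zz_post=np.empty(N),
        mu_w=np.empty((N, D)),
        var_w=np.empty((N, D)),
    )
    prev_input = None  # x_{n-1} or mu_z_post_{n-1}
    for n in range(N):
        q = trajectory.qdot[n]
        x = trajectory.x[n]
        # Kalman predict with the learner's current estimate
        mu_z = mu_z + float(q @ mu_w)
        Szz = Szz + params.sigma_p**2 + float(q @ cov_w @ q)
        out.mu_z_prior[n] = mu_z
        out.Sigma_zz_prior[n] = Szz
        # Kalman update; S == 0 only when prediction and measurement are both
        # exact (noiseless degenerate case) — nothing to fuse then
        S = ss2 + Szz
        if S > 0.0:
            mu_z = mu_z + Szz / S * (x - mu_z)
            Szz = ss2 * Szz / S
        out.mu_z_post[n] = mu_z
        out.Sigma_zz_post[n] = Szz
        # learner update on the differenced channel
        cur_input = x if learner_input == "measurements" else mu_z
        if prev_input is not None:
            rls = classical_rls_step(rls, q, cur_input - prev_input)
            mu_w = rls.mu_w
            cov_w = rls.sigma_w2
        prev_input = cur_input
        out.mu_w[n] = mu_w
        out.var_w[n] = np.diag(cov_w)
    return out


def run_rls_to_kalman(
    params: SystemParams, trajectory: Trajectory, priors: JointBelief | None = None
) -> CoupledRun:
    """RLS on raw measurement differences feeding a Kalman filter."""
    if priors is None:
        priors = JointBelief.default_prior(params.D_q)
    return _run_coupled(params, trajectory, priors, "measurements")


def run_kalman_rls_loop(
    params: SystemParams, trajectory: Trajectory, priors: JointBelief | None = None
) -> CoupledRun:
    """Closed loop: RLS learns from differences of the Kalman-filtered means."""
    if priors is None:
        priors = JointBelief.default_prior(params.D_q)
    return _run_coupled(params, trajectory, priors, "estimates")
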