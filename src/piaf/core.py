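"""The PIAF filter: joint Gaussian belief over (state, forward model).

The belief is a joint Gaussian over the scalar state ``z`` and the weight
vector ``w`` of the linear forward model, parameterized by its means and the
blocks of its covariance:

    [[Sigma_zz, Sigma_zw],
     [Sigma_zw^T, Sigma_ww]]

Each filter iteration is a *prediction* step, which pushes the belief through
the state transition using the known motor command (leaving the weight
marginal untouched — issuing a command reveals nothing about the weights),
and a *measurement update*, which conditions the joint belief on the noisy
observation.  Because the cross-covariance Sigma_zw is carried along, the
state prediction error also updates the weight estimate, and uncertainty
about the weights inflates the state prediction variance.  The recursion is
algebraically a Kalman filter on the augmented state (z, w) with
dynamics-free parameters, but with the state/parameter interaction written
out explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .generative import SystemParams, Trajectory

logger = logging.getLogger(__name__)

__all__ = ["JointBelief", "predict", "measure_update", "run_filter", "FilterRun"]


@dataclass
class JointBelief:
    """Sufficient statistics of the joint Gaussian belief over (z, w)."""

    mu_z: float
    mu_w: np.ndarray
    Sigma_zz: float
    Sigma_ww: np.ndarray
    Sigma_zw: np.ndarray

    def __post_init__(self) -> None:
        self.mu_w = np.atleast_1d(np.asarray(self.mu_w, dtype=float))
        self.Sigma_ww = np.atleast_2d(np.asarray(self.Sigma_ww, dtype=float))
        self.Sigma_zw = np.atleast_1d(np.asarray(self.Sigma_zw, dtype=float))
        D = self.mu_w.size
        if self.Sigma_ww.shape != (D, D) or self.Sigma_zw.size != D:
            raise ValueError("inconsistent belief dimensions")

    @property
    def D_q(self) -> int:
        return self.mu_w.size

    def joint_mean(self) -> np.ndarray:
        return np.concatenate([[self.mu_z], self.mu_w])

    def joint_cov(self) -> np.ndarray:
        D = self.D_q
        P = np.empty((1 + D, 1 + D))
        P[0, 0] = self.Sigma_zz
        P[0, 1:] = self.Sigma_zw
        P[1:, 0] = self.Sigma_zw
        P[1:, 1:] = self.Sigma_ww
        return P

    def min_eig_margin(self) -> float:
        """Smallest eigenvalue of the joint covariance, scaled by its trace.

        Nonnegative up to roundoff for a valid belief.
        """
        P = self.joint_cov()
        tr = float(np.trace(P))
        if tr == 0.0:
            return 0.0
        return float(np.linalg.eigvalsh(P)[0]) / tr

    def validate(self, tol: float = 1e-9) -> None:
        if self.Sigma_zz < 0:
            raise ValueError("Sigma_zz must be >= 0")
        if not np.allclose(self.Sigma_ww, self.Sigma_ww.T):
            raise ValueError("Sigma_ww must be symmetric")
        if self.min_eig_margin() < -tol:
            raise ValueError("joint covariance is not positive semidefinite")

    @classmethod
    def default_prior(cls, D_q: int = 1) -> "JointBelief":
        """Vague standard prior: mu_z=0, Sigma_zz=1e4 (range of the unknown
        signal), mu_w=0, Sigma_ww=I (commands and signal share scale),
        Sigma_zw=0."""
        return cls(
            mu_z=0.0,
            mu_w=np.zeros(D_q),
            Sigma_zz=1.0e4,
            Sigma_ww=np.eye(D_q),
            Sigma_zw=np.zeros(D_q),
        )


def predict(
    belief: JointBelief, qdot: np.ndarray, sigma_p: float, jitter: float = 0.0
) -> JointBelief:
    """Prediction step: push the belief through one state transition.

    With command q the moments move as

        mu_z     <- mu_z + q^T mu_w
        Sigma_zz <- Sigma_zz + sigma_p^2 + q^T Sigma_ww q + 2 Sigma_zw q
        Sigma_zw <- Sigma_zw + q^T Sigma_ww

    while mu_w and Sigma_ww are unchanged.  The state prediction variance
    absorbs both process noise and weight uncertainty (including the cross
    term, which may be negative).
    """
    q = np.atleast_1d(np.asarray(qdot, dtype=float))
    if q.size != belief.D_q:
        raise ValueError("command dimension mismatch")
    Sww_q = belief.Sigma_ww @ q
    Sigma_zz = (
        belief.Sigma_zz
        + sigma_p**2
        + float(q @ Sww_q)
        + 2.0 * float(belief.Sigma_zw @ q)
        + jitter
    )
    return JointBelief(
        mu_z=belief.mu_z + float(q @ belief.mu_w),
        mu_w=belief.mu_w.copy(),
        Sigma_zz=Sigma_zz,
        Sigma_ww=belief.Sigma_ww.copy(),
        Sigma_zw=belief.Sigma_zw + Sww_q,
    )


def measure_update(
    prior: JointBelief, x: float, sigma_s: float, *, sigma_s_sq: float | None = None
) -> JointBelief:
    """Measurement update: condition the joint belief on x = z + noise.

    With innovation variance S = sigma_s^2 + Sigma_zz and prediction error
    r = x - mu_z:

        mu_z     <- mu_z + (Sigma_zz / S) r
        Sigma_zz <- sigma_s^2 Sigma_zz / S
        Sigma_zw <- (sigma_s^2 / S) Sigma_zw
        mu_w     <- mu_w + (Sigma_zw^T / S) r
        Sigma_ww <- Sigma_ww - Sigma_zw^T Sigma_zw / S

    The same scalar prediction error drives both the state correction
    (through the Kalman gain) and the weight correction (through the
    cross-covariance).  ``sigma_s_sq`` overrides sigma_s^2; the
    independence-assuming recursive-least-squares variant passes the
    inflated value 2*sigma_s^2 here.

    Sigma_ww is re-symmetrized after the rank-one downdate: the update is
    symmetric in exact arithmetic but drifts in floating point.
    """
    ss2 = sigma_s**2 if sigma_s_sq is None else float(sigma_s_sq)
    S = ss2 + prior.Sigma_zz
    if S <= 0.0:
        raise ValueError("degenerate update: sigma_s^2 + Sigma_zz must be > 0")
    r = x - prior.mu_z
    Sigma_ww = prior.Sigma_ww - np.outer(prior.Sigma_zw, prior.Sigma_zw) / S
    Sigma_ww = (Sigma_ww + Sigma_ww.T) / 2.0
    return JointBelief(
        mu_z=prior.mu_z + prior.Sigma_zz / S * r,
        mu_w=prior.mu_w + prior.Sigma_zw / S * r,
        Sigma_zz=ss2 * prior.Sigma_zz / S,
        Sigma_ww=Sigma_ww,
        Sigma_zw=ss2 / S * prior.Sigma_zw,
    )


@dataclass
class FilterRun:
    """Per-step prior (n|n-1) and posterior (n|n) statistics of one run.

    Priors are retained because residual-based metrics need the
    pre-measurement state estimate.  ``n_variance_drops`` counts prediction
    steps whose state variance grew by less than sigma_p^2 (possible when
    the cross term 2 Sigma_zw q is negative); such steps are legal and only
    logged.
    """

    mu_z_prior: np.ndarray
    mu_z_post: np.ndarray
    Sigma_zz_prior: np.ndarray
    Sigma_zz_post: np.ndarray
    mu_w: np.ndarray
    Sigma_ww: np.ndarray
    Sigma_zw: np.ndarray
    n_variance_drops: int = 0
    final: JointBelief | None = field(default=None, repr=False)

    @property
    def N(self) -> int:
        return self.mu_z_post.size

    def to_frame(self):
        import pandas as pd

        D = self.mu_w.shape[1]
        cols = {
            "step": np.arange(1, self.N + 1),
            "mu_z_prior": self.mu_z_prior,
            "mu_z_post": self.mu_z_post,
            "Sigma_zz_prior": self.Sigma_zz_prior,
            "Sigma_zz_post": self.Sigma_zz_post,
        }
        for d in range(D):
            cols[f"mu_w_{d}"] = self.mu_w[:, d]
        for d in range(D):
            cols[f"Sigma_ww_{d}"] = self.Sigma_ww[:, d, d]
        for d in range(D):
            cols[f"Sigma_zw_{d}"] = self.Sigma_zw[:, d]
        return pd.DataFrame(cols)


def run_filter(
    params: SystemParams,
    trajectory: Trajectory,
    priors: JointBelief | None = None,
    jitter: float = 0.0,
) -> FilterRun:
    """Run the full predict/update recursion over a trajectory.

    One iteration per step n = 1..N: predict with qdot_n, then update with
    x_n.  Returns both the prior and posterior statistics of every step.
    """
    if priors is None:
        priors = JointBelief.default_prior(trajectory.D_q)
    if trajectory.D_q != params.D_q or priors.D_q != params.D_q:
        raise ValueError("dimension mismatch between params, trajectory and priors")
    N, D = trajectory.N, params.D_q
    out = FilterRun(
        mu_z_prior=np.empty(N),
        mu_z_post=np.empty(N),
        Sigma_zz_prior=np.empty(N),
        Sigma_zz_post=np.empty(N),
        mu_w=np.empty((N, D)),
        Sigma_ww=np.empty((N, D, D)),
        Sigma_zw=np.empty((N, D)),
    )
    belief = priors
    drops = 0
    for n in range(N):
        post_var = belief.Sigma_zz
        belief = predict(belief, trajectory.qdot[n], params.sigma_p, jitter=jitter)
        if belief.Sigma_zz < post_var + params.sigma_p**2:
            drops += 1
        out.mu_z_prior[n] = belief.mu_z
        out.Sigma_zz_prior[n] = belief.Sigma_zz
        belief = measure_update(belief, trajectory.x[n], params.sigma_s)
        out.mu_z_post[n] = belief.mu_z
        out.Sigma_zz_post[n] = belief.Sigma_zz
        out.mu_w[n] = belief.mu_w
        out.Sigma_ww[n] = belief.Sigma_ww
        out.Sigma_zw[n] = belief.Sigma_zw
    if drops:
        logger.debug(
            "%d/%d prediction steps grew the state variance by less than "
            "sigma_p^2 (negative cross term)",
            drops,
            N,
        )
    out.n_variance_drops = drops
    out.final = belief
    return out
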