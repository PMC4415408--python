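"""Generative system model and synthetic trajectory simulation.

The world is a scalar latent state ``z`` driven by known motor commands
``qdot`` through an unknown linear forward model ``w``:

    z_n = z_{n-1} + qdot_n^T w + eps_p,    eps_p ~ N(0, sigma_p^2)
    x_n = z_n + eps_s,                      eps_s ~ N(0, sigma_s^2)

Commands are D_q-dimensional vectors; all the stock experiments use the
scalar case D_q = 1 with either a sinusoidal command sequence
``qdot_n = omega * cos(omega * n + phi)`` (so the noise-free state is a unit
sinusoid) or i.i.d. Gaussian commands with matching mean and variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "SystemParams",
    "ControlSpec",
    "Trajectory",
    "gen_sinusoidal_control",
    "gen_gaussian_control",
    "simulate_trajectory",
    "mse_snr",
]


@dataclass(frozen=True)
class SystemParams:
    """True parameters of the simulated world.

    Parameters
    ----------
    w
        Command-to-state weight vector, length ``D_q`` (dimensionless).
    sigma_s
        Sensor-noise standard deviation (state units).
    sigma_p
        Process-noise standard deviation (state units).
    """

    w: np.ndarray
    sigma_s: float
    sigma_p: float

    def __post_init__(self) -> None:
        w = np.atleast_1d(np.asarray(self.w, dtype=float))
        if w.ndim != 1 or w.size < 1:
            raise ValueError("w must be a non-empty 1-D vector")
        object.__setattr__(self, "w", w)
        if self.sigma_s < 0 or self.sigma_p < 0:
            raise ValueError("noise standard deviations must be >= 0")

    @property
    def D_q(self) -> int:
        return self.w.size


@dataclass(frozen=True)
class ControlSpec:
    """Which command regime to simulate.

    ``sinusoidal`` produces the deterministic sequence
    ``omega * cos(omega * n + phi)``; ``gaussian`` draws each command
    component i.i.d. from N(0, omega^2 / 2), which has the same mean and
    variance as the sinusoid.  ``phi`` also fixes the initial state through
    ``z_0 = sin(phi)``.
    """

    regime: Literal["sinusoidal", "gaussian"] = "sinusoidal"
    T: int = 50
    phi: float = 0.0

    def __post_init__(self) -> None:
        if self.regime not in ("sinusoidal", "gaussian"):
            raise ValueError(f"unknown control regime {self.regime!r}")
        if self.T < 2:
            raise ValueError("period T must be >= 2 steps")

    @property
    def omega(self) -> float:
        """Angular frequency 2*pi/T in radians per step."""
        return 2.0 * np.pi / self.T


@dataclass
class Trajectory:
    """One simulated episode.

    ``z`` holds the latent states at indices 0..N, ``x`` the measurements and
    ``qdot`` the commands at indices 1..N (stored at array offsets 0..N-1).
    """

    z: np.ndarray
    x: np.ndarray
    qdot: np.ndarray
    phi: float | None = field(default=None)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.qdot = np.atleast_2d(np.asarray(self.qdot, dtype=float))
        if self.qdot.shape[0] == 1 and self.x.size > 1:
            self.qdot = self.qdot.T
        if self.z.size != self.x.size + 1 or self.qdot.shape[0] != self.x.size:
            raise ValueError("inconsistent lengths: need |z| == N+1, |x| == |qdot| == N")

    @property
    def N(self) -> int:
        return self.x.size

    @property
    def D_q(self) -> int:
        return self.qdot.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = {"step": np.arange(1, self.N + 1), "z": self.z[1:], "x": self.x}
        for d in range(self.D_q):
            cols[f"qdot_{d}"] = self.qdot[:, d]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _as_commands(controls: np.ndarray) -> np.ndarray:
    q = np.asarray(controls, dtype=float)
    if q.ndim == 1:
        q = q[:, None]
    if q.ndim != 2 or q.shape[0] < 1:
        raise ValueError("controls must be a non-empty (N,) or (N, D_q) array")
    return q


def gen_sinusoidal_control(spec: ControlSpec, N: int) -> np.ndarray:
    """Deterministic scalar command sequence qdot_n = omega*cos(omega*n + phi).

    Returns an (N, 1) array for steps n = 1..N.  Integrated with w = 1 and no
    process noise, these commands keep the state on (approximately) the unit
    sinusoid sin(omega*n + phi).
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if spec.regime != "sinusoidal":
        raise ValueError("spec.regime must be 'sinusoidal'")
    n = np.arange(1, N + 1)
    return (spec.omega * np.cos(spec.omega * n + spec.phi))[:, None]


def gen_gaussian_control(
    spec: ControlSpec, N: int, rng: np.random.Generator, D_q: int = 1
) -> np.ndarray:
    """i.i.d. Gaussian commands, mean 0, variance omega^2/2 per component.

    Mean and variance match the sinusoidal regime (a cosine of amplitude
    omega has mean square omega^2/2), so the two regimes inject the same
    average command power.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    return rng.normal(0.0, spec.omega / np.sqrt(2.0), size=(N, D_q))


def simulate_trajectory(
    params: SystemParams,
    controls: np.ndarray,
    z0: float,
    rng: np.random.Generator,
) -> Trajectory:
    """Run the system forward under a given command sequence.

    The state follows ``z_n = z_{n-1} + qdot_n^T w + eps_p`` and each
    measurement is ``x_n = z_n + eps_s``.
    """
    q = _as_commands(controls)
    if q.shape[1] != params.D_q:
        raise ValueError(
            f"command dimension {q.shape[1]} != weight dimension {params.D_q}"
        )
    N = q.shape[0]
    drift = q @ params.w
    eps_p = rng.normal(0.0, params.sigma_p, size=N) if params.sigma_p > 0 else 0.0
    z = np.empty(N + 1)
    z[0] = z0
    z[1:] = z0 + np.cumsum(drift + eps_p)
    eps_s = rng.normal(0.0, params.sigma_s, size=N) if params.sigma_s > 0 else 0.0
    x = z[1:] + eps_s
    return Trajectory(z=z, x=x, qdot=q)


def sample_phase(rng: np.random.Generator) -> float:
    """Draw a start phase uniformly on [0, 2*pi); z_0 = sin(phi) pairs with it."""
    return float(rng.uniform(0.0, 2.0 * np.pi))


def mse_snr(
    signal: np.ndarray,
    sigma_s: float,
    sigma_p: float = 0.0,
    channel: Literal["state", "difference"] = "state",
) -> float:
    """Noise-to-signal mean-square ratio for a measurement channel.

    ``signal`` is the noise-free latent trajectory for the channel of
    interest.  On the ``state`` channel (x vs z) the noise variance is
    sigma_s^2.  On the ``difference`` channel (xdot = x_n - x_{n-1} vs
    zdot) consecutive measurements share a sensor-noise term, so the
    per-observation noise variance is 2*sigma_s^2 + sigma_p^2 while the
    signal is the command-driven increment — this is why differenced
    observations are so much noisier than raw ones.
    """
    s = np.asarray(signal, dtype=float)
    if channel == "state":
        power = float(np.mean(s**2))
        noise = sigma_s**2
    elif channel == "difference":
        d = np.diff(s)
        if d.size == 0:
            raise ValueError("difference channel needs at least 2 signal samples")
        power = float(np.mean(d**2))
        noise = 2.0 * sigma_s**2 + sigma_p**2
    else:
        raise ValueError(f"unknown channel {channel!r}")
    if power == 0.0:
        raise ValueError("zero signal power")
    return noise / power
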