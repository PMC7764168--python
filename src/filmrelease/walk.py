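"""Isotropic 3-D random walks and Einstein mean-squared-displacement analysis.

Molecular diffusion can be pictured as a sequence of hops: a molecule sits
in a cage of surrounding chains for most of the time and occasionally jumps
a fixed distance in a random direction.  For such an isotropic fixed-step
walk the ensemble mean squared displacement grows exactly linearly,
``MSD(n steps) = n * l^2``, and Einstein's relation in three dimensions,

    <|r - r0|^2> = 6 D t,

identifies the diffusion coefficient as ``D = l^2 / (6 dt)`` where ``dt`` is
the mean time per hop.  This module simulates the walk, computes the MSD
from the origin and recovers D by a through-origin fit — a self-consistency
check of the diffusion picture underlying the release model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DomainError

__all__ = ["WalkEnsemble", "MsdSeries", "simulate_walk", "msd",
           "estimate_D_from_msd"]


@dataclass(frozen=True)
class WalkEnsemble:
    """Trajectories of N walkers: positions[k, i] is walker i after k steps.

    Shape (T+1, N, 3); every walker starts at the origin (positions[0] = 0).
    """

    positions: np.ndarray
    dt: float
    step_length: float

    def __post_init__(self):
        p = np.asarray(self.positions, dtype=float)
        if p.ndim != 3 or p.shape[2] != 3 or p.shape[0] < 2 or p.shape[1] < 1:
            raise DomainError(
                "positions must have shape (T+1 >= 2, N >= 1, 3)"
            )
        if not self.dt > 0:
            raise DomainError(f"dt must be > 0, got {self.dt}")
        object.__setattr__(self, "positions", p)

    @property
    def n_walkers(self) -> int:
        return self.positions.shape[1]

    @property
    def n_steps(self) -> int:
        return self.positions.shape[0] - 1


@dataclass(frozen=True)
class MsdSeries:
    """Mean squared displacement from the origin at each lag time."""

    lag_times: np.ndarray
    msd: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.lag_times, dtype=float)
        m = np.asarray(self.msd, dtype=float)
        if t.shape != m.shape or t.ndim != 1 or t.size < 2:
            raise DomainError("lag_times and msd must be equal-length (>= 2)")
        if np.any(m < 0):
            raise DomainError("msd must be >= 0")
        object.__setattr__(self, "lag_times", t)
        object.__setattr__(self, "msd", m)


def simulate_walk(n_walkers: int, n_steps: int, step_length: float,
                  dt: float, seed: int) -> WalkEnsemble:
    """Simulate N independent fixed-step walks with uniform random directions.

    Directions are drawn as normalised 3-D Gaussians (uniform on the unit
    sphere); each hop has length ``step_length`` and takes ``dt`` seconds.
    Bit-reproducible for a fixed seed.
    """
    if n_walkers < 1 or n_steps < 1:
        raise DomainError("need n_walkers >= 1 and n_steps >= 1")
    if step_length < 0:
        raise DomainError("step_length must be >= 0")
    if not dt > 0:
        raise DomainError("dt must be > 0")
    rng = np.random.default_rng(seed)
    steps = rng.standard_normal((n_steps, n_walkers, 3))
    norms = np.linalg.norm(steps, axis=-1, keepdims=True)
    np.maximum(norms, np.finfo(float).tiny, out=norms)  # zero-vector guard
    steps *= step_length / norms
    positions = np.empty((n_steps + 1, n_walkers, 3))
    positions[0] = 0.0
    np.cumsum(steps, axis=0, out=positions[1:])
    return WalkEnsemble(positions=positions, dt=dt, step_length=step_length)


def msd(ensemble: WalkEnsemble) -> MsdSeries:
    """Ensemble MSD from the starting position at every lag.

    msd(k dt) = (1/N) sum_i |r_i(k) - r_i(0)|^2; msd(0) = 0 exactly.
    """
    disp = ensemble.positions - ensemble.positions[0]
    sq = np.einsum("kij,kij->k", disp, disp) / ensemble.n_walkers
    sq[0] = 0.0
    lags = np.arange(ensemble.n_steps + 1) * ensemble.dt
    return MsdSeries(lag_times=lags, msd=sq)


def estimate_D_from_msd(series: MsdSeries) -> float:
    """Diffusion coefficient from the Einstein relation MSD = 6 D t.

    A through-origin least-squares slope over the positive lags, divided by
    six.  A non-positive slope (possible only for pathological input) warns
    and returns 0.
    """
    mask = series.lag_times > 0
    if np.count_nonzero(mask) < 1:
        raise DomainError("need at least one positive lag time")
    t = series.lag_times[mask]
    m = series.msd[mask]
    slope = float(t @ m) / float(t @ t)
    if slope <= 0:
        warnings.warn("non-positive MSD slope; returning D = 0", stacklevel=2)
        return 0.0
    return slope / 6.0
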