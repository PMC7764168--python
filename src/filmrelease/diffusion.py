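"""Plane-sheet Fickian release kinetics for one-way release from a film.

A film of thickness ``d_p`` (cm) is loaded uniformly with a diffusant and
exposed to a perfect-sink solvent on one face, the other face being
impermeable (the "one-way release" configuration).  The cumulative released
fraction follows the classical series solution of Fick's second law,

    M_t / M_inf = 1 - sum_{n=0}^inf 8 / ((2n+1)^2 pi^2)
                      * exp(-(2n+1)^2 pi^2 D t / (4 d_p^2)),

which depends on ``(D, d_p, t)`` only through the dimensionless time
``tau = D t / d_p^2``.  The ``4 d_p^2`` denominator reflects the one-exposed-
face geometry: the full thickness plays the role of the half-thickness of a
doubly exposed sheet.

All quantities are in cm, s and cm^2/s internally; millimetre thicknesses
are converted at the I/O boundary (:func:`FilmGeometry.from_mm`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import ConvergenceError, DomainError

__all__ = [
    "FilmGeometry",
    "ReleaseCurve",
    "check_diffusion_coefficient",
    "dimensionless_time",
    "release_fraction",
    "release_fraction_tau",
    "release_curve",
    "time_to_fraction",
    "half_release_time",
    "HALF_RELEASE_TAU",
]

_PI2 = math.pi**2

#: Default series-truncation tolerance: terms below this magnitude are dropped.
TERM_TOL = 1e-14

#: Below this tau the short-time law (2/sqrt(pi)) sqrt(tau) is used instead of
#: the exponential series, whose convergence degrades as tau -> 0.  At the
#: cutoff the two representations agree far beyond double precision.
SMALL_TAU_CUTOFF = 1e-6

#: Hard cap on the number of series terms.
MAX_TERMS = 10**6

#: Dimensionless half-release time of the one-way plane sheet (root of the
#: series at fraction 1/2, to five figures).
HALF_RELEASE_TAU = 0.19676

#: Plausibility window for diffusion coefficients in polymer films (cm^2/s).
D_PLAUSIBLE_RANGE = (1e-14, 1e-4)


def check_diffusion_coefficient(D: float, *, plausible=D_PLAUSIBLE_RANGE) -> float:
    """Validate a diffusion coefficient (cm^2/s).

    Raises :class:`DomainError` if non-positive; warns if outside the
    plausible range for diffusion in packaging films.
    """
    D = float(D)
    if not D > 0:
        raise DomainError(f"diffusion coefficient must be > 0, got {D}")
    lo, hi = plausible
    if not lo <= D <= hi:
        warnings.warn(
            f"D = {D:g} cm^2/s lies outside the plausible range "
            f"[{lo:g}, {hi:g}] cm^2/s",
            stacklevel=2,
        )
    return D


@dataclass(frozen=True)
class FilmGeometry:
    """Film thickness, optionally split into two layers.

    Parameters
    ----------
    d_p
        Total film thickness in cm.
    d1, d2
        Optional layer thicknesses in cm (e.g. a porous diffusant-rich
        stratum and a compact polymer-rich stratum).  When given, both must
        be positive and sum to ``d_p``.
    """

    d_p: float
    d1: float | None = None
    d2: float | None = None

    def __post_init__(self):
        if not self.d_p > 0:
            raise DomainError(f"film thickness must be > 0, got {self.d_p}")
        if (self.d1 is None) != (self.d2 is None):
            raise DomainError("layer thicknesses d1 and d2 must be given together")
        if self.d1 is not None:
            if not (self.d1 > 0 and self.d2 > 0):
                raise DomainError("layer thicknesses must be > 0")
            if not math.isclose(self.d1 + self.d2, self.d_p, rel_tol=1e-9):
                raise DomainError(
                    f"layer thicknesses must sum to the total: "
                    f"{self.d1} + {self.d2} != {self.d_p}"
                )

    @classmethod
    def from_mm(cls, d_p_mm: float, d1_mm: float | None = None,
                d2_mm: float | None = None) -> "FilmGeometry":
        """Build a geometry from millimetre thicknesses (as tabulated)."""
        conv = lambda x: None if x is None else x * 0.1
        return cls(d_p_mm * 0.1, conv(d1_mm), conv(d2_mm))

    @property
    def d1_over_d(self) -> float:
        if self.d1 is None:
            raise DomainError("geometry has no layer split")
        return self.d1 / self.d_p


@dataclass(frozen=True)
class ReleaseCurve:
    """Sampled cumulative release for one film/solvent pair.

    ``fractions`` are M_t / M_inf in [0, 1] at strictly increasing ``times``
    (seconds).  When built from raw released amounts, ``fractions`` are
    ``amounts / m_inf`` and both are retained.
    """

    times: np.ndarray
    fractions: np.ndarray
    amounts: np.ndarray | None = None
    m_inf: float | None = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.fractions, dtype=float)
        if t.ndim != 1 or t.size == 0:
            raise DomainError("times must be a non-empty 1-D array")
        if t.shape != f.shape:
            raise DomainError("times and fractions must have equal length")
        if t[0] < 0:
            raise DomainError("times must be >= 0")
        if np.any(np.diff(t) <= 0):
            raise DomainError(
                "times must be strictly increasing; deduplicate first "
                "(see ReleaseCurve.from_samples)"
            )
        if np.any(f < 0) or np.any(f > 1):
            raise DomainError("fractions must lie in [0, 1]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fractions", f)
        if self.amounts is not None:
            a = np.asarray(self.amounts, dtype=float)
            if a.shape != t.shape:
                raise DomainError("amounts must match times in length")
            object.__setattr__(self, "amounts", a)

    def __len__(self) -> int:
        return self.times.size

    @classmethod
    def from_samples(cls, times, fractions) -> "ReleaseCurve":
        """Build a curve from possibly unsorted samples with duplicate times.

        Rows are sorted by time and duplicate times averaged.
        """
        t = np.asarray(times, dtype=float)
        f = np.asarray(fractions, dtype=float)
        order = np.argsort(t, kind="stable")
        t, f = t[order], f[order]
        uniq, inv = np.unique(t, return_inverse=True)
        if uniq.size < t.size:
            f = np.bincount(inv, weights=f) / np.bincount(inv)
            t = uniq
        return cls(t, f)

    @classmethod
    def from_amounts(cls, times, amounts, m_inf: float | None = None,
                     *, plateau_rel_tol: float = 0.02,
                     plateau_points: int = 3) -> "ReleaseCurve":
        """Build a curve from raw released amounts.

        If ``m_inf`` is not given it is taken as the mean of the final
        ``plateau_points`` amounts, provided their relative spread is below
        ``plateau_rel_tol`` (otherwise a warning is issued and the mean is
        used regardless).
        """
        a = np.asarray(amounts, dtype=float)
        if m_inf is None:
            if a.size < plateau_points:
                raise DomainError(
                    f"need >= {plateau_points} samples to infer the plateau"
                )
            tail = a[-plateau_points:]
            scale = max(abs(tail).max(), np.finfo(float).tiny)
            if (tail.max() - tail.min()) / scale >= plateau_rel_tol:
                warnings.warn(
                    "release curve has not plateaued over the final "
                    f"{plateau_points} samples; equilibrium amount taken as "
                    "their mean anyway",
                    stacklevel=2,
                )
            m_inf = float(tail.mean())
        if not m_inf > 0:
            raise DomainError(f"equilibrium amount must be > 0, got {m_inf}")
        frac = np.clip(a / m_inf, 0.0, 1.0)
        curve = cls.from_samples(times, frac)
        object.__setattr__(curve, "amounts", np.asarray(a, dtype=float))
        object.__setattr__(curve, "m_inf", float(m_inf))
        return curve


def dimensionless_time(D: float, geom: FilmGeometry, t) -> np.ndarray | float:
    """tau = D t / d_p^2, the similarity variable of the plane-sheet problem."""
    check_diffusion_coefficient(D)
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise DomainError("time must be >= 0")
    tau = D * t_arr / geom.d_p**2
    return float(tau) if np.isscalar(t) or t_arr.ndim == 0 else tau


def _n_terms(tau_min: float, term_tol: float) -> int:
    """Number of series terms needed so the first dropped term < term_tol.

    The n-th term is bounded by (8/pi^2) exp(-(2n+1)^2 pi^2 tau / 4); solving
    for the exponent gives the count below.  Terms decay like exp(-n^2), so
    this is sharp.
    """
    m = 4.0 * math.log(8.0 / (_PI2 * term_tol)) / (_PI2 * tau_min)
    n = int(math.ceil((math.sqrt(max(m, 1.0)) - 1.0) / 2.0)) + 1
    if n > MAX_TERMS:
        raise ConvergenceError(
            f"series needs {n} terms at tau = {tau_min:g} (cap {MAX_TERMS})"
        )
    return max(n, 1)


def release_fraction_tau(tau, term_tol: float = TERM_TOL):
    """Released fraction as a function of dimensionless time tau.

    Vectorised; uses the exponential series with adaptive truncation for
    tau >= ``SMALL_TAU_CUTOFF`` and the short-time law (2/sqrt(pi)) sqrt(tau)
    below it.
    """
    if not 0 < term_tol <= 1e-3:
        raise DomainError(f"term_tol must be in (0, 1e-3], got {term_tol}")
    tau_arr = np.atleast_1d(np.asarray(tau, dtype=float))
    if np.any(tau_arr < 0):
        raise DomainError("tau must be >= 0")
    out = np.empty_like(tau_arr)
    small = tau_arr < SMALL_TAU_CUTOFF
    if small.any():
        out[small] = (2.0 / math.sqrt(math.pi)) * np.sqrt(tau_arr[small])
    if (~small).any():
        tb = tau_arr[~small]
        n = np.arange(_n_terms(float(tb.min()), term_tol))
        odd_sq = (2 * n + 1).astype(float) ** 2
        coef = 8.0 / (odd_sq * _PI2)
        rate = odd_sq * _PI2 / 4.0
        out[~small] = 1.0 - coef @ np.exp(-np.outer(rate, tb))
    np.clip(out, 0.0, 1.0, out)
    if np.isscalar(tau) or np.asarray(tau).ndim == 0:
        return float(out[0])
    return out


def release_fraction(D: float, geom: FilmGeometry, t,
                     term_tol: float = TERM_TOL):
    """Cumulative released fraction M_t / M_inf at time(s) ``t`` (seconds)."""
    return release_fraction_tau(dimensionless_time(D, geom, t), term_tol)


def release_curve(D: float, geom: FilmGeometry, times) -> ReleaseCurve:
    """Evaluate the model release curve at the given times (seconds)."""
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise DomainError("times must be non-empty")
    if np.any(np.diff(t) < 0):
        raise DomainError("times must be nondecreasing")
    return ReleaseCurve.from_samples(t, release_fraction(D, geom, t))


def time_to_fraction(D: float, geom: FilmGeometry, fraction: float) -> float:
    """Time (s) at which the released fraction reaches ``fraction``.

    Solved by root bracketing on tau; exact 0 for fraction 0.
    """
    check_diffusion_coefficient(D)
    if not 0 <= fraction < 1:
        raise DomainError(f"target fraction must lie in [0, 1), got {fraction}")
    if fraction == 0:
        return 0.0
    # f(tau) spans (0, 1): sqrt law at small tau, exponential tail at large.
    tau_lo = (fraction * math.sqrt(math.pi) / 2.0) ** 2 * 0.5
    tau_hi = 10.0
    while release_fraction_tau(tau_hi) < fraction:  # pragma: no cover
        tau_hi *= 2.0
    tau = brentq(lambda x: release_fraction_tau(x) - fraction, tau_lo, tau_hi,
                 xtol=1e-15, rtol=1e-14)
    return tau * geom.d_p**2 / D


def half_release_time(D: float, geom: FilmGeometry) -> float:
    """Time (s) to 50% release; equals ``HALF_RELEASE_TAU * d_p^2 / D``."""
    return time_to_fraction(D, geom, 0.5)
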