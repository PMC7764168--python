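"""Swelling of films in contact with solvent.

The swelling rate is the relative mass change of a film against its dry
mass, s = (m_t - m_0) / m_0.  It is negative when the film loses mass to
the solvent (leaching exceeds uptake, as seen for films in nearly anhydrous
ethanol) and grows toward an equilibrium plateau in water-rich solvents.
Equilibrium is declared when consecutive swelling values stop changing: the
criterion here is a relative change below ``rel_tol`` (default 2%) across a
three-point window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError

__all__ = ["MassSeries", "EquilibriumSwelling", "swelling_rate",
           "equilibrium_swelling"]


@dataclass(frozen=True)
class MassSeries:
    """Film masses over time plus the dry mass m0 (grams, seconds)."""

    times: np.ndarray
    masses: np.ndarray
    m0: float

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        m = np.asarray(self.masses, dtype=float)
        if t.shape != m.shape or t.ndim != 1 or t.size == 0:
            raise DomainError("times and masses must be equal-length 1-D")
        if np.any(np.diff(t) < 0):
            raise DomainError("times must be nondecreasing")
        if np.any(m < 0):
            raise DomainError("masses must be >= 0")
        if not self.m0 > 0:
            raise DomainError(f"dry mass must be > 0, got {self.m0}")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "masses", m)

    def swelling(self) -> np.ndarray:
        return (self.masses - self.m0) / self.m0


@dataclass(frozen=True)
class EquilibriumSwelling:
    """Detected equilibrium swelling value and whether it was reached."""

    s: float
    time: float
    equilibrated: bool


def swelling_rate(m0: float, mt: float) -> float:
    """s = (mt - m0) / m0; negative under net mass loss."""
    if not m0 > 0:
        raise DomainError(f"dry mass must be > 0, got {m0}")
    if mt < 0:
        raise DomainError(f"swelled mass must be >= 0, got {mt}")
    return (mt - m0) / m0


def equilibrium_swelling(series: MassSeries,
                         rel_tol: float = 0.02) -> EquilibriumSwelling:
    """Detect the equilibrium swelling rate of a mass time-series.

    Scans for the first three-point window in which each consecutive pair of
    swelling values differs by less than ``rel_tol`` relative, and reports
    the swelling at the end of that window.  If no such window exists the
    final value is returned with ``equilibrated=False``.
    """
    if len(series.times) < 3:
        raise DomainError("need at least 3 time points")
    if not rel_tol > 0:
        raise DomainError(f"rel_tol must be > 0, got {rel_tol}")
    s = series.swelling()
    tiny = np.finfo(float).tiny
    rel = np.abs(np.diff(s)) / np.maximum(np.abs(s[1:]), tiny)
    # masses equal to m0 give s = 0; treat a zero-difference step as settled
    rel[np.abs(np.diff(s)) == 0] = 0.0
    for i in range(rel.size - 1):
        if rel[i] < rel_tol and rel[i + 1] < rel_tol:
            return EquilibriumSwelling(
                s=float(s[i + 2]), time=float(series.times[i + 2]),
                equilibrated=True,
            )
    return EquilibriumSwelling(
        s=float(s[-1]), time=float(series.times[-1]), equilibrated=False
    )
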