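"""Series-resistance composition of diffusion across stacked film layers.

Phase-separated films present strata with very different transport
properties (e.g. a porous oil-rich layer over a compact polymer-rich
layer).  For diffusion normal to the layers the thickness-over-D terms add
like electrical resistances,

    d / D = d_1/D_1 + d_2/D_2 + ... + d_n/D_n,

so the effective coefficient D is a thickness-weighted harmonic mean of the
layer coefficients.  For a two-layer film this relation can be solved for
the ratio of the layer coefficients given only measurable quantities,

    D_1 / D_2 = (D_1/D - d_1/d) / (1 - d_1/d),

which is how the compact-layer coefficient is inferred when only the whole-
film D, the fast-layer D_1 and the thickness split d_1/d are known.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .diffusion import FilmGeometry, check_diffusion_coefficient
from .errors import DegenerateGeometryError, DomainError

__all__ = ["LayerSystem", "TwoLayerResult", "effective_D", "two_layer_ratio",
           "decompose_two_layer"]


@dataclass(frozen=True)
class LayerSystem:
    """Ordered stack of (thickness cm, D cm^2/s) layers."""

    layers: tuple[tuple[float, float], ...]

    def __init__(self, layers: Sequence[Sequence[float]]):
        layers = tuple((float(d), float(D)) for d, D in layers)
        if len(layers) == 0:
            raise DomainError("a layer system needs at least one layer")
        for i, (d, D) in enumerate(layers):
            if not d > 0:
                raise DomainError(f"layer {i}: thickness must be > 0, got {d}")
            if not D > 0:
                raise DomainError(f"layer {i}: D must be > 0, got {D}")
        object.__setattr__(self, "layers", layers)

    @property
    def total_thickness(self) -> float:
        return sum(d for d, _ in self.layers)


@dataclass(frozen=True)
class TwoLayerResult:
    """Decomposition of a two-layer film into per-layer coefficients."""

    D: float          # effective, cm^2/s
    D1: float         # first (fast) layer, cm^2/s
    D2: float         # second layer, cm^2/s
    d1_over_d: float  # thickness share of layer 1
    D1_over_D2: float

    def __post_init__(self):
        lo, hi = min(self.D1, self.D2), max(self.D1, self.D2)
        # 1e-9 relative slack: the bound is exact in real arithmetic but the
        # inputs arrive independently rounded
        if not lo * (1 - 1e-9) <= self.D <= hi * (1 + 1e-9):
            raise DomainError(
                "effective D must lie between the layer coefficients"
            )


def effective_D(system: LayerSystem) -> float:
    """Effective diffusion coefficient of a layer stack (cm^2/s).

    D = d / sum_i(d_i / D_i); always bounded by the extreme layer values.
    """
    d = system.total_thickness
    resistance = sum(di / Di for di, Di in system.layers)
    D = d / resistance
    # the weighted harmonic mean lies within the layer extremes; clamp the
    # final rounding so the bound holds exactly in floating point
    ds = [Di for _, Di in system.layers]
    return min(max(D, min(ds)), max(ds))


def two_layer_ratio(D1_over_D: float, d1_over_d: float) -> float:
    """Layer-coefficient ratio D1/D2 from whole-film observables.

    Parameters are the ratio of the fast-layer coefficient to the effective
    one and the thickness share of the fast layer.  Requires
    ``D1_over_D > d1_over_d``; otherwise the implied second-layer
    coefficient would be non-positive.
    """
    if not 0 < d1_over_d < 1:
        raise DomainError(f"d1/d must lie in (0, 1), got {d1_over_d}")
    if not D1_over_D > 0:
        raise DomainError(f"D1/D must be > 0, got {D1_over_D}")
    if D1_over_D <= d1_over_d:
        raise DegenerateGeometryError(
            f"degenerate geometry: requires D1/D > d1/d, got "
            f"D1/D = {D1_over_D:g} <= d1/d = {d1_over_d:g}"
        )
    return (D1_over_D - d1_over_d) / (1.0 - d1_over_d)


def decompose_two_layer(D: float, D1: float, geom: FilmGeometry) -> TwoLayerResult:
    """Solve the two-layer series relation for the second layer's coefficient.

    Given the effective D, the first layer's D1 and a geometry carrying the
    layer split, solves d/D = d1/D1 + d2/D2 for D2.
    """
    check_diffusion_coefficient(D)
    check_diffusion_coefficient(D1)
    if geom.d1 is None:
        raise DomainError("geometry must carry a two-layer split (d1, d2)")
    x = geom.d1_over_d
    ratio = two_layer_ratio(D1 / D, x)  # raises if D1/D <= d1/d
    # algebraically D2 = d2 / (d/D - d1/D1); deriving it from the ratio
    # keeps D1_over_D2 and D1/D2 consistent to the last bit
    D2 = D1 / ratio
    return TwoLayerResult(D=D, D1=D1, D2=D2, d1_over_d=x, D1_over_D2=ratio)
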