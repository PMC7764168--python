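"""Published reference measurements for crosslinked calcium-alginate films
loaded with cinnamon essential oil (CEO).

These are the measured film thicknesses (mm) and fitted diffusion
coefficients (cm^2/s) for one-way CEO release into food-simulating solvents
at 4 degC, plus the two-layer decomposition inputs for the uncrosslinked
parent films.  The raw release time-series behind them were never deposited,
so these tabulated values serve as anchors for synthetic scenarios and
round-trip tests rather than as recomputable results.

Film naming: EG / EGA / EGC denote the emulsifier blend (gelatin alone,
gelatin + gum acacia, gelatin + carboxymethylcellulose); the trailing digit
k = 1..4 encodes the glycerol content (0.3 k grams).
"""

from __future__ import annotations

__all__ = ["ETHANOL_FILMS", "WATER_FILMS", "AQUEOUS_ETHANOL_SERIES",
           "TWO_LAYER_FILMS"]

#: One-way release into absolute ethanol: film -> (thickness mm, D cm^2/s, RMSE).
ETHANOL_FILMS: dict[str, tuple[float, float, float]] = {
    "EG1":  (0.048, 5.800e-10, 0.03248),
    "EG2":  (0.053, 3.433e-9,  0.03436),
    "EG3":  (0.062, 1.096e-8,  0.09119),
    "EG4":  (0.079, 1.606e-8,  0.07104),
    "EGA1": (0.047, 4.200e-11, 0.05190),
    "EGA2": (0.051, 7.000e-10, 0.06900),
    "EGA3": (0.059, 8.216e-9,  0.09958),
    "EGA4": (0.076, 9.900e-9,  0.1029),
    "EGC1": (0.049, 8.800e-12, 0.07831),
    "EGC2": (0.050, 4.510e-11, 0.04025),
    "EGC3": (0.062, 3.340e-9,  0.07512),
    "EGC4": (0.072, 5.938e-9,  0.09671),
}

#: One-way release into water: film -> (thickness mm, D cm^2/s, RMSE).
WATER_FILMS: dict[str, tuple[float, float, float]] = {
    "EG11":  (0.047, 4.050e-10, 0.05661),
    "EG21":  (0.049, 5.100e-10, 0.03139),
    "EG31":  (0.053, 6.354e-10, 0.04163),
    "EGA11": (0.044, 4.500e-10, 0.01860),
    "EGA21": (0.050, 5.085e-10, 0.02774),
    "EGA31": (0.063, 8.500e-10, 0.04937),
    "EGC11": (0.046, 2.896e-10, 0.06030),
    "EGC21": (0.052, 4.400e-10, 0.04030),
    "EGC31": (0.060, 9.988e-10, 0.04996),
}

#: Release into ethanol/water mixtures: film -> {w: (thickness mm, D cm^2/s)}.
#: D decreases with water fraction w for EG3 and increases for EGC1.
AQUEOUS_ETHANOL_SERIES: dict[str, dict[float, tuple[float, float]]] = {
    "EG3": {
        0.00: (0.062, 1.127e-8),
        0.05: (0.062, 1.099e-8),
        0.30: (0.057, 3.900e-9),
        0.60: (0.056, 2.156e-9),
        0.95: (0.057, 1.712e-9),
        1.00: (0.053, 6.354e-10),
    },
    "EGC1": {
        0.00: (0.049, 8.800e-12),
        0.05: (0.047, 1.670e-11),
        0.30: (0.048, 1.747e-10),
        0.60: (0.041, 2.556e-10),
        0.95: (0.041, 2.700e-10),
        1.00: (0.046, 2.896e-10),
    },
}

#: Two-layer decomposition inputs for the uncrosslinked parent films:
#: film -> (effective D cm^2/s, fast-layer D1 cm^2/s, thickness share d1/d).
TWO_LAYER_FILMS: dict[str, tuple[float, float, float]] = {
    "G":  (2.000e-9,  8.064e-9,  0.75),
    "GA": (6.680e-10, 2.950e-9,  0.73),
    "GC": (4.140e-11, 1.760e-10, 0.74),
}
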