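import math

import numpy as np
import pytest


def brute_force_fraction(tau, n_terms=100_000):
    """Independent oracle: direct summation of the plane-sheet series.

    Deliberately naive (fixed high term count, plain loop-free sum) so it
    shares no code path with the package's adaptive evaluation.
    """
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    n = np.arange(n_terms, dtype=float)
    odd = 2.0 * n + 1.0
    coef = 8.0 / (odd**2 * math.pi**2)
    out = 1.0 - coef @ np.exp(-np.outer(odd**2 * math.pi**2 / 4.0, tau))
    return out if out.size > 1 else float(out[0])


@pytest.fixture(scope="session")
def oracle():
    return brute_force_fraction


@pytest.fixture(scope="session")
def two_layer_reference():
    """Published two-layer inputs: label -> (D, D1, d1/d, printed D1/D, printed D1/D2)."""
    return {
        "G":  (2.000e-9,  8.064e-9,  0.75, 4.032, 13.13),
        "GA": (6.680e-10, 2.950e-9,  0.73, 4.416, 13.47),
        "GC": (4.140e-11, 1.760e-10, 0.74, 4.251, 13.27),
    }


@pytest.fixture(scope="session")
def ethanol_film_params():
    """Measured (thickness mm, D cm^2/s) anchors used for round trips."""
    return {"EG3": (0.062, 1.096e-8), "EGC1": (0.049, 8.800e-12)}
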