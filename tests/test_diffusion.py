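import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from filmrelease import (
    FilmGeometry,
    ReleaseCurve,
    dimensionless_time,
    half_release_time,
    release_curve,
    release_fraction,
    release_fraction_tau,
    time_to_fraction,
)
from filmrelease.diffusion import HALF_RELEASE_TAU
from filmrelease.errors import DomainError


class TestFilmGeometry:
    def test_mm_conversion(self):
        assert FilmGeometry.from_mm(0.62).d_p == pytest.approx(0.062)

    def test_layer_split_must_sum(self):
        FilmGeometry(0.01, 0.0075, 0.0025)  # consistent split is accepted
        with pytest.raises(DomainError):
            FilmGeometry(0.01, 0.005, 0.004)

    @pytest.mark.parametrize("kwargs", [
        {"d_p": 0.0}, {"d_p": -1.0},
        {"d_p": 0.01, "d1": 0.01, "d2": None},
        {"d_p": 0.01, "d1": -0.002, "d2": 0.012},
    ])
    def test_invalid_geometry_rejected(self, kwargs):
        with pytest.raises(DomainError):
            FilmGeometry(**kwargs)


class TestReleaseCurveType:
    def test_from_samples_sorts_and_averages_duplicates(self):
        c = ReleaseCurve.from_samples([10, 0, 10], [0.3, 0.0, 0.5])
        assert c.times.tolist() == [0, 10]
        assert c.fractions.tolist() == [0.0, 0.4]

    def test_fraction_bounds_enforced(self):
        with pytest.raises(DomainError):
            ReleaseCurve(np.array([0.0, 1.0]), np.array([0.0, 1.2]))

    def test_from_amounts_plateau_normalisation(self):
        t = np.arange(6.0)
        amounts = np.array([0.0, 2.0, 3.5, 4.0, 4.0, 4.0])
        c = ReleaseCurve.from_amounts(t, amounts)
        assert c.m_inf == pytest.approx(4.0)
        assert c.fractions[-1] == pytest.approx(1.0)
        assert c.fractions[1] == pytest.approx(0.5)

    def test_from_amounts_warns_without_plateau(self):
        with pytest.warns(UserWarning, match="not plateaued"):
            ReleaseCurve.from_amounts(np.arange(4.0), [0.0, 1.0, 2.0, 3.0])


class TestDimensionlessTime:
    def test_arithmetic_identity(self):
        geom = FilmGeometry(0.01)
        assert dimensionless_time(1e-8, geom, 1e4) == pytest.approx(1.0)

    def test_zero_time(self):
        assert dimensionless_time(3e-9, FilmGeometry(0.005), 0.0) == 0.0

    def test_linear_in_D(self):
        geom = FilmGeometry(0.004)
        assert dimensionless_time(2e-9, geom, 123.0) == pytest.approx(
            2 * dimensionless_time(1e-9, geom, 123.0))

    def test_negative_time_rejected(self):
        with pytest.raises(DomainError):
            dimensionless_time(1e-9, FilmGeometry(0.01), -1.0)


class TestReleaseFraction:
    def test_initial_condition_exact_zero(self):
        assert release_fraction_tau(0.0) == 0.0

    def test_equilibrium_limit(self):
        # the leading series term is 8/pi^2 exp(-pi^2 tau / 4): ~1.6e-11 at
        # tau = 10, below 1e-13 at tau = 12
        assert release_fraction_tau(10.0) == pytest.approx(1.0, abs=1e-10)
        assert release_fraction_tau(12.0) == pytest.approx(1.0, abs=1e-12)

    def test_half_release_tau(self):
        assert release_fraction_tau(HALF_RELEASE_TAU) == pytest.approx(
            0.500, abs=1e-3)

    def test_short_time_sqrt_law(self):
        tau = 0.01
        expected = 2.0 / math.sqrt(math.pi) * math.sqrt(tau)
        assert release_fraction_tau(tau) == pytest.approx(expected, abs=1e-3)

    def test_matches_brute_force_series(self, oracle):
        taus = np.geomspace(1e-6, 10.0, 60)
        ours = release_fraction_tau(taus)
        assert np.max(np.abs(ours - oracle(taus))) < 1e-10

    def test_small_tau_branch_continuous_at_cutoff(self, oracle):
        # approximation below the cutoff agrees with the series at it
        below, at = 0.999e-6, 1e-6
        assert release_fraction_tau(below) == pytest.approx(
            oracle(below), abs=1e-12)
        assert release_fraction_tau(at) == pytest.approx(oracle(at), abs=1e-12)

    @given(st.floats(min_value=1e-4, max_value=5.0),
           st.floats(min_value=1.01, max_value=10.0))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_in_tau(self, tau, factor):
        assert release_fraction_tau(tau * factor) > release_fraction_tau(tau)

    @given(st.floats(min_value=-12, max_value=-6),
           st.floats(min_value=0.002, max_value=0.01),
           st.floats(min_value=1.0, max_value=1e6))
    @settings(max_examples=50, deadline=None)
    def test_depends_only_on_tau(self, log10_d, d_p, t):
        """Dimensional invariance: (D, d_p, t) enter only through tau."""
        D = 10.0**log10_d
        geom = FilmGeometry(d_p)
        tau = D * t / d_p**2
        assert release_fraction(D, geom, t) == pytest.approx(
            release_fraction_tau(tau), rel=1e-12)

    def test_increasing_in_D_at_fixed_time(self):
        geom = FilmGeometry(0.005)
        t = 1000.0
        f = [release_fraction(D, geom, t) for D in (1e-9, 2e-9, 4e-9)]
        assert f[0] < f[1] < f[2]

    def test_nonpositive_D_rejected(self):
        with pytest.raises(DomainError):
            release_fraction(0.0, FilmGeometry(0.01), 1.0)

    def test_tolerance_domain(self):
        with pytest.raises(DomainError):
            release_fraction_tau(0.1, term_tol=0.1)


class TestReleaseCurveOp:
    def test_zero_time_only(self):
        c = release_curve(1e-9, FilmGeometry(0.01), [0.0])
        assert c.fractions.tolist() == [0.0]

    def test_empty_times_rejected(self):
        with pytest.raises(DomainError):
            release_curve(1e-9, FilmGeometry(0.01), [])

    def test_curve_nondecreasing_and_matches_oracle(self, oracle):
        geom = FilmGeometry(0.0062)
        D = 1.096e-8
        taus = np.geomspace(0.01, 2.0, 25)
        times = taus * geom.d_p**2 / D
        c = release_curve(D, geom, times)
        assert np.all(np.diff(c.fractions) >= 0)
        assert np.max(np.abs(c.fractions - oracle(taus))) < 1e-9


class TestHalfReleaseTime:
    def test_matches_known_dimensionless_time(self):
        geom = FilmGeometry(0.005)
        D = 1e-8
        expected = HALF_RELEASE_TAU * geom.d_p**2 / D
        assert half_release_time(D, geom) == pytest.approx(expected, rel=1e-3)

    def test_halves_when_D_doubles(self):
        geom = FilmGeometry(0.004)
        assert half_release_time(2e-9, geom) == pytest.approx(
            half_release_time(1e-9, geom) / 2, rel=1e-9)

    def test_zero_fraction_target(self):
        assert time_to_fraction(1e-9, FilmGeometry(0.01), 0.0) == 0.0

    def test_root_is_exact(self):
        geom = FilmGeometry(0.0079)
        D = 1.606e-8
        t = time_to_fraction(D, geom, 0.85)
        assert release_fraction(D, geom, t) == pytest.approx(0.85, abs=1e-9)
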