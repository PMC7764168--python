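import numpy as np
import pytest

from filmrelease import (
    FilmGeometry,
    FitOptions,
    ReleaseCurve,
    bootstrap_ci,
    fit_D,
    release_curve,
    rmse,
)
from filmrelease.errors import (
    ConfigurationError,
    DomainError,
    NonIdentifiableError,
)
from filmrelease.synthetic import default_schedule


class TestRmse:
    def test_identical_vectors(self):
        assert rmse([0.1, 0.5, 0.9], [0.1, 0.5, 0.9]) == 0.0

    def test_unit_error(self):
        assert rmse([0.0, 1.0], [1.0, 0.0]) == pytest.approx(1.0)

    def test_against_longhand_arithmetic(self):
        rng = np.random.default_rng(11)
        obs, pred = rng.random(40), rng.random(40)
        expected = float(np.sqrt(sum((o - p) ** 2 for o, p in zip(obs, pred))
                                 / 40))
        assert rmse(obs, pred) == pytest.approx(expected, rel=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(DomainError):
            rmse([0.1, 0.2], [0.1])


def _noiseless_curve(thickness_mm, D, n=20, tau_span=(0.02, 2.0)):
    geom = FilmGeometry.from_mm(thickness_mm)
    times = default_schedule(D, geom.d_p, n, tau_span)
    return release_curve(D, geom, times), geom


class TestFitD:
    @pytest.mark.parametrize("film", ["EG3", "EGC1"])
    def test_noiseless_round_trip(self, film, ethanol_film_params):
        thickness_mm, D = ethanol_film_params[film]
        curve, geom = _noiseless_curve(thickness_mm, D)
        res = fit_D(curve, geom)
        assert res.converged
        assert res.d_hat == pytest.approx(D, rel=1e-3)
        assert res.rmse < 1e-6

    def test_identifiable_across_printed_D_range(self):
        """Noiseless recovery within 0.1% over the full measured span."""
        for D in (8.8e-12, 5.8e-10, 3.4e-9, 1.606e-8):
            curve, geom = _noiseless_curve(0.05, D)
            assert fit_D(curve, geom).d_hat == pytest.approx(D, rel=1e-3)

    def test_all_zero_curve_not_identifiable(self):
        geom = FilmGeometry(0.005)
        curve = ReleaseCurve(np.linspace(0, 100, 10), np.zeros(10))
        with pytest.raises(NonIdentifiableError):
            fit_D(curve, geom)

    def test_too_few_points_rejected(self):
        geom = FilmGeometry(0.005)
        curve = ReleaseCurve(np.array([0.0, 10.0, 20.0]),
                             np.array([0.0, 0.3, 0.5]))
        with pytest.raises(NonIdentifiableError):
            fit_D(curve, geom)

    def test_deterministic(self, ethanol_film_params):
        curve, geom = _noiseless_curve(*ethanol_film_params["EG3"])
        assert fit_D(curve, geom).d_hat == fit_D(curve, geom).d_hat

    def test_optimum_beats_dense_grid(self):
        """Optimizer sanity: RMSE at the optimum is <= the best of an
        independent 200-point log10-D grid scan."""
        geom = FilmGeometry.from_mm(0.05)
        D = 3e-9
        times = default_schedule(D, geom.d_p)
        clean = release_curve(D, geom, times).fractions
        rng = np.random.default_rng(5)
        curve = ReleaseCurve(times,
                             np.clip(clean + rng.normal(0, 0.03, 20), 0, 1))
        res = fit_D(curve, geom)
        grid_rmse = min(
            rmse(curve.fractions,
                 release_curve(10.0**g, geom, times).fractions)
            for g in np.linspace(-14, -4, 200)
        )
        assert res.rmse <= grid_rmse + 1e-12

    def test_scale_equivariance(self):
        """Scaling d_p by k and D by k^2 leaves fit and RMSE unchanged."""
        k = 3.0
        geom1 = FilmGeometry(0.005)
        D = 2e-9
        times = default_schedule(D, geom1.d_p)
        fr = release_curve(D, geom1, times).fractions
        rng = np.random.default_rng(9)
        noisy = np.clip(fr + rng.normal(0, 0.02, fr.shape), 0, 1)
        res1 = fit_D(ReleaseCurve(times, noisy), geom1)
        res2 = fit_D(ReleaseCurve(times, noisy), FilmGeometry(k * 0.005))
        assert res2.d_hat == pytest.approx(k**2 * res1.d_hat, rel=1e-6)
        assert res2.rmse == pytest.approx(res1.rmse, rel=1e-9)

    def test_noisy_median_bias_small(self):
        """sigma = 0.03 noise leaves the estimator nearly unbiased."""
        geom = FilmGeometry.from_mm(0.062)
        D = 1.096e-8
        times = default_schedule(D, geom.d_p)
        clean = release_curve(D, geom, times).fractions
        errs = []
        for i in range(30):
            rng = np.random.default_rng(100 + i)
            noisy = np.clip(clean + rng.normal(0, 0.03, clean.shape), 0, 1)
            res = fit_D(ReleaseCurve(times, noisy), geom)
            errs.append(res.d_hat / D - 1)
        assert abs(np.median(errs)) < 0.05

    def test_co_estimated_scale_recovers_normalisation(self):
        """A curve normalised with a 20%-low equilibrium amount refits D
        correctly once the scale is co-estimated."""
        geom = FilmGeometry.from_mm(0.05)
        D = 1e-9
        times = default_schedule(D, geom.d_p)
        true_frac = release_curve(D, geom, times).fractions
        mis = ReleaseCurve(times, np.clip(true_frac * 0.8, 0, 1))
        res = fit_D(mis, geom, FitOptions(m_inf_mode="co-estimate"))
        assert res.d_hat == pytest.approx(D, rel=1e-3)
        assert res.scale == pytest.approx(0.8, rel=1e-3)


class TestBootstrap:
    def test_noiseless_interval_degenerate(self, ethanol_film_params):
        curve, geom = _noiseless_curve(*ethanol_film_params["EG3"])
        opts = FitOptions(bootstrap=100, seed=1)
        lo, hi = bootstrap_ci(curve, geom, opts)
        d_hat = fit_D(curve, geom).d_hat
        assert (hi - lo) / d_hat < 1e-6

    def test_reproducible_under_seed(self):
        geom = FilmGeometry.from_mm(0.05)
        D = 3e-9
        times = default_schedule(D, geom.d_p)
        clean = release_curve(D, geom, times).fractions
        rng = np.random.default_rng(3)
        curve = ReleaseCurve(times,
                             np.clip(clean + rng.normal(0, 0.03, 20), 0, 1))
        opts = FitOptions(bootstrap=150, seed=77)
        assert bootstrap_ci(curve, geom, opts) == bootstrap_ci(curve, geom, opts)

    def test_small_B_rejected(self, ethanol_film_params):
        curve, geom = _noiseless_curve(*ethanol_film_params["EG3"])
        with pytest.raises(ConfigurationError):
            bootstrap_ci(curve, geom, FitOptions(bootstrap=50, seed=1))

    def test_seed_required(self, ethanol_film_params):
        curve, geom = _noiseless_curve(*ethanol_film_params["EG3"])
        with pytest.raises(ConfigurationError):
            bootstrap_ci(curve, geom, FitOptions(bootstrap=100))
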