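"""Plane-parallel transport engine: sources, estimators, invariants."""

import numpy as np
import pytest
from scipy import integrate

from groundshine.transport import (
    ExponentialSourceSpec,
    KermaGrid,
    TransportConfig,
    run_grid,
    sample_source_depth,
    score_plane_crossing,
    simulate_kerma,
    truncation_depth,
    uncollided_plane_kerma,
)
from groundshine.materials import get_table
from groundshine.transport import CM2G_TO_M2KG, MEV_TO_J


def _ratio_err(k1, e1, k0, e0):
    r = k1 / k0
    return r, r * np.sqrt((e1 / k1) ** 2 + (e0 / k0) ** 2)


class TestSourceSampling:
    def test_plane_source_degenerate_case(self, rng):
        assert sample_source_depth(0.0, 20.0, rng) == 0.0
        assert np.all(sample_source_depth(0.0, 20.0, rng, size=100) == 0.0)

    def test_truncated_exponential_mean(self, rng):
        alpha, trunc, n = 1.0, 20.0, 100_000
        d = sample_source_depth(alpha, trunc, rng, size=n)
        expected = alpha * (1 - 21 * np.exp(-20)) / (1 - np.exp(-20))
        se = np.std(d) / np.sqrt(n)
        assert abs(np.mean(d) - expected) < 3 * se

    def test_truncation_bound(self, rng):
        d = sample_source_depth(5.0, 20.0, rng, size=100_000)
        assert np.all(d >= 0) and np.all(d <= 100.0)
        assert truncation_depth(10.0) == 100.0  # capped at 100 g/cm^2

    def test_negative_alpha_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_source_depth(-1.0, 20.0, rng)


class TestCrossingEstimator:
    def test_normal_incidence_contribution(self):
        e = 0.662
        expected = e * MEV_TO_J * get_table("air").mu_en(e) * CM2G_TO_M2KG
        assert score_plane_crossing(1.0, e, 1.0) == pytest.approx(expected, rel=1e-12)

    def test_inverse_cosine_scaling(self):
        e = 0.662
        assert score_plane_crossing(1.0, e, 0.5) == pytest.approx(
            2.0 * score_plane_crossing(1.0, e, 1.0), rel=1e-12)

    def test_grazing_contributions_are_capped(self):
        e = 1.0
        assert score_plane_crossing(1.0, e, 1e-6) == pytest.approx(
            score_plane_crossing(1.0, e, 0.01), rel=1e-12)


class TestUncollidedOracle:
    def test_plane_source_matches_exponential_integral(self):
        """Uncollided-only MC vs the E1 closed form, 3 sigma."""
        cfg = TransportConfig(n_histories=150_000, seed=11, uncollided_only=True)
        grid = simulate_kerma(ExponentialSourceSpec(0.662, plane_depth=0.5), cfg)
        mc, err = grid.K[0, 0, 0], grid.stderr[0, 0, 0]
        cf = uncollided_plane_kerma(0.662, 0.5, 1.0)
        assert abs(mc - cf) < 3 * err

    def test_exponential_source_matches_depth_quadrature(self):
        """For alpha > 0 the closed form integrates over the truncated
        exponential depth profile; MC within 3 sigma of the quadrature."""
        alpha, energy = 1.0, 0.662
        cfg = TransportConfig(n_histories=150_000, seed=13, uncollided_only=True)
        grid = simulate_kerma(ExponentialSourceSpec(energy, alpha), cfg)
        mc, err = grid.K[0, 0, 0], grid.stderr[0, 0, 0]
        t = truncation_depth(alpha)
        norm = 1.0 - np.exp(-t / alpha)
        cf, _ = integrate.quad(
            lambda d: np.exp(-d / alpha) / alpha / norm
            * uncollided_plane_kerma(energy, d, 1.0), 0.0, t, limit=200)
        assert abs(mc - cf) < 3 * err

    def test_uncollided_never_exceeds_total(self):
        src = ExponentialSourceSpec(0.662, 0.0)
        unc = simulate_kerma(src, TransportConfig(
            n_histories=60_000, seed=5, uncollided_only=True))
        tot = simulate_kerma(src, TransportConfig(n_histories=60_000, seed=5))
        err = np.hypot(unc.stderr[0, 0, 0], tot.stderr[0, 0, 0])
        assert unc.K[0, 0, 0] <= tot.K[0, 0, 0] + 3 * err


class TestTransportInvariants:
    def test_same_seed_is_bitwise_reproducible(self):
        cfg = TransportConfig(n_histories=20_000, seed=99)
        g1 = run_grid([0.3], [0.0, 1.0], cfg)
        g2 = run_grid([0.3], [0.0, 1.0], cfg)
        np.testing.assert_array_equal(g1.K, g2.K)
        np.testing.assert_array_equal(g1.stderr, g2.stderr)

    def test_density_invariance_in_mass_depth(self):
        """Doubling the geometric soil density leaves K unchanged when the
        source depth is expressed in g/cm^2 (3 sigma)."""
        src = ExponentialSourceSpec(0.662, plane_depth=2.0)
        k = {}
        for rho in (1.0, 2.0):
            g = simulate_kerma(src, TransportConfig(
                n_histories=120_000, seed=17, soil_density=rho))
            k[rho] = (g.K[0, 0, 0], g.stderr[0, 0, 0])
        err = np.hypot(k[1.0][1], k[2.0][1])
        assert abs(k[1.0][0] - k[2.0][0]) < 3 * err

    def test_kerma_decreases_with_relaxation_depth(self):
        cfg = TransportConfig(n_histories=80_000, seed=23)
        g = run_grid([0.662], [0.0, 1.0, 5.0], cfg)
        k = g.K[0, :, 0]
        err = g.stderr[0, :, 0]
        assert k[0] - k[1] > -3 * np.hypot(err[0], err[1])
        assert k[1] - k[2] > -3 * np.hypot(err[1], err[2])
        # and strictly decreasing in the estimates themselves
        assert k[0] > k[1] > k[2]

    def test_kerma_decreases_with_height_for_shallow_sources(self):
        cfg = TransportConfig(n_histories=80_000, seed=29,
                              detector_heights=(0.1, 1.0, 10.0))
        g = simulate_kerma(ExponentialSourceSpec(0.662, 0.1), cfg)
        k = g.K[0, 0, :]
        err = g.stderr[0, 0, :]
        assert k[0] - k[1] > -3 * np.hypot(err[0], err[1])
        assert k[1] - k[2] > -3 * np.hypot(err[1], err[2])

    def test_stderr_shrinks_with_sqrt_of_histories(self):
        src = ExponentialSourceSpec(0.662, 0.0)
        e1 = simulate_kerma(src, TransportConfig(
            n_histories=40_000, seed=31)).stderr[0, 0, 0]
        e2 = simulate_kerma(src, TransportConfig(
            n_histories=160_000, seed=37)).stderr[0, 0, 0]
        # quadrupling the histories should halve the error, within 20 %
        assert e2 / e1 == pytest.approx(0.5, rel=0.35)

    def test_collision_density_estimator_agrees_with_plane_crossing(self):
        src = ExponentialSourceSpec(0.3, 0.0)
        pc = simulate_kerma(src, TransportConfig(n_histories=150_000, seed=41))
        cd = simulate_kerma(src, TransportConfig(
            n_histories=400_000, seed=43, estimator="collision-density",
            slab_thickness_m=4.0))
        err = np.hypot(pc.stderr[0, 0, 0], cd.stderr[0, 0, 0])
        assert abs(pc.K[0, 0, 0] - cd.K[0, 0, 0]) < 3.5 * err


class TestKermaGrid:
    def test_grid_shape_and_flags(self):
        cfg = TransportConfig(n_histories=10_000, seed=3,
                              detector_heights=(0.5, 1.0))
        g = run_grid([0.2, 1.0], [0.0, 1.0], cfg)
        assert g.K.shape == (2, 2, 2)
        assert np.all(g.K > 0)
        assert g.converged.shape == g.K.shape

    def test_interpolation_and_range_errors(self):
        grid = KermaGrid([0.1, 1.0], [0.0, 5.0], [1.0],
                         K=np.array([[[1e-17], [5e-18]], [[1e-16], [6e-17]]]),
                         stderr=np.zeros((2, 2, 1)), n_histories=1)
        # node exactness
        assert grid.interpolate(0.1, 0.0) == pytest.approx(1e-17, rel=1e-12)
        # linear in alpha
        assert grid.interpolate(0.1, 2.5) == pytest.approx(7.5e-18, rel=1e-12)
        with pytest.raises(ValueError):
            grid.interpolate(2.0, 0.0)
        with pytest.raises(ValueError):
            grid.interpolate(0.5, 7.0)

    def test_csv_round_trip(self, tmp_path):
        cfg = TransportConfig(n_histories=5_000, seed=3)
        g = run_grid([0.3], [0.0], cfg)
        path = tmp_path / "grid.csv"
        g.to_csv(path)
        g2 = KermaGrid.from_csv(path)
        np.testing.assert_allclose(g2.K, g.K, rtol=1e-12)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            run_grid([], [0.0], TransportConfig(n_histories=100, seed=1))


class TestSourceSpecValidation:
    def test_exclusive_modes(self):
        with pytest.raises(ValueError):
            ExponentialSourceSpec(1.0, relaxation_depth=1.0, plane_depth=0.5)
        with pytest.raises(ValueError):
            ExponentialSourceSpec(-1.0)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TransportConfig(n_histories=0)
        with pytest.raises(ValueError):
            TransportConfig(detector_heights=(-1.0,))
        with pytest.raises(ValueError):
            TransportConfig(estimator="adjoint")
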