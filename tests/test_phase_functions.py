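"""Phase-function families: evaluation, moments, cone integrals, sampling, grid."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

import sfrmodel as s
from sfrmodel.phase_functions import (GegenbauerKernel, HenyeyGreenstein,
                                      ModifiedHenyeyGreenstein,
                                      TwoTermHenyeyGreenstein,
                                      build_tissue_grid)

FAMILIES = [
    HenyeyGreenstein(0.7),
    HenyeyGreenstein(-0.3),
    ModifiedHenyeyGreenstein(g=0.9, alpha=0.8),
    TwoTermHenyeyGreenstein(alpha=0.9, gf=0.9, gb=-0.3),
    GegenbauerKernel(alpha=1.5, g=0.6),
    GegenbauerKernel(alpha=0.5, g=0.8),  # reduces to HG(0.8)
]


def sphere_integral(model):
    val, _ = quad(lambda t: 2 * np.pi * model.pdf(t) * np.sin(t), 0.0, np.pi,
                  limit=200)
    return val


class TestEvaluation:
    def test_isotropic_density(self):
        hg = HenyeyGreenstein(1e-14)
        assert np.allclose(hg.pdf([0.0, 1.0, np.pi]), 1.0 / (4 * np.pi))

    def test_mhg_alpha_one_reduces_to_hg(self):
        theta = np.linspace(0, np.pi, 50)
        mhg = ModifiedHenyeyGreenstein(g=0.85, alpha=1.0)
        hg = HenyeyGreenstein(0.85)
        assert np.allclose(mhg.pdf(theta), hg.pdf(theta), rtol=1e-14)

    def test_hg_forward_peak_value(self):
        # (1/4pi)(1-g^2)/(1-g)^3 at theta = 0
        g = 0.9
        expected = (1 - g * g) / (4 * np.pi * (1 - g) ** 3)
        assert np.isclose(HenyeyGreenstein(g).pdf(0.0), expected, rtol=1e-12)
        assert np.isclose(expected, 15.1197, rtol=1e-4)

    @pytest.mark.parametrize("model", FAMILIES, ids=lambda m: m.label())
    def test_normalized_and_nonnegative(self, model):
        theta = np.linspace(0, np.pi, 300)
        assert np.all(model.pdf(theta) >= 0)
        assert abs(sphere_integral(model) - 1.0) < 1e-6

    def test_gegenbauer_half_alpha_is_hg(self):
        theta = np.linspace(0, np.pi, 50)
        assert np.allclose(GegenbauerKernel(alpha=0.5, g=0.8).pdf(theta),
                           HenyeyGreenstein(0.8).pdf(theta), rtol=1e-12)

    @pytest.mark.parametrize("bad", [
        lambda: HenyeyGreenstein(1.0),
        lambda: ModifiedHenyeyGreenstein(g=0.5, alpha=1.2),
        lambda: TwoTermHenyeyGreenstein(alpha=0.5, gf=-0.2, gb=-0.5),
        lambda: TwoTermHenyeyGreenstein(alpha=0.5, gf=0.5, gb=0.2),
        lambda: GegenbauerKernel(alpha=0.0, g=0.5),
        lambda: GegenbauerKernel(alpha=1.0, g=1.0),
    ])
    def test_domain_errors_name_parameter(self, bad):
        with pytest.raises(ValueError, match="parameter"):
            bad()

    def test_theta_domain_checked(self):
        with pytest.raises(ValueError):
            HenyeyGreenstein(0.5).pdf(3.5)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.sampled_from(["HG", "MHG", "TTHG", "RMC"]), st.randoms(use_true_random=False))
def test_normalization_random_parameters(family, rnd):
    """Every family integrates to 1 over the sphere for random parameters."""
    if family == "HG":
        m = HenyeyGreenstein(rnd.uniform(-0.9, 0.95))
    elif family == "MHG":
        m = ModifiedHenyeyGreenstein(g=rnd.uniform(0.0, 0.95),
                                     alpha=rnd.uniform(0, 1))
    elif family == "TTHG":
        m = TwoTermHenyeyGreenstein(alpha=rnd.uniform(0, 1),
                                    gf=rnd.uniform(0.05, 0.95),
                                    gb=rnd.uniform(-0.95, -0.05))
    else:
        a = rnd.uniform(0.05, 2.5)
        m = GegenbauerKernel(alpha=a, g=rnd.uniform(0.05, 0.9))
    assert abs(sphere_integral(m) - 1.0) < 1e-6


class TestMoments:
    def test_hg_powers(self):
        mom = HenyeyGreenstein(0.6).moments(3)
        assert np.allclose(mom.g, [0.6, 0.36, 0.216], atol=1e-15)

    def test_mhg_mixture_moments(self):
        mom = ModifiedHenyeyGreenstein(g=0.9, alpha=0.8).moments(2)
        assert np.isclose(mom[1], 0.72, atol=1e-12)
        assert np.isclose(mom[2], 0.8 * 0.81 + 0.2 * 0.4, atol=1e-12)
        assert np.isclose(mom[2], 0.728, atol=1e-12)

    def test_tthg_mixture_moments(self):
        mom = TwoTermHenyeyGreenstein(alpha=0.9, gf=0.9, gb=-0.3).moments(2)
        assert np.isclose(mom[1], 0.9 * 0.9 - 0.1 * 0.3, atol=1e-12)
        assert np.isclose(mom[1], 0.78, atol=1e-12)
        assert np.isclose(mom[2], 0.9 * 0.81 + 0.1 * 0.09, atol=1e-12)
        assert np.isclose(mom[2], 0.738, atol=1e-12)

    @pytest.mark.parametrize("model", FAMILIES, ids=lambda m: m.label())
    def test_closed_forms_match_quadrature(self, model):
        """Analytic/mixture moments agree with direct quadrature."""
        mom = model.moments(5)
        for n in range(1, 6):
            ref, _ = quad(
                lambda t: 2 * np.pi * model.pdf(t)
                * np.polynomial.legendre.Legendre.basis(n)(np.cos(t))
                * np.sin(t), 0.0, np.pi, limit=300)
            assert abs(mom[n] - ref) < 1e-8

    def test_moment_magnitude_bound(self, grid):
        for mom in grid.moments:
            assert np.all(np.abs(mom.g) <= 1.0)


class TestPartialIntegrals:
    def test_isotropic_forward_closed_form(self):
        iso = HenyeyGreenstein(1e-14)
        expected = (1 - np.cos(np.deg2rad(23))) / 2
        got = iso.partial_integral(np.deg2rad(23), "forward")
        assert np.isclose(got, expected, rtol=1e-10)
        assert np.isclose(got, 0.03975, atol=2e-5)

    def test_isotropic_backward_closed_form(self):
        iso = HenyeyGreenstein(1e-14)
        got = iso.partial_integral(np.deg2rad(1), "backward")
        assert np.isclose(got, 7.615e-5, rtol=1e-3)

    @pytest.mark.parametrize("model", FAMILIES, ids=lambda m: m.label())
    def test_hemispheres_partition_sphere(self, model):
        f = model.partial_integral(np.pi / 2, "forward")
        b = model.partial_integral(np.pi / 2, "backward")
        assert abs(f + b - 1.0) < 1e-6

    @pytest.mark.parametrize("model", FAMILIES, ids=lambda m: m.label())
    @pytest.mark.parametrize("direction", ["forward", "backward"])
    def test_closed_form_matches_quadrature(self, model, direction):
        theta_lim = np.deg2rad(17.0)
        got = model.partial_integral(theta_lim, direction)
        lo, hi = ((0.0, theta_lim) if direction == "forward"
                  else (np.pi - theta_lim, np.pi))
        ref, _ = quad(lambda t: 2 * np.pi * model.pdf(t) * np.sin(t), lo, hi)
        assert np.isclose(got, ref, rtol=1e-8, atol=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            HenyeyGreenstein(0.5).partial_integral(2.0, "forward")


class TestSampling:
    @pytest.mark.parametrize("model,seed", [
        (HenyeyGreenstein(0.8), 11),
        (TwoTermHenyeyGreenstein(alpha=0.9, gf=0.9, gb=-0.3), 12),
        (GegenbauerKernel(alpha=1.5, g=0.6), 13),
    ], ids=lambda v: str(v))
    def test_first_three_sampled_moments(self, model, seed):
        """Empirical moments of cos(theta) match quadrature moments at n=1e6."""
        n = 10 ** 6
        mu = model.sample_mu(n, seed)
        mom = model.moments(3)
        for k in (1, 2, 3):
            emp = np.mean(np.polynomial.legendre.Legendre.basis(k)(mu))
            se = np.std(np.polynomial.legendre.Legendre.basis(k)(mu)) / np.sqrt(n)
            assert abs(emp - mom[k]) < 4 * se + 2e-4

    def test_isotropic_uniform_in_mu(self):
        mu = HenyeyGreenstein(1e-14).sample_mu(10 ** 6, 7)
        sorted_mu = np.sort((mu + 1) / 2)
        ks = np.max(np.abs(sorted_mu - np.arange(1, mu.size + 1) / mu.size))
        assert ks < 0.002

    def test_reproducible(self):
        m = HenyeyGreenstein(0.5)
        assert np.array_equal(m.sample_angles(1000, 3), m.sample_angles(1000, 3))
        assert np.all(m.sample_angles(1000, 3) >= 0)
        assert np.all(m.sample_angles(1000, 3) <= np.pi)


class TestGrid:
    def test_counts_by_family(self, grid):
        # MHG and RMC counts pin down the grid conventions; the TTHG count
        # follows deterministically from the standard two-term mixture.
        counts = grid.counts_by_family()
        assert counts["MHG"] == 15
        assert counts["RMC"] == 46
        assert counts["TTHG"] == 132
        assert len(grid) == sum(counts.values())

    def test_filter_restrictions_hold(self, grid):
        for mom in grid.moments:
            assert mom[1] >= 0.5
            assert mom[2] < 0.9

    def test_g1_range(self, grid):
        g1 = np.array([m[1] for m in grid.moments])
        assert round(g1.max(), 2) <= 0.94
        assert g1.min() >= 0.5

    def test_deterministic(self, grid):
        again = build_tissue_grid()
        assert again.provenance == grid.provenance
        assert np.allclose([m[1] for m in again.moments],
                           [m[1] for m in grid.moments])

    def test_csv_round_trip(self, grid, tmp_path):
        path = tmp_path / "grid.csv"
        grid.to_csv(path)
        import pandas as pd

        frame = pd.read_csv(path)
        assert len(frame) == len(grid)
        assert {"family", "g1", "g2", "g3"} <= set(frame.columns)
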