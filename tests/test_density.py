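import numpy as np
import pytest
from scipy.signal import find_peaks

from myovstep.density import (DensityModel, kl_divergence, project_density)
from myovstep.params import LoadForce, MotorParams
from tests.conftest import COARSE_QUAD


class TestKLDivergence:
    def test_identity_zero(self):
        p = np.array([0.2, 0.5, 0.3])
        assert kl_divergence(p, p) == pytest.approx(0.0, abs=1e-14)

    def test_hand_value_two_point(self):
        # 0.8 ln 1.6 + 0.2 ln 0.4
        expected = 0.8 * np.log(1.6) + 0.2 * np.log(0.4)
        assert kl_divergence([0.8, 0.2], [0.5, 0.5]) == \
            pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.1927, abs=1e-4)

    def test_nonnegative_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            p = rng.random(12) + 1e-3
            q = rng.random(12) + 1e-3
            assert kl_divergence(p, q) >= 0

    def test_support_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kl_divergence([0.5, 0.5], [1.0, 0.0])
        with pytest.raises(ValueError):
            kl_divergence([0.5, 0.5, 0.0], [0.5, 0.5])


class TestSiteDensities:
    def test_full_window_equals_marginal(self, density_f0, lattice):
        n, marg, joint = density_f0.site_densities(lattice, delta1=np.pi)
        np.testing.assert_allclose(joint, marg, rtol=1e-12)

    def test_empty_window_is_zero(self, density_f0, lattice):
        _, _, joint = density_f0.site_densities(lattice, delta1=0.0)
        assert np.all(joint == 0.0)

    def test_window_never_exceeds_marginal(self, density_f0, lattice):
        _, marg, joint = density_f0.site_densities(lattice)
        assert np.all(joint <= marg + 1e-18)
        assert np.all(joint >= 0)

    def test_half_helical_site_dominates_at_zero_force(self, density_f0,
                                                       lattice):
        n, _, joint = density_f0.site_densities(lattice)
        assert n[np.argmax(joint)] == 13

    def test_full_helix_unreachable_for_wild_type(self, density_f0, lattice):
        # site 26 sits at 72 nm > 2L = 70 nm for the 6IQ construct
        n, marg, _ = density_f0.site_densities(lattice)
        assert marg[n == 26][0] == 0.0

    def test_quadrature_convergence(self, params, lattice, density_f0):
        # production (default) quadrature vs 1.5x resolution
        fine = DensityModel(params, quad=density_f0.quad.scaled(1.5))
        n, _, jd = density_f0.site_densities(lattice)
        _, _, jf = fine.site_densities(lattice)
        big = jf > 1e-6  # compare the sites that dominate the kinetics
        np.testing.assert_allclose(jd[big], jf[big], rtol=0.05)
        # aggregate rate (what the kinetics consumes) converges tightly
        assert jd[big].sum() == pytest.approx(jf[big].sum(), rel=0.02)


class TestGridAndProjections:
    def test_grid_normalized(self, coarse_grid_f0):
        assert coarse_grid_f0.integral() == pytest.approx(1.0, abs=0.01)

    @pytest.mark.parametrize("plane", ["z-x", "z-y", "y-x"])
    def test_projection_normalized(self, coarse_grid_f0, plane):
        a1, a2, dens = project_density(coarse_grid_f0, plane)
        total = np.trapezoid(np.trapezoid(dens, a2, axis=1), a1)
        assert total == pytest.approx(1.0, abs=0.01)

    def test_cylindrical_projection_normalized(self, coarse_grid_f0):
        z, rho, dens = project_density(coarse_grid_f0, "z-rho")
        total = np.sum(dens) * (z[1] - z[0]) * (rho[1] - rho[0])
        assert total == pytest.approx(1.0, abs=0.02)

    def test_fubini_sum_rule(self, coarse_grid_f0):
        # z-marginal from the z-x plane equals that from the z-y plane
        _, x, dzx = project_density(coarse_grid_f0, "z-x")
        _, y, dzy = project_density(coarse_grid_f0, "z-y")
        np.testing.assert_allclose(np.trapezoid(dzx, x, axis=1),
                                   np.trapezoid(dzy, y, axis=1), rtol=1e-8)

    def test_unknown_plane(self, coarse_grid_f0):
        with pytest.raises(ValueError):
            project_density(coarse_grid_f0, "x-q")


def _zx_ridge_peaks(grid):
    _, _, dzx = project_density(grid, "z-x")
    prof = dzx.max(axis=1)
    pk, _ = find_peaks(prof, prominence=0.15 * prof.max())
    return pk


class TestConstraintEffects:
    def test_bimodal_with_constraint_unimodal_without(self, params,
                                                      coarse_grid_f0):
        assert len(_zx_ridge_peaks(coarse_grid_f0)) == 2
        free = DensityModel(params.with_(mu_c=0.0), quad=COARSE_QUAD)
        assert len(_zx_ridge_peaks(free.grid(spacing=4.0))) == 1

    def test_backward_force_rotates_density_backward(self, params,
                                                     coarse_grid_f0):
        loaded = DensityModel(params, LoadForce(F=2.0), quad=COARSE_QUAD)
        gl = loaded.grid(spacing=4.0)

        def z_centroid(g):
            w = g.values.sum(axis=(0, 1))
            return float(np.sum(g.axes[2] * w) / w.sum())

        assert z_centroid(gl) < z_centroid(coarse_grid_f0) - 5.0

    def test_mutant_densities_are_radial_rescalings(self, lattice):
        # 4IQ and 8IQ occupy shells scaled by lever-arm length
        from myovstep.params import mutant_params
        stats = {}
        for label in ("4IQ", "6IQ", "8IQ"):
            m = DensityModel(mutant_params(label), quad=COARSE_QUAD)
            g = m.grid(spacing=4.0)
            X, Y, Z = np.meshgrid(*g.axes, indexing="ij")
            r = np.sqrt(X**2 + Y**2 + Z**2)
            w = g.values / g.values.sum()
            stats[label] = float(np.sum(w * r))
        assert stats["4IQ"] / stats["6IQ"] == pytest.approx(25 / 35, rel=0.1)
        assert stats["8IQ"] / stats["6IQ"] == pytest.approx(45 / 35, rel=0.1)


class TestJointPotentialForms:
    def test_cosine_vs_harmonic_quartic_small_kl(self, params, lattice):
        from myovstep.params import JointPotentialSpec
        cos_model = DensityModel(params, quad=COARSE_QUAD)
        quart = JointPotentialSpec(form="quartic", mu_c=params.mu_c,
                                   theta_p=params.theta_p, h3=0.0, h4=0.0)
        quart_model = DensityModel(params, joint_spec=quart, quad=COARSE_QUAD)
        gc = cos_model.grid(spacing=5.0)
        gq = quart_model.grid(spacing=5.0)
        pc = gc.values.ravel() + 1e-15
        pq = gq.values.ravel() + 1e-15
        assert kl_divergence(pc, pq) < 0.05
        # and both remain bimodal
        assert len(_zx_ridge_peaks(gc)) == 2
        assert len(_zx_ridge_peaks(gq)) == 2
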