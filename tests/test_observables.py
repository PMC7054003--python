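import numpy as np
import pytest
from scipy.stats import norm

from myovstep.kinetics import PathwayProbabilities
from myovstep.observables import (StepDistribution,
                                  head_separation_distribution,
                                  measurement_convolve, run_monte_carlo,
                                  run_statistics, step_distribution)
from myovstep.params import KineticRates, LoadForce, MotorParams
from tests.conftest import COARSE_QUAD


def _point_mass_pathways(n_site: int, g: float = 8.0):
    """Pathway probabilities with all mass on one binding site."""
    n = np.array([-n_site, n_site])
    pT = np.array([0.0, 1.0])
    pL = np.array([0.0, 1.0])
    return PathwayProbabilities(n=n, pT=pT, pL=pL, g=g)


class TestSeparationDistribution:
    def test_normalized_positive_support(self, model_f0):
        sep = head_separation_distribution(model_f0.pathways)
        assert np.all(sep.n > 0)
        assert sep.total() == pytest.approx(1.0, abs=1e-12)

    def test_wild_type_mode_at_half_helix(self, model_f0):
        sep = head_separation_distribution(model_f0.pathways)
        assert sep.n[np.argmax(sep.mass)] == 13
        assert sep.z[np.argmax(sep.mass)] == pytest.approx(36.0)

    def test_point_mass_case(self):
        sep = head_separation_distribution(_point_mass_pathways(13))
        assert sep.mass[sep.n == 13][0] == pytest.approx(1.0)

    def test_max_sep_truncation(self, model_f0):
        sep = head_separation_distribution(model_f0.pathways, max_sep=18)
        assert np.all(sep.mass[sep.n > 18] == 0)
        assert sep.total() == pytest.approx(1.0)


class TestStepDistribution:
    def test_convolution_shift_identity(self):
        # point mass separation 13 + point mass target 13 -> 72 nm step
        pp = _point_mass_pathways(13)
        d = step_distribution(pp, mode="trailing")
        assert d.z[np.argmax(d.mass)] == pytest.approx(72.0, abs=1e-9)

    def test_combined_mass_is_success_probability(self, model_f0):
        pp = model_f0.pathways
        d = model_f0.step_distribution("combined")
        assert d.total() == pytest.approx(1.0 - pp.Pt, abs=1e-12)

    def test_forward_only_normalized_nonnegative_support(self, model_f0):
        d = model_f0.step_distribution("forward-only")
        assert d.total() == pytest.approx(1.0)
        assert np.all(d.mass[d.z < 0] < 1e-12)

    def test_unknown_mode(self, model_f0):
        with pytest.raises(ValueError):
            model_f0.step_distribution("sideways")

    def test_forward_peak_shift_under_load_at_most_one_subunit(self, params,
                                                               rates):
        from myovstep.observables import StepModel
        peak = {}
        for F in (0.0, 1.0):
            m = StepModel(params, rates, LoadForce(F=F), quad=COARSE_QUAD)
            d = m.step_distribution("forward-only")
            peak[F] = d.z[np.argmax(d.mass)]
        assert abs(peak[0.0] - peak[1.0]) <= 72 / 13 + 1e-9

    def test_stall_force_symmetry_of_combined_distribution(self, params,
                                                           rates):
        from myovstep.observables import StepModel
        m = StepModel(params, rates, LoadForce(F=1.9), quad=COARSE_QUAD)
        d = m.step_distribution("combined")
        fwd = d.mass[d.z > 18].sum()
        bwd = d.mass[d.z < -18].sum()
        assert fwd == pytest.approx(bwd, rel=0.25)


class TestMeasurementConvolve:
    def test_mass_conserved(self, model_f0):
        d = model_f0.step_distribution("forward-only")
        for sigma in (0.0, 1.0, 3.0):
            _, h = measurement_convolve(d, sigma=sigma, bin_width=5.0)
            assert h.sum() == pytest.approx(d.total(), abs=1e-6)

    def test_zero_sigma_is_binning_identity(self):
        d = StepDistribution(n=np.array([13]), mass=np.array([1.0]))
        centers, h = measurement_convolve(d, sigma=0.0, bin_width=2.0)
        assert h.sum() == pytest.approx(1.0)
        assert centers[np.argmax(h)] == pytest.approx(37.0)  # 36 in [36, 38)

    def test_point_mass_matches_normal_cdf(self):
        d = StepDistribution(n=np.array([13]), mass=np.array([1.0]))
        centers, h = measurement_convolve(d, sigma=1.0, bin_width=1.0)
        edges = np.append(centers - 0.5, centers[-1] + 0.5)
        expected = np.diff(norm.cdf(edges, loc=36.0, scale=1.0))
        np.testing.assert_allclose(h, expected, atol=1e-9)

    def test_bad_bin_width(self, model_f0):
        with pytest.raises(ValueError):
            measurement_convolve(model_f0.step_distribution(), bin_width=0.0)


class TestRunStatistics:
    def test_velocity_identity(self, model_f0):
        ro = model_f0.run_observables()
        assert ro.v_run == pytest.approx(ro.z_run / ro.t_run, rel=1e-12)

    def test_mean_step_count_is_inverse_termination(self, model_f0):
        ro = model_f0.run_observables()
        assert ro.N_run == pytest.approx(1.0 / model_f0.pathways.Pt)

    def test_requires_combined_distribution(self, model_f0, rates):
        with pytest.raises(ValueError):
            run_statistics(model_f0.pathways,
                           model_f0.step_distribution("forward-only"),
                           model_f0.times, rates)

    def test_zero_force_run_length_about_micron(self, model_f0):
        # fitted parameter set targets ~1.3 um at zero load
        assert model_f0.run_observables().z_run == pytest.approx(1300, rel=0.1)


class TestRunMonteCarlo:
    def test_seed_reproducibility(self, params, rates):
        r1 = run_monte_carlo(params, rates, n_runs=20, seed=7,
                             quad=COARSE_QUAD)
        r2 = run_monte_carlo(params, rates, n_runs=20, seed=7,
                             quad=COARSE_QUAD)
        assert [r.length for r in r1] == [r.length for r in r2]
        assert [r.steps for r in r1] == [r.steps for r in r2]

    def test_agrees_with_closed_forms_within_3se(self, params, rates):
        from myovstep.observables import StepModel
        m = StepModel(params, rates, quad=COARSE_QUAD)
        ro = m.run_observables()
        runs = run_monte_carlo(params, rates, n_runs=400, seed=11,
                               quad=COARSE_QUAD)
        lens = np.array([r.length for r in runs])
        nev = np.array([r.n_events for r in runs])
        times = np.array([r.time for r in runs])
        for sample, target in ((lens, ro.z_run), (nev, ro.N_run),
                               (times, ro.t_run)):
            se = sample.std(ddof=1) / np.sqrt(len(sample))
            assert abs(sample.mean() - target) < 3 * se + 0.02 * abs(target)

    def test_trap_rule_runs_and_is_deterministic(self, params, rates):
        r1 = run_monte_carlo(params, rates, n_runs=3, seed=2,
                             force_rule="trap", trap_stiffness=0.02,
                             quad=COARSE_QUAD, max_events=60)
        r2 = run_monte_carlo(params, rates, n_runs=3, seed=2,
                             force_rule="trap", trap_stiffness=0.02,
                             quad=COARSE_QUAD, max_events=60)
        assert [r.length for r in r1] == [r.length for r in r2]
        assert all(r.n_events >= 1 for r in r1)
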