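import numpy as np
import pytest
from scipy.signal import find_peaks
from scipy.stats import chisquare

from myovstep.bd import SimSettings, ensemble_contours, estimate_dV, simulate_step
from myovstep.chain import (bd_trajectory, chain_energy, chain_gradient,
                            initial_configuration, metropolis_sample,
                            pack_chain_params)
from myovstep.params import KineticRates, LoadForce, MotorParams


@pytest.fixture(scope="module")
def params():
    return MotorParams()


@pytest.fixture(scope="module")
def rates():
    return KineticRates()


class TestChainEnergetics:
    def test_gradient_matches_finite_differences(self, params):
        rng = np.random.default_rng(0)
        x = initial_configuration(params, 7) + rng.normal(0, 1.5, (15, 3))
        x[0] = 0.0
        par = pack_chain_params(params,
                               LoadForce.from_degrees(1.5, 20.0, 30.0),
                               m=7, bead_excl_diam=5.0, coverslip=-25.0)
        grad = np.zeros_like(x)
        chain_gradient(x, par, grad)
        h = 1e-6
        for i in (1, 7, 14):
            for k in range(3):
                xp, xm = x.copy(), x.copy()
                xp[i, k] += h
                xm[i, k] -= h
                num = (chain_energy(xp, par) - chain_energy(xm, par)) / (2 * h)
                assert grad[i, k] == pytest.approx(num, abs=1e-4)

    def test_energy_terms_switchable(self, params):
        # all couplings off: only bonds and bending remain, and the
        # straight two-leg configuration has zero energy
        p0 = params.with_(nu_c=0.0, mu_c=0.0)
        par = pack_chain_params(p0, m=7, head_head=False)
        x = initial_configuration(p0, m=7)
        assert chain_energy(x, par) == pytest.approx(0.0, abs=1e-9)

    def test_zero_noise_relaxation_decreases_energy(self, params):
        par = pack_chain_params(params, m=7, k_bond=25.0)
        x0 = initial_configuration(params, m=7)
        x0[1:] += 1.0  # distort
        e0 = chain_energy(x0, par)
        _, _, _, _, xf = bd_trajectory(par, x0, 5e-8, 20000, noise=False)
        ef = chain_energy(xf, par)
        assert ef < e0
        assert ef < 1.0  # near the minimum

    def test_integrator_instability_detected(self, params):
        par = pack_chain_params(params, m=7, k_bond=25.0)
        x0 = initial_configuration(params, m=7)
        with pytest.raises(RuntimeError, match="time step"):
            bd_trajectory(par, x0, 1e-4, 5000)  # dt far too large


class TestTrajectories:
    def test_seed_determinism(self, params, rates):
        st = SimSettings(max_time=0.02)
        o1 = simulate_step(params, rates, settings=st, capture_radius=2.0,
                           gate_hydrolysis=False, allow_termination=False,
                           seed=3)
        o2 = simulate_step(params, rates, settings=st, capture_radius=2.0,
                           gate_hydrolysis=False, allow_termination=False,
                           seed=3)
        assert o1.status == o2.status and o1.site == o2.site
        assert o1.elapsed == o2.elapsed

    def test_termination_pathway(self, params):
        # near-instant bound-head detachment ends the run unbound
        fast = KineticRates(td1=1e-4, td2=2e-4, th=1e-5)
        st = SimSettings(max_time=0.05)
        out = simulate_step(params, fast, settings=st, seed=1)
        assert out.status == "terminated"

    def test_stationarity_endpoints_match_equilibrium(self, params):
        # detailed balance: walkers seeded from chain equilibrium and
        # integrated briefly must reproduce the equilibrium histogram
        m = 7
        par = pack_chain_params(params, m=m, k_bond=25.0)
        x0 = initial_configuration(params, m=m)
        heads, _, _, configs = metropolis_sample(
            par, x0, 64, thin=150, burn=4000, seed=8, keep_configs=True)
        ref_heads, _, _ = metropolis_sample(par, x0, 20000, thin=10,
                                            burn=4000, seed=9)
        ends = []
        for i, cfg in enumerate(configs):
            _, _, _, _, xf = bd_trajectory(
                par, np.ascontiguousarray(cfg), 5e-8, 60000, seed=100 + i)
            ends.append(xf[2 * m])
        ends = np.asarray(ends)
        edges = np.quantile(ref_heads[:, 2], np.linspace(0, 1, 5))
        edges[0], edges[-1] = -np.inf, np.inf
        obs, _ = np.histogram(ends[:, 2], bins=edges)
        stat, pval = chisquare(obs)
        assert pval > 1e-3


class TestExclusionEstimate:
    def test_wild_type_effective_length(self, params):
        dv = estimate_dV(params, SimSettings(), n_samples=25000, seed=2)
        assert dv == pytest.approx(27.5, rel=0.15)

    def test_short_legs_shorter_exclusion(self):
        from myovstep.params import mutant_params
        st = SimSettings(n_beads_per_leg=5)
        dv = estimate_dV(mutant_params("4IQ"), st, n_samples=25000, seed=2)
        assert dv == pytest.approx(20.0, rel=0.15)

    def test_disabled_exclusion_gives_zero(self, params):
        assert estimate_dV(params, SimSettings(), bead_excl_diam=0.0,
                           n_samples=2000, seed=0) == 0.0
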