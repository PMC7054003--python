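import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myovstep.params import (JointPotentialSpec, KineticRates, LoadForce,
                             MotorParams, effective_constraint,
                             joint_potential, mutant_params)


class TestMotorParams:
    def test_table_defaults(self):
        p = MotorParams()
        assert p.L == 35.0 and p.lp == 350.0
        assert math.degrees(p.theta_c) == pytest.approx(65.0)
        assert math.degrees(p.theta_p) == pytest.approx(83.0)
        assert math.degrees(p.dphi_ac) == pytest.approx(55.6)
        assert p.nu_c == 261.0 and p.mu_c == 5.0
        assert p.a == 0.4 and p.b == 0.045

    def test_power_stroke_effectiveness(self):
        # T = 1 + 20*261/(20 + 7*0.1*261) ~ 26.75
        assert MotorParams().T_eff == pytest.approx(26.75, abs=0.01)

    def test_capture_diffusion_time(self):
        # a^2/Dh = 0.16 / 5.7e4 nm^2/ms ~ 2.8 ns
        assert MotorParams().ta * 1e6 == pytest.approx(2.8, abs=0.05)

    @pytest.mark.parametrize("bad", [
        dict(L=-1.0), dict(lp=10.0), dict(b=0.0), dict(b=1.5),
        dict(a=-0.1), dict(mu_c=-1.0), dict(dphi_ac=4.0),
    ])
    def test_validation(self, bad):
        with pytest.raises(ValueError):
            MotorParams(**bad)

    def test_mutants(self):
        assert mutant_params("4IQ").L == 25.0
        assert mutant_params("6IQ").L == 35.0
        assert mutant_params("8IQ").L == 45.0
        assert mutant_params("4IQ").dV == 20.0
        assert mutant_params("8IQ").dV == 35.0
        with pytest.raises(ValueError):
            mutant_params("5IQ")


class TestKineticRates:
    def test_gating_ratio(self):
        r = KineticRates()
        assert r.g == pytest.approx(8.0)
        assert r.td1 == pytest.approx(1000 / 12)
        assert r.th == pytest.approx(1000 / 750)
        # mean waiting time between detachments g td1/(1+g)
        assert r.t_wait == pytest.approx(8 / 9 * 1000 / 12)

    def test_gating_required(self):
        with pytest.raises(ValueError):
            KineticRates(td1=100.0, td2=50.0)


class TestLoadForce:
    def test_backward_direction(self):
        f = LoadForce(F=2.0)
        np.testing.assert_allclose(f.direction, [0, 0, -1], atol=1e-12)
        np.testing.assert_allclose(f.vector, [0, 0, -2.0], atol=1e-12)

    def test_off_axis_direction(self):
        f = LoadForce.from_degrees(F=1.0, theta_F=90.0, phi_F=90.0)
        np.testing.assert_allclose(f.direction, [0, 1, 0], atol=1e-12)


class TestJointPotential:
    def test_minimum_at_preferred_angle(self):
        for form in ("cosine", "quartic"):
            spec = JointPotentialSpec(form=form, mu_c=5.0, h3=0.3, h4=0.2)
            assert joint_potential(spec.theta_p, spec) == pytest.approx(0.0)

    def test_hand_value(self):
        spec = JointPotentialSpec(mu_c=5.0)
        assert joint_potential(spec.theta_p + math.pi / 2, spec) == \
            pytest.approx(5.0)

    @settings(max_examples=60, deadline=None)
    @given(d=st.floats(-0.15, 0.15), mu=st.floats(0.5, 12.0))
    def test_small_angle_harmonic_match(self, d, mu):
        cos_spec = JointPotentialSpec(form="cosine", mu_c=mu)
        quad_spec = JointPotentialSpec(form="quartic", mu_c=mu)
        th = cos_spec.theta_p + d
        assert joint_potential(th, cos_spec) == pytest.approx(
            joint_potential(th, quad_spec), abs=mu * abs(d) ** 4 + 1e-12)


class TestEffectiveConstraint:
    def test_zero_force_identity(self):
        p = MotorParams()
        ps = effective_constraint(p, LoadForce())
        assert ps.T_eff == pytest.approx(p.T_eff)
        np.testing.assert_allclose(ps.u_c_prime, p.u_c)

    def test_backward_force_value(self):
        # T' = sqrt(T^2 + bFL^2 + 2 T bFL Fhat.uc) at F=1.9 pN backward
        p = MotorParams()
        ps = effective_constraint(p, LoadForce(F=1.9))
        bfl = 1.9 * 35 / 4.1
        expected = math.sqrt(p.T_eff**2 + bfl**2
                             - 2 * p.T_eff * bfl * math.cos(p.theta_c))
        assert ps.T_eff == pytest.approx(expected, rel=1e-12)
        assert ps.T_eff == pytest.approx(24.7, abs=0.3)
        assert np.linalg.norm(ps.u_c_prime) == pytest.approx(1.0)

    def test_strong_force_aligns_with_load(self):
        p = MotorParams()
        f = LoadForce.from_degrees(F=200.0, theta_F=30.0, phi_F=45.0)
        ps = effective_constraint(p, f)
        assert float(ps.u_c_prime @ f.direction) > 0.999

    def test_backward_force_tilts_toward_minus_end(self):
        # backward load increases the effective constraint polar angle
        p = MotorParams()
        ps = effective_constraint(p, LoadForce(F=1.5))
        assert ps.theta_c_prime > p.theta_c

    @settings(max_examples=50, deadline=None)
    @given(F=st.floats(0.01, 5.0), th=st.floats(0, 80), ph=st.floats(-180, 180))
    def test_unit_norm_and_consistency(self, F, th, ph):
        p = MotorParams()
        f = LoadForce.from_degrees(F=F, theta_F=th, phi_F=ph)
        ps = effective_constraint(p, f)
        np.testing.assert_allclose(np.linalg.norm(ps.u_c_prime), 1.0,
                                   atol=1e-12)
        vec = p.T_eff * p.u_c + F * p.L / p.kBT * f.direction
        np.testing.assert_allclose(ps.T_eff * ps.u_c_prime, vec, atol=1e-9)
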