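import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myovstep.lattice import ActinLattice, acceptance_test, wrap_angle


@pytest.fixture(scope="module")
def lat():
    return ActinLattice()


class TestSitePosition:
    @pytest.mark.parametrize("n, expected", [
        (0, (0.0, 0.0, 0.0)),
        (13, (0.0, 0.0, 36.0)),          # half-helical site
        (26, (0.0, 0.0, 72.0)),          # full helical repeat
        (-13, (0.0, 0.0, -36.0)),
    ])
    def test_special_sites(self, lat, n, expected):
        assert lat.site_position(n) == pytest.approx(expected, abs=1e-10)

    def test_generic_site_formula(self, lat):
        # direct evaluation of the helical formula at n=1
        phi = -12 * math.pi / 13
        expected = (5.5 * (math.cos(phi) - 1), 5.5 * math.sin(phi),
                    0.5 * 72 / 13)
        assert lat.site_position(1) == pytest.approx(expected, abs=1e-3)
        assert lat.site_position(1) == pytest.approx(
            (-10.84, -1.316, 2.769), abs=0.01)

    def test_out_of_range(self, lat):
        with pytest.raises(IndexError):
            lat.site_position(lat.n_max + 1)

    def test_helical_period(self, lat):
        n = np.arange(-13, 14)
        p0 = lat.site_position(n)
        p1 = lat.site_position(n + 26)
        np.testing.assert_allclose(p1 - p0, np.tile([0, 0, 72.0], (27, 1)),
                                   atol=1e-9)

    def test_z_strictly_increasing(self, lat):
        z = lat.site_position(lat.sites)[:, 2]
        assert np.all(np.diff(z) > 0)

    def test_protofilament_azimuthal_period(self, lat):
        # even and odd subsets each repeat azimuthally with period 26 in n
        for parity in (0, 1):
            n = np.array([parity, parity + 26])
            phi = lat.site_normal_azimuth(n)
            assert wrap_angle(phi[1] - phi[0]) == pytest.approx(0.0, abs=1e-9)


class TestNormalAzimuth:
    def test_values(self, lat):
        assert lat.site_normal_azimuth(0) == pytest.approx(0.0)
        # n=13 wraps: -12*pi = -6 full turns exactly
        assert lat.site_normal_azimuth(13) == pytest.approx(0.0, abs=1e-9)
        assert lat.site_normal_azimuth(1) == pytest.approx(-12 * math.pi / 13)

    def test_range(self, lat):
        phi = lat.site_normal_azimuth(lat.sites)
        assert np.all(phi > -math.pi - 1e-12)
        assert np.all(phi <= math.pi + 1e-12)


class TestAcceptance:
    def test_anti_parallel_accepts(self, lat):
        for n in (1, 5, -7, 13):
            phi_n = lat.site_normal_azimuth(n)
            assert lat.acceptance_test(phi_n - math.pi, n, 0.1)

    def test_zero_window_rejects_everything(self, lat):
        phis = np.linspace(-math.pi, math.pi, 50)
        assert not np.any(lat.acceptance_test(phis, 3, 0.0))

    def test_boundary(self, lat):
        delta = math.radians(55.6)
        phi_n = lat.site_normal_azimuth(4)
        inside = phi_n - math.pi + math.radians(55.0)
        outside = phi_n - math.pi + math.radians(56.0)
        assert lat.acceptance_test(inside, 4, delta)
        assert not lat.acceptance_test(outside, 4, delta)

    def test_asymmetric_window(self, lat):
        phi_n = lat.site_normal_azimuth(2)
        probe = phi_n - math.pi + math.radians(30.0)
        assert lat.acceptance_test(probe, 2, math.radians(40), math.radians(5))
        assert not lat.acceptance_test(probe, 2, math.radians(20),
                                       math.radians(40))

    @settings(max_examples=100, deadline=None)
    @given(phi=st.floats(-10, 10), n=st.integers(-20, 20),
           k=st.integers(-3, 3))
    def test_2pi_invariance(self, lat, phi, n, k):
        d = math.radians(55.6)
        assert (lat.acceptance_test(phi, n, d)
                == lat.acceptance_test(phi + 2 * math.pi * k, n, d))


@settings(max_examples=200, deadline=None)
@given(phi=st.floats(-50, 50))
def test_wrap_angle_range_and_identity(phi):
    w = wrap_angle(phi)
    assert -math.pi < w <= math.pi
    assert math.isclose(math.sin(w), math.sin(phi), abs_tol=1e-9)
    assert math.isclose(math.cos(w), math.cos(phi), abs_tol=1e-9)


def test_standalone_matches_lattice_method():
    lat = ActinLattice()
    phi_n = lat.site_normal_azimuth(9)
    probe = np.linspace(-4, 4, 41)
    np.testing.assert_array_equal(
        acceptance_test(probe, phi_n, 0.7),
        lat.acceptance_test(probe, 9, 0.7))


def test_invalid_lattice():
    with pytest.raises(ValueError):
        ActinLattice(n_max=20)
    with pytest.raises(ValueError):
        ActinLattice(R=-1.0)


def test_export_roundtrip(tmp_path):
    lat = ActinLattice()
    path = tmp_path / "lattice.txt"
    lat.export(path)
    data = np.loadtxt(path)
    assert data.shape == (2 * lat.n_max + 1, 5)
    np.testing.assert_allclose(data[:, 1:4], lat.site_position(lat.sites),
                               atol=1e-6)
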