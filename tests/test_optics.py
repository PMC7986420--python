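import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from beamtune.errors import DomainError, InfeasibleOpticsError
from beamtune.optics import (
    AIR_RADIATION_LENGTH_MM,
    BeamlineGeometry,
    OpticsPlane,
    SecondMoments,
    Segment,
    air_scattering_moment_increments,
    drift,
    emittance_at_waist,
    moments_from_optics,
    optics_from_moments,
    scattering_power,
    scattering_moments_at,
    spot_sigma_at,
    waist_position,
)
from beamtune.particles import PROTON

def vacuum_line(source_z=-1300.0, end_z=2500.0):
    return BeamlineGeometry(
        source_z_mm=source_z,
        segments=(Segment(length_mm=end_z - source_z, medium="vacuum"),),
    )


def air_line(source_z=-1300.0, end_z=250.0):
    return BeamlineGeometry(
        source_z_mm=source_z,
        segments=(Segment(length_mm=end_z - source_z, medium="air"),),
    )


feasible_planes = st.builds(
    OpticsPlane,
    sigma=st.floats(0.5, 10.0),
    theta=st.floats(0.2, 5.0),
    epsilon=st.just(0.0),
    sign=st.sampled_from([-1, 1]),
).flatmap(
    lambda p: st.floats(0.0, 1.0).map(
        lambda f: OpticsPlane(p.sigma, p.theta, f * math.pi * p.sigma * p.theta, p.sign)
    )
)


class TestEmittance:
    @pytest.mark.parametrize(
        "sigma, theta, expected",
        [(1.0, 1.0, math.pi), (0.0, 5.0, 0.0), (2.0, 3.0, 6.0 * math.pi)],
    )
    def test_waist_area(self, sigma, theta, expected):
        assert emittance_at_waist(sigma, theta) == pytest.approx(expected, rel=1e-12)

    def test_negative_input_rejected(self):
        with pytest.raises(DomainError):
            emittance_at_waist(-1.0, 1.0)


class TestMoments:
    def test_waist_has_zero_correlation(self):
        m = moments_from_optics(OpticsPlane(2.0, 1.0, 2.0 * math.pi))
        assert m.cov_xxp == pytest.approx(0.0, abs=1e-9)

    def test_zero_emittance_is_fully_correlated(self):
        m = moments_from_optics(OpticsPlane(2.0, 1.0, 0.0, sign=1))
        assert m.cov_xxp == pytest.approx(2.0, rel=1e-12)

    def test_infeasible_triple_rejected(self):
        with pytest.raises(InfeasibleOpticsError):
            OpticsPlane(1.0, 1.0, 4.0 * math.pi)

    @given(feasible_planes)
    def test_round_trip_through_moments(self, plane):
        back = optics_from_moments(moments_from_optics(plane))
        assert back.sigma == pytest.approx(plane.sigma, rel=1e-9)
        assert back.theta == pytest.approx(plane.theta, rel=1e-9)
        assert back.epsilon == pytest.approx(plane.epsilon, rel=1e-6, abs=1e-6)


class TestDrift:
    def test_waist_beam_grows_as_closed_form(self):
        m = moments_from_optics(OpticsPlane(2.0, 1.0, 2.0 * math.pi))
        out = drift(m, 1000.0)
        assert math.sqrt(out.var_x) == pytest.approx(math.sqrt(5.0), rel=1e-12)

    def test_zero_drift_is_identity(self):
        m = SecondMoments(4.0, 1.5, 2.0)
        out = drift(m, 0.0)
        assert (out.var_x, out.cov_xxp, out.var_xp) == (4.0, 1.5, 2.0)

    def test_converging_zero_emittance_beam_focuses_to_point(self):
        m = moments_from_optics(OpticsPlane(2.0, 1.0, 0.0, sign=-1))
        out = drift(m, 2000.0)
        assert out.var_x == pytest.approx(0.0, abs=1e-9)

    @given(feasible_planes, st.floats(-3000, 3000))
    def test_determinant_conserved(self, plane, dz):
        m = moments_from_optics(plane)
        out = drift(m, dz)
        assert out.determinant == pytest.approx(
            m.determinant, rel=1e-12, abs=1e-9
        )

    def test_waist_is_unique_minimum_at_analytic_location(self):
        plane = OpticsPlane(3.0, 2.0, 0.3 * math.pi * 6.0, sign=-1)
        m = moments_from_optics(plane)
        z_star = waist_position(m)
        grid = np.linspace(z_star - 500, z_star + 500, 2001)
        widths = np.array([drift(m, dz).var_x for dz in grid])
        assert abs(grid[np.argmin(widths)] - z_star) <= grid[1] - grid[0]

    def test_sign_flip_mirrors_width_evolution(self):
        eps = 0.4 * math.pi * 3.0 * 2.0
        conv = moments_from_optics(OpticsPlane(3.0, 2.0, eps, sign=-1))
        div = moments_from_optics(OpticsPlane(3.0, 2.0, eps, sign=1))
        for dz in (100.0, 500.0, 1200.0):
            assert drift(conv, dz).var_x == pytest.approx(
                drift(div, -dz).var_x, rel=1e-12
            )


class TestScattering:
    def test_vacuum_segment_contributes_nothing(self):
        seg = Segment(length_mm=1000.0, medium="vacuum")
        inc = air_scattering_moment_increments(100.0, seg, PROTON)
        assert (inc.var_x, inc.cov_xxp, inc.var_xp) == (0.0, 0.0, 0.0)

    def test_increments_match_trapezoid_quadrature_oracle(self):
        """Fermi--Eyges moments vs a 1000-step quadrature of T(z)."""
        seg = Segment(length_mm=1000.0, medium="air")
        inc = air_scattering_moment_increments(100.0, seg, PROTON)
        t = scattering_power(100.0, PROTON, AIR_RADIATION_LENGTH_MM, 1000.0)
        z = np.linspace(0.0, 1000.0, 1001)
        tz = np.full_like(z, t)
        a0 = np.trapezoid(tz, z)
        a1 = np.trapezoid(tz * (1000.0 - z), z)
        a2 = np.trapezoid(tz * (1000.0 - z) ** 2, z)
        assert inc.var_xp == pytest.approx(a0 * 1e6, rel=1e-6)
        assert inc.cov_xxp == pytest.approx(a1 * 1e3, rel=1e-6)
        assert inc.var_x == pytest.approx(a2, rel=1e-4)

    def test_higher_energy_scatters_less(self):
        seg = Segment(length_mm=1000.0, medium="air")
        low = air_scattering_moment_increments(100.0, seg, PROTON)
        high = air_scattering_moment_increments(200.0, seg, PROTON)
        assert high.var_x < low.var_x
        assert high.var_xp < low.var_xp

    def test_nonphysical_energy_rejected(self):
        seg = Segment(length_mm=1000.0, medium="air")
        with pytest.raises(DomainError):
            air_scattering_moment_increments(-5.0, seg, PROTON)


class TestSpotSigma:
    def test_vacuum_path_reproduces_drift_closed_form(self):
        plane = OpticsPlane(2.0, 1.0, 2.0 * math.pi)
        geo = vacuum_line(source_z=0.0, end_z=2000.0)
        (sigma,) = spot_sigma_at(plane, geo, 150.0, PROTON, [1000.0])
        assert sigma == pytest.approx(math.sqrt(5.0), rel=1e-12)

    def test_air_never_shrinks_the_spot(self):
        plane = OpticsPlane(3.0, 2.0, 0.5 * math.pi * 6.0, sign=-1)
        z = [-200.0, 0.0, 200.0]
        in_air = spot_sigma_at(plane, air_line(), 62.0, PROTON, z)
        in_vac = spot_sigma_at(plane, vacuum_line(end_z=250.0), 62.0, PROTON, z)
        assert np.all(in_air >= in_vac)

    def test_upstream_position_rejected(self):
        plane = OpticsPlane(3.0, 2.0, 1.0)
        with pytest.raises(DomainError):
            spot_sigma_at(plane, air_line(), 100.0, PROTON, [-1400.0])

    def test_scattering_only_moments_equal_full_transport_of_point_source(self):
        geo = air_line()
        scat = scattering_moments_at(geo, 62.0, PROTON, 0.0)
        assert scat.var_x > 0
        assert scat.determinant >= 0

    def test_reference_converging_beam_matches_sampling_oracle(self, mc_spot_sigma):
        """62 MeV converging beam vs the 2e6-particle oracle, within 1 %."""
        plane = OpticsPlane(3.0, 2.0, 0.5 * math.pi * 3.0 * 2.0, sign=-1)
        geo = air_line()
        for z in (-200.0, 0.0, 200.0):
            (sigma,) = spot_sigma_at(plane, geo, 62.0, PROTON, [z])
            mc = mc_spot_sigma(plane, geo, 62.0, PROTON, z, seed=17)
            assert sigma == pytest.approx(mc, rel=0.01)

    def test_random_optics_match_sampling_oracle_within_one_percent(self, mc_spot_sigma):
        """20 random feasible optics settings vs the particle oracle."""
        rng = np.random.default_rng(2024)
        geo = air_line()
        for i in range(20):
            plane = OpticsPlane(
                sigma=rng.uniform(1.5, 8.0),
                theta=rng.uniform(0.5, 3.0),
                epsilon=0.0,
                sign=int(rng.choice([-1, 1])),
            )
            plane = OpticsPlane(
                plane.sigma,
                plane.theta,
                rng.uniform(0.05, 0.95) * math.pi * plane.sigma * plane.theta,
                plane.sign,
            )
            energy = rng.uniform(62.0, 253.0)
            z = rng.uniform(-200.0, 200.0)
            (sigma,) = spot_sigma_at(plane, geo, energy, PROTON, [z])
            mc = mc_spot_sigma(plane, geo, energy, PROTON, z, seed=100 + i)
            assert sigma == pytest.approx(mc, rel=0.01), f"setting {i}"
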