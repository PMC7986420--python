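import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def toy_idc():
    """Tiny hand-checkable depth-dose curve: peak 4 at depth 2."""
    depths = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
    dose = np.array([1.0, 2.0, 4.0, 2.0, 0.0])
    return depths, dose


@pytest.fixture(scope="session")
def zero_noise_machine():
    """Small noiseless synthetic machine shared by recovery tests."""
    from beamtune.synthetic import ZERO_NOISE, generate_measurements, make_machine_truth

    truth = make_machine_truth("synchrotron-5", seed=42)
    return truth, generate_measurements(truth, ZERO_NOISE)


@pytest.fixture(scope="session")
def mc_spot_sigma():
    """Particle-sampling oracle for lateral beam size (as a callable)."""
    return _mc_spot_sigma


def _mc_spot_sigma(
    plane,
    geometry,
    energy_mev,
    particle,
    z_target,
    n_particles=2_000_000,
    slab_mm=50.0,
    seed=0,
):
    """Particle-sampling oracle for the lateral beam size at one plane.

    Samples the Gaussian source phase space from the optics triple, then
    alternates free drift with Highland-angle slab kicks through the
    geometry.  Written directly from the transport physics (drift in mm/rad
    units, Highland angle with the log-correction of the full segment
    thickness) so it shares no propagation code with the implementation it
    checks.
    """
    rng = np.random.default_rng(seed)
    s2 = plane.sigma**2
    t2 = (plane.theta * 1e-3) ** 2
    cov = plane.sign * np.sqrt(
        max(s2 * t2 - (plane.epsilon * 1e-3 / np.pi) ** 2, 0.0)
    )
    cov_mat = np.array([[s2, cov], [cov, t2]])
    x, xp = rng.multivariate_normal([0.0, 0.0], cov_mat, size=n_particles).T

    mass = particle.mass_per_nucleon_mev * particle.mass_number
    t_kin = energy_mev * particle.mass_number
    pv = (t_kin**2 + 2 * mass * t_kin) / (t_kin + mass)

    z = geometry.source_z_mm
    for seg in geometry.segments:
        if z >= z_target:
            break
        length = min(seg.length_mm, z_target - z)
        if seg.medium == "vacuum":
            x = x + xp * length
        else:
            ratio = seg.length_mm / seg.radiation_length_mm
            corr = max(1.0 + 0.038 * np.log(ratio), 0.0)
            theta0_sq_per_mm = (13.6 * particle.charge / pv * corr) ** 2 / (
                seg.radiation_length_mm
            )
            n_slabs = max(int(np.ceil(length / slab_mm)), 1)
            dz = length / n_slabs
            kick = np.sqrt(theta0_sq_per_mm * dz)
            # midpoint scheme: kick at slab center, O(dz^2) accurate
            for _ in range(n_slabs):
                x = x + xp * (dz / 2.0)
                xp = xp + kick * rng.standard_normal(n_particles)
                x = x + xp * (dz / 2.0)
        z += length
    return float(np.std(x))
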