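"""Lateral phase-space transport: Gaussian beam optics in vacuum and air.

One transverse plane of a scanned pencil beam is described by the Gaussian
phase-space ellipse of the (x, x') distribution.  Three parameters fix the
ellipse up to its tilt direction: the beam width ``sigma`` [mm], the
divergence ``theta`` [mrad] and the emittance ``epsilon`` [mm mrad], the
latter being the ellipse area.  At the beam waist the ellipse is upright and

    epsilon = pi * sigma * theta.

Away from the waist the ellipse is sheared; the shear (position--angle
correlation) is recovered from the three parameters up to a sign, which is
stored explicitly (+1 diverging, -1 converging).

Internally the second moments <x^2>, <x x'>, <x'^2> are propagated, because
free drift and Fermi--Eyges scattering are exactly linear in the moments.
Multiple Coulomb scattering in air uses the Highland parametrization of the
scattering power integrated over each geometry segment.

Units are mm / mrad / mm mrad throughout the public surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, InfeasibleOpticsError
from .particles import ParticleSpec, momentum_velocity_mev

#: Radiation length of dry air at NTP [mm].
AIR_RADIATION_LENGTH_MM = 304.2e3

#: FWHM of a Gaussian in units of its sigma.
FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))

# Relative slack for the ellipse feasibility check; keeps the exact-waist
# boundary (epsilon == pi*sigma*theta) representable in floating point.
_FEAS_RTOL = 1e-9


def emittance_at_waist(sigma: float, theta: float) -> float:
    """Emittance [mm mrad] of an upright ellipse with width and divergence.

    Only valid at the beam waist, where the phase-space ellipse is upright.
    """
    if sigma < 0 or theta < 0:
        raise DomainError(f"sigma and theta must be >= 0, got ({sigma}, {theta})")
    return math.pi * sigma * theta


@dataclass(frozen=True)
class OpticsPlane:
    """Beam-optics triple of one transverse plane, plus convergence sign.

    ``sign`` = +1 for a diverging beam (positive x--x' correlation), -1 for a
    converging one.  Feasibility requires ``epsilon <= pi * sigma * theta``;
    equality holds exactly at the waist.
    """

    sigma: float
    theta: float
    epsilon: float
    sign: int = 1

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.theta <= 0:
            raise DomainError(
                f"sigma and theta must be > 0, got ({self.sigma}, {self.theta})"
            )
        if self.epsilon < 0:
            raise DomainError(f"epsilon must be >= 0, got {self.epsilon}")
        lim = math.pi * self.sigma * self.theta
        if self.epsilon > lim * (1.0 + _FEAS_RTOL):
            raise InfeasibleOpticsError(
                f"epsilon={self.epsilon} exceeds pi*sigma*theta={lim}"
            )
        if self.sign not in (-1, 1):
            raise DomainError(f"sign must be +1 or -1, got {self.sign}")

    @property
    def emittance_fraction(self) -> float:
        """epsilon relative to the waist bound pi*sigma*theta (1 at a waist)."""
        return self.epsilon / (math.pi * self.sigma * self.theta)


@dataclass(frozen=True)
class SecondMoments:
    """Second moments of the (x, x') distribution: mm^2, mm mrad, mrad^2."""

    var_x: float
    cov_xxp: float
    var_xp: float

    def __post_init__(self) -> None:
        if self.var_x < 0 or self.var_xp < 0:
            raise DomainError("variances must be >= 0")

    @property
    def determinant(self) -> float:
        """var_x*var_xp - cov^2 [mm^2 mrad^2]; equals (epsilon/pi)^2."""
        return self.var_x * self.var_xp - self.cov_xxp**2

    @property
    def sigma(self) -> float:
        return math.sqrt(self.var_x)


def moments_from_optics(plane: OpticsPlane) -> SecondMoments:
    """Convert (sigma, theta, epsilon, sign) to second moments.

    The correlation magnitude follows from the conserved ellipse area:
    ``cov = sign * sqrt(sigma^2 theta^2 - (epsilon/pi)^2)``.
    """
    s2t2 = (plane.sigma * plane.theta) ** 2
    det = (plane.epsilon / math.pi) ** 2
    # Tolerate the rounding slack admitted by the OpticsPlane invariant.
    cov = plane.sign * math.sqrt(max(s2t2 - det, 0.0))
    return SecondMoments(plane.sigma**2, cov, plane.theta**2)


def optics_from_moments(m: SecondMoments) -> OpticsPlane:
    """Inverse of :func:`moments_from_optics` (sign from the correlation)."""
    det = m.determinant
    scale = max(m.var_x * m.var_xp, 1e-300)
    if det < 0:
        if -det > 1e-9 * scale:
            raise InfeasibleOpticsError(f"moment determinant is negative: {det}")
        det = 0.0  # rounding at the waist boundary
    return OpticsPlane(
        sigma=math.sqrt(m.var_x),
        theta=math.sqrt(m.var_xp),
        epsilon=math.pi * math.sqrt(det),
        sign=-1 if m.cov_xxp < 0 else 1,
    )


def drift(m: SecondMoments, dz: float) -> SecondMoments:
    """Free drift of the second moments over ``dz`` [mm].

    ``dz`` may be negative (propagation upstream).  The moment determinant --
    the squared ellipse area over pi^2 -- is conserved exactly.
    """
    if not math.isfinite(dz):
        raise DomainError(f"dz must be finite, got {dz}")
    t = dz * 1e-3  # mrad -> rad unit bridge
    return SecondMoments(
        var_x=m.var_x + 2.0 * t * m.cov_xxp + t * t * m.var_xp,
        cov_xxp=m.cov_xxp + dz * 1e-3 * m.var_xp,
        var_xp=m.var_xp,
    )


def waist_position(m: SecondMoments) -> float:
    """Drift distance [mm] from the current plane to the beam waist.

    Negative for a beam that already passed its waist (diverging).
    """
    if m.var_xp == 0:
        raise DomainError("zero divergence beam has no waist")
    return -m.cov_xxp / m.var_xp * 1e3


@dataclass(frozen=True)
class Segment:
    """One stretch of the beam path with a homogeneous medium."""

    length_mm: float
    medium: str  # "vacuum" | "air"
    radiation_length_mm: float = AIR_RADIATION_LENGTH_MM

    def __post_init__(self) -> None:
        if self.length_mm <= 0:
            raise DomainError(f"segment length must be > 0, got {self.length_mm}")
        if self.medium not in ("vacuum", "air"):
            raise DomainError(f"medium must be 'vacuum' or 'air', got {self.medium!r}")
        if self.radiation_length_mm <= 0:
            raise DomainError("radiation length must be > 0")


@dataclass(frozen=True)
class BeamlineGeometry:
    """Axial layout of the modeled beam line.

    The isocenter sits at z = 0 and the beam travels toward +z.  Segments are
    contiguous starting at ``source_z_mm`` (which must be upstream, i.e.
    negative of every measurement plane).  ``phantom_surface_z_mm`` marks
    where the water phantom begins for depth-dose simulation.
    """

    source_z_mm: float
    segments: tuple[Segment, ...]
    measurement_positions_mm: tuple[float, ...] = ()
    phantom_surface_z_mm: float = 0.0

    def __post_init__(self) -> None:
        if not self.segments:
            raise DomainError("geometry needs at least one segment")
        object.__setattr__(self, "segments", tuple(self.segments))
        object.__setattr__(
            self, "measurement_positions_mm", tuple(self.measurement_positions_mm)
        )
        for z in self.measurement_positions_mm:
            if z <= self.source_z_mm:
                raise DomainError(
                    f"measurement plane {z} mm is not downstream of the "
                    f"source at {self.source_z_mm} mm"
                )
            if z > self.end_z_mm + 1e-9:
                raise DomainError(
                    f"measurement plane {z} mm lies beyond the modeled path "
                    f"ending at {self.end_z_mm} mm"
                )

    @property
    def end_z_mm(self) -> float:
        return self.source_z_mm + sum(s.length_mm for s in self.segments)

    def boundaries(self) -> list[float]:
        """Segment boundary z positions, starting at the source plane."""
        z = [self.source_z_mm]
        for s in self.segments:
            z.append(z[-1] + s.length_mm)
        return z


def scattering_power(
    energy_per_u: float,
    particle: ParticleSpec,
    radiation_length_mm: float,
    correction_length_mm: float,
) -> float:
    """Highland scattering power T [rad^2/mm] in a homogeneous medium.

    T is defined so that the squared Highland angle of a slab of thickness L
    is ``T * L``, with the logarithmic thickness correction evaluated at
    ``correction_length_mm`` (conventionally the full slab traversed, so that
    the correction is applied once per physical scatterer rather than per
    integration step).
    """
    pv = momentum_velocity_mev(energy_per_u, particle)
    ratio = correction_length_mm / radiation_length_mm
    if ratio <= 0:
        raise DomainError("correction length must be > 0")
    corr = max(1.0 + 0.038 * math.log(ratio), 0.0)
    theta0_per_sqrt_mm = 13.6 / pv * particle.charge * corr
    return theta0_per_sqrt_mm**2 / radiation_length_mm


def air_scattering_moment_increments(
    energy_per_u: float,
    segment: Segment,
    particle: ParticleSpec,
    length_mm: float | None = None,
) -> SecondMoments:
    """Fermi--Eyges moment increments for traversing (part of) a segment.

    Returns the scattering contributions accumulated at the *end* of the
    traversed length: with constant scattering power T over a length L,

        d<x'^2> = T L          (A0)
        d<x x'> = T L^2 / 2    (A1)
        d<x^2>  = T L^3 / 3    (A2)

    converted to mrad^2 / mm mrad / mm^2.  Vacuum segments contribute zero.
    The Highland log-correction uses the full segment length also for partial
    traversals, so increments are additive along a segment.
    """
    length = segment.length_mm if length_mm is None else length_mm
    if length < 0 or length > segment.length_mm * (1 + 1e-12):
        raise DomainError(f"traversed length {length} outside segment")
    if segment.medium == "vacuum" or length == 0.0:
        return SecondMoments(0.0, 0.0, 0.0)
    t = scattering_power(
        energy_per_u, particle, segment.radiation_length_mm, segment.length_mm
    )
    return SecondMoments(
        var_x=t * length**3 / 3.0,
        cov_xxp=t * length**2 / 2.0 * 1e3,
        var_xp=t * length * 1e6,
    )


def _advance(
    m: SecondMoments,
    segment: Segment,
    length_mm: float,
    energy_per_u: float,
    particle: ParticleSpec,
) -> SecondMoments:
    """Drift + scattering through ``length_mm`` of one segment."""
    drifted = drift(m, length_mm)
    if segment.medium == "vacuum":
        return drifted
    inc = air_scattering_moment_increments(energy_per_u, segment, particle, length_mm)
    return SecondMoments(
        var_x=drifted.var_x + inc.var_x,
        cov_xxp=drifted.cov_xxp + inc.cov_xxp,
        var_xp=drifted.var_xp + inc.var_xp,
    )


def propagate_moments(
    plane: OpticsPlane,
    geometry: BeamlineGeometry,
    energy_per_u: float,
    particle: ParticleSpec,
    z_mm: float,
) -> SecondMoments:
    """Second moments at axial position ``z_mm``, starting from the source."""
    if z_mm < geometry.source_z_mm:
        raise DomainError(
            f"z={z_mm} mm is upstream of the source at {geometry.source_z_mm} mm"
        )
    if z_mm > geometry.end_z_mm + 1e-9:
        raise DomainError(
            f"z={z_mm} mm is beyond the modeled path ending at {geometry.end_z_mm} mm"
        )
    m = moments_from_optics(plane)
    z = geometry.source_z_mm
    for seg in geometry.segments:
        if z >= z_mm:
            break
        step = min(seg.length_mm, z_mm - z)
        m = _advance(m, seg, step, energy_per_u, particle)
        z += step
    return m


def scattering_moments_at(
    geometry: BeamlineGeometry,
    energy_per_u: float,
    particle: ParticleSpec,
    z_mm: float,
) -> SecondMoments:
    """Pure-scattering moments accumulated from the source plane to ``z_mm``.

    This is the beam-size contribution of the traversed media alone (zero
    initial phase-space area); subtracting its ``var_x`` from a measured
    squared spot size isolates the vacuum-optics part of the beam.
    """
    if z_mm < geometry.source_z_mm or z_mm > geometry.end_z_mm + 1e-9:
        raise DomainError(f"z={z_mm} mm outside the modeled path")
    m = SecondMoments(0.0, 0.0, 0.0)
    z = geometry.source_z_mm
    for seg in geometry.segments:
        if z >= z_mm:
            break
        step = min(seg.length_mm, z_mm - z)
        m = _advance(m, seg, step, energy_per_u, particle)
        z += step
    return m


def spot_sigma_at(
    plane: OpticsPlane,
    geometry: BeamlineGeometry,
    energy_per_u: float,
    particle: ParticleSpec,
    z_positions_mm,
) -> np.ndarray:
    """Beam sigma [mm] at each requested plane along the modeled path."""
    out = np.empty(len(z_positions_mm))
    for i, z in enumerate(z_positions_mm):
        out[i] = propagate_moments(plane, geometry, energy_per_u, particle, z).sigma
    return out


def spot_fwhm_at(
    plane: OpticsPlane,
    geometry: BeamlineGeometry,
    energy_per_u: float,
    particle: ParticleSpec,
    z_positions_mm,
) -> np.ndarray:
    """Gaussian-equivalent FWHM [mm] at each requested plane."""
    return FWHM_PER_SIGMA * spot_sigma_at(
        plane, geometry, energy_per_u, particle, z_positions_mm
    )
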