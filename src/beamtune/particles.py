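"""Particle species and relativistic kinematics.

The forward models need only a handful of per-species constants: the
Bragg--Kleeman range--energy coefficients ``R_cm = alpha * E^p`` (protons in
water: alpha = 0.0022 cm/MeV^p, p = 1.77), the range-straggling power law
``sigma_cm = c * R_cm^m``, and rest mass / charge for multiple-Coulomb
scattering kinematics.  Everything else (stopping-power tables, nuclear
interactions) is deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DomainError

#: Proton rest mass [MeV/c^2] (CODATA).
PROTON_MASS_MEV = 938.27208816
#: Atomic mass unit [MeV/c^2], used for heavier ions.
AMU_MEV = 931.49410242


@dataclass(frozen=True)
class ParticleSpec:
    """Physical constants describing one beam species.

    Energies are kinetic, in MeV for protons and MeV/u for heavier ions;
    ranges are in water.  ``bragg_kleeman_alpha`` is in cm/MeV^p so that
    ``alpha * E^p`` yields a range in cm; ``straggling_c``/``straggling_m``
    parametrize the range-straggling sigma as ``c * R_cm^m`` (cm).
    """

    name: str
    mass_number: int
    charge: int
    mass_per_nucleon_mev: float
    bragg_kleeman_alpha: float
    bragg_kleeman_p: float
    straggling_c: float
    straggling_m: float

    def __post_init__(self) -> None:
        if self.mass_number < 1 or self.charge < 1:
            raise DomainError("mass_number and charge must be >= 1")
        if self.bragg_kleeman_alpha <= 0:
            raise DomainError("bragg_kleeman_alpha must be > 0")
        if not 1.0 < self.bragg_kleeman_p < 2.2:
            raise DomainError("bragg_kleeman_p must lie in (1, 2.2)")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "mass_number": self.mass_number,
            "charge": self.charge,
            "mass_per_nucleon_mev": self.mass_per_nucleon_mev,
            "bragg_kleeman_alpha": self.bragg_kleeman_alpha,
            "bragg_kleeman_p": self.bragg_kleeman_p,
            "straggling_c": self.straggling_c,
            "straggling_m": self.straggling_m,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParticleSpec":
        return cls(**d)


#: Protons in water; alpha/p are the classic Bragg--Kleeman values and
#: c/m the standard range-straggling power law for water.
PROTON = ParticleSpec(
    name="proton",
    mass_number=1,
    charge=1,
    mass_per_nucleon_mev=PROTON_MASS_MEV,
    bragg_kleeman_alpha=0.0022,
    bragg_kleeman_p=1.77,
    straggling_c=0.012,
    straggling_m=0.935,
)

# Effective carbon constants: at equal E/u the range scales with A/Z^2
# relative to protons, and straggling (relative to range) is suppressed by
# roughly 1/sqrt(A).  Fragmentation tails are not modeled.
CARBON = ParticleSpec(
    name="carbon",
    mass_number=12,
    charge=6,
    mass_per_nucleon_mev=AMU_MEV,
    bragg_kleeman_alpha=0.0022 * 12 / 36,
    bragg_kleeman_p=1.77,
    straggling_c=0.012 / 12**0.5,
    straggling_m=0.935,
)

PARTICLES = {p.name: p for p in (PROTON, CARBON)}


def momentum_velocity_mev(energy_per_u: float, particle: ParticleSpec) -> float:
    """Return ``p*v`` [MeV] for a kinetic energy per nucleon.

    ``p*v = (pc)^2 / W`` with total kinetic energy ``T = A*E_u`` and total
    rest mass ``M = A * m_u``; this is the quantity entering the Highland
    scattering-angle formula.
    """
    if energy_per_u <= 0:
        raise DomainError(f"kinetic energy must be > 0, got {energy_per_u}")
    t = particle.mass_number * energy_per_u
    m = particle.mass_number * particle.mass_per_nucleon_mev
    return (t * t + 2.0 * m * t) / (t + m)
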