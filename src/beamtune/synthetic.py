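"""Synthetic commissioning machines: ground truth plus noisy measurements.

A :class:`MachineTruth` holds smooth, low-order parameter-versus-energy
curves -- the "hidden" accelerator settings -- from which the forward
engines generate exactly the tables a commissioning campaign produces:
per-energy laterally integrated depth-dose curves in water and spot-size
(FWHM) records in air at several isocenter distances.  Running the tuning
pipeline on such a dataset turns every pipeline stage into a parameter-
recovery experiment with a known answer.

Presets mirror common clinical layouts: a synchrotron covering 62-253 MeV
protons with 20 (or 5) uniformly spaced energies and spot planes at 0,
+-100 and +-200 mm around the isocenter, and a cyclotron covering
100-226.7 MeV with 27 energies and planes at 0, +-100, +-150 mm.

Noise defaults emulate a well-conducted measurement campaign: 0.5 %
multiplicative noise per IDC dose bin and 0.05 mm additive noise per FWHM
record.  Zero-noise configurations reproduce the forward model exactly,
which the exact-recovery tests exploit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .depth_dose import DepthDoseCurve, EnergySpectrum, simulate_idc
from .errors import DomainError
from .optics import (
    AIR_RADIATION_LENGTH_MM,
    BeamlineGeometry,
    OpticsPlane,
    Segment,
    spot_fwhm_at,
)
from .particles import PARTICLES, ParticleSpec
from .tuning import MeasurementSet

_TRUTH_PARAMS = (
    "energy_offset",
    "sigma_e",
    "sigma_x",
    "theta_x",
    "eps_frac_x",
    "sigma_y",
    "theta_y",
    "eps_frac_y",
)


@dataclass(frozen=True)
class NoiseConfig:
    """Measurement-noise magnitudes and the seed that realizes them."""

    idc_dose_relative_sigma: float = 0.005
    fwhm_absolute_sigma: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.idc_dose_relative_sigma < 0 or self.fwhm_absolute_sigma < 0:
            raise DomainError("noise sigmas must be >= 0")


ZERO_NOISE = NoiseConfig(idc_dose_relative_sigma=0.0, fwhm_absolute_sigma=0.0)


@dataclass(frozen=True)
class MachineTruth:
    """Hidden ground-truth parameter curves of a synthetic beam line.

    Each entry of ``curves`` maps a parameter name to polynomial
    coefficients (lowest first) in the shifted energy ``u = E - energies[0]``.
    ``energy_offset`` is the deviation of the true mean energy from the
    nominal one; the emittances are stored as fractions of the waist bound
    ``pi * sigma * theta`` so feasibility holds by construction.
    """

    particle: ParticleSpec
    energies: np.ndarray
    curves: dict
    signs: dict
    geometry: BeamlineGeometry
    seed: int
    preset: str = "custom"

    def __post_init__(self) -> None:
        energies = np.asarray(self.energies, dtype=float)
        object.__setattr__(self, "energies", energies)
        missing = set(_TRUTH_PARAMS) - set(self.curves)
        if missing:
            raise DomainError(f"truth curves missing {sorted(missing)}")
        for e in energies:
            self.spectrum(e)  # validates positivity / spread bound
            for plane_id in ("x", "y"):
                self.optics(e, plane_id)  # validates feasibility

    def _eval(self, name: str, energy: float) -> float:
        u = energy - self.energies[0]
        return float(np.polynomial.polynomial.polyval(u, self.curves[name]))

    def spectrum(self, energy: float) -> EnergySpectrum:
        return EnergySpectrum(
            energy=energy + self._eval("energy_offset", energy),
            sigma_e=self._eval("sigma_e", energy),
        )

    def optics(self, energy: float, plane_id: str) -> OpticsPlane:
        sigma = self._eval(f"sigma_{plane_id}", energy)
        theta = self._eval(f"theta_{plane_id}", energy)
        frac = self._eval(f"eps_frac_{plane_id}", energy)
        if not 0.0 < frac < 1.0:
            raise DomainError(
                f"emittance fraction {frac:.3f} at {energy} MeV ({plane_id}) "
                "outside (0, 1): truth curves infeasible"
            )
        return OpticsPlane(
            sigma=sigma,
            theta=theta,
            epsilon=frac * math.pi * sigma * theta,
            sign=self.signs[plane_id],
        )


def _preset_layout(name: str) -> dict:
    source_z = -1300.0
    if name == "synchrotron-20":
        return {
            "energies": np.linspace(62.0, 253.0, 20),
            "positions": (-200.0, -100.0, 0.0, 100.0, 200.0),
            "source_z": source_z,
            "path_end": 250.0,
        }
    if name == "synchrotron-5":
        return {
            "energies": np.linspace(62.0, 253.0, 5),
            "positions": (-200.0, -100.0, 0.0, 100.0, 200.0),
            "source_z": source_z,
            "path_end": 250.0,
        }
    if name == "cyclotron-27":
        return {
            "energies": np.linspace(100.0, 226.7, 27),
            "positions": (-150.0, -100.0, 0.0, 100.0, 150.0),
            "source_z": -1100.0,
            "path_end": 200.0,
        }
    raise DomainError(
        f"unknown preset {name!r}; available: synchrotron-20, synchrotron-5, "
        "cyclotron-27"
    )


# Base truth-curve coefficients in u = E - E_min; the per-seed jitter below
# perturbs them a few percent so different seeds yield different machines.
_BASE_CURVES = {
    "energy_offset": (0.4, -2e-3, 1e-5),
    "sigma_e": (0.45, 4e-3),
    "sigma_x": (7.5, -1.0e-2),
    "theta_x": (2.4, -3.0e-3),
    "eps_frac_x": (0.45, 5e-4),
    "sigma_y": (5.0, -5.0e-3),
    "theta_y": (1.8, -2.0e-3),
    "eps_frac_y": (0.5, 2e-4),
}

_BASE_SIGNS = {"x": -1, "y": 1}


def make_machine_truth(
    preset: str = "synchrotron-20",
    seed: int = 0,
    particle: str | ParticleSpec = "proton",
    curves: dict | None = None,
    signs: dict | None = None,
) -> MachineTruth:
    """Create a ground-truth machine, deterministic in ``seed``.

    The preset fixes energies, geometry and measurement planes; the truth
    curves start from realistic base values and receive a small seeded
    jitter (a few percent on leading coefficients).  Custom ``curves`` /
    ``signs`` override the jittered defaults entirely and are validated for
    feasibility at every nominal energy.
    """
    layout = _preset_layout(preset)
    if isinstance(particle, str):
        try:
            particle = PARTICLES[particle]
        except KeyError:
            raise DomainError(f"unknown particle {particle!r}") from None
    if curves is None:
        rng = np.random.default_rng(seed)
        curves = {}
        for name, base in _BASE_CURVES.items():
            scale = 1.0 + 0.03 * rng.standard_normal()
            curves[name] = tuple(c * scale for c in base)
    geometry = BeamlineGeometry(
        source_z_mm=layout["source_z"],
        segments=(
            Segment(
                length_mm=layout["path_end"] - layout["source_z"],
                medium="air",
                radiation_length_mm=AIR_RADIATION_LENGTH_MM,
            ),
        ),
        measurement_positions_mm=layout["positions"],
        phantom_surface_z_mm=0.0,
    )
    return MachineTruth(
        particle=particle,
        energies=layout["energies"],
        curves=dict(curves),
        signs=dict(signs or _BASE_SIGNS),
        geometry=geometry,
        seed=seed,
        preset=preset,
    )


def generate_measurements(
    truth: MachineTruth,
    noise: NoiseConfig = NoiseConfig(),
    straggling_scale: float = 1.0,
) -> MeasurementSet:
    """Generate a noisy commissioning dataset from a ground-truth machine.

    IDCs receive multiplicative Gaussian noise per dose bin, spot FWHMs
    additive Gaussian noise; every output is fully determined by
    ``(truth.seed, noise.rng_seed)``.  ``straggling_scale`` perturbs the
    generator's range-straggling coefficient to emulate a forward-model
    mismatch between machine and tuning engine (1.0 = perfect match).
    """
    rng = np.random.default_rng(noise.rng_seed)
    particle = truth.particle
    if straggling_scale != 1.0:
        particle = replace(
            particle, straggling_c=particle.straggling_c * straggling_scale
        )
    idcs = {}
    spot_rows = []
    positions = np.asarray(truth.geometry.measurement_positions_mm)
    for energy in truth.energies:
        spectrum = truth.spectrum(energy)
        clean = simulate_idc(spectrum, particle)
        dose = clean.dose * (
            1.0 + noise.idc_dose_relative_sigma * rng.standard_normal(clean.dose.size)
        )
        idcs[float(energy)] = DepthDoseCurve(
            depths=clean.depths, dose=np.maximum(dose, 0.0)
        )
        fwhm = {}
        for plane_id in ("x", "y"):
            clean_fwhm = spot_fwhm_at(
                truth.optics(energy, plane_id),
                truth.geometry,
                spectrum.energy,
                truth.particle,
                positions,
            )
            fwhm[plane_id] = clean_fwhm + noise.fwhm_absolute_sigma * rng.standard_normal(
                positions.size
            )
        for i, z in enumerate(positions):
            spot_rows.append(
                {
                    "energy_MeV": float(energy),
                    "position_mm": float(z),
                    "fwhm_x_mm": float(fwhm["x"][i]),
                    "fwhm_y_mm": float(fwhm["y"][i]),
                }
            )
    return MeasurementSet(
        particle=truth.particle,
        geometry=truth.geometry,
        energies=truth.energies.copy(),
        idcs=idcs,
        spots=pd.DataFrame(spot_rows),
    )
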