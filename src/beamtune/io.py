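"""File formats: IDC and spot-size CSV tables, geometry and manifest JSON.

All tables are plain comma-separated text with a single header line, '.'
decimal separator and UTF-8 encoding; writers and readers round-trip
exactly (floats are written in shortest-repr form).  A measurement set on
disk is a directory containing ``manifest.json``, ``geometry.json``,
``spots.csv`` and one ``idc_NN.csv`` per nominal energy.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .depth_dose import DepthDoseCurve
from .errors import DomainError, MeasurementFormatError
from .optics import BeamlineGeometry, Segment
from .particles import ParticleSpec
from .tuning import MeasurementSet, TuningConfig

MANIFEST_NAME = "manifest.json"
GEOMETRY_NAME = "geometry.json"
SPOTS_NAME = "spots.csv"

SPOT_COLUMNS = ["energy_MeV", "position_mm", "fwhm_x_mm", "fwhm_y_mm"]


# ---------------------------------------------------------------------------
# IDC curves
# ---------------------------------------------------------------------------


def write_idc(path, curve: DepthDoseCurve) -> None:
    """Write a depth-dose curve as two-column CSV with a header line."""
    lines = ["depth_mm,dose"]
    lines += [f"{float(d)!r},{float(v)!r}" for d, v in zip(curve.depths, curve.dose)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_idc(path) -> DepthDoseCurve:
    """Read a two-column IDC CSV; malformed rows are reported by line number."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip().lower() not in ("depth_mm,dose",):
        raise MeasurementFormatError(
            f"{path}: first line must be the header 'depth_mm,dose'"
        )
    depths, dose = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        try:
            d, v = float(parts[0]), float(parts[1])
        except (ValueError, IndexError):
            raise MeasurementFormatError(
                f"{path}:{lineno}: expected 'depth,dose', got {line!r}"
            ) from None
        depths.append(d)
        dose.append(v)
    depths = np.asarray(depths)
    bad = np.nonzero(np.diff(depths) <= 0)[0]
    if bad.size:
        raise MeasurementFormatError(
            f"{path}:{int(bad[0]) + 3}: depth grid not strictly increasing"
        )
    try:
        return DepthDoseCurve(depths=depths, dose=np.asarray(dose))
    except DomainError as exc:
        raise MeasurementFormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Spot tables
# ---------------------------------------------------------------------------


def write_spots(path, spots: pd.DataFrame) -> None:
    spots.to_csv(path, index=False, columns=SPOT_COLUMNS)


def read_spots(path) -> pd.DataFrame:
    path = Path(path)
    try:
        spots = pd.read_csv(path)
    except Exception as exc:
        raise MeasurementFormatError(f"{path}: unreadable CSV: {exc}") from exc
    missing = set(SPOT_COLUMNS) - set(spots.columns)
    if missing:
        raise MeasurementFormatError(f"{path}: missing columns {sorted(missing)}")
    if spots[SPOT_COLUMNS].isna().any().any():
        bad = int(spots[SPOT_COLUMNS].isna().any(axis=1).idxmax()) + 2
        raise MeasurementFormatError(f"{path}:{bad}: non-numeric or missing value")
    return spots


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


def geometry_to_dict(geometry: BeamlineGeometry) -> dict:
    return {
        "source_z_mm": geometry.source_z_mm,
        "segments": [
            {
                "length_mm": s.length_mm,
                "medium": s.medium,
                "radiation_length_mm": s.radiation_length_mm,
            }
            for s in geometry.segments
        ],
        "measurement_positions_mm": list(geometry.measurement_positions_mm),
        "phantom_surface_z_mm": geometry.phantom_surface_z_mm,
    }


def geometry_from_dict(d: dict) -> BeamlineGeometry:
    return BeamlineGeometry(
        source_z_mm=d["source_z_mm"],
        segments=tuple(Segment(**s) for s in d["segments"]),
        measurement_positions_mm=tuple(d.get("measurement_positions_mm", ())),
        phantom_surface_z_mm=d.get("phantom_surface_z_mm", 0.0),
    )


def write_geometry(path, geometry: BeamlineGeometry) -> None:
    Path(path).write_text(
        json.dumps(geometry_to_dict(geometry), indent=2, sort_keys=True)
    )


def read_geometry(path) -> BeamlineGeometry:
    return geometry_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Measurement sets
# ---------------------------------------------------------------------------


def write_measurement_set(
    measurements: MeasurementSet, directory, seeds: dict | None = None
) -> Path:
    """Write a measurement set plus manifest; returns the directory path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    idc_files = {}
    for i, energy in enumerate(measurements.energies):
        name = f"idc_{i:02d}.csv"
        write_idc(directory / name, measurements.idcs[energy])
        idc_files[f"{float(energy)!r}"] = name
    write_spots(directory / SPOTS_NAME, measurements.spots)
    write_geometry(directory / GEOMETRY_NAME, measurements.geometry)
    manifest = {
        "particle": measurements.particle.to_dict(),
        "energies_MeV": [float(e) for e in measurements.energies],
        "idc_files": idc_files,
        "spots_file": SPOTS_NAME,
        "geometry_file": GEOMETRY_NAME,
        "seeds": seeds or {},
    }
    (directory / MANIFEST_NAME).write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return directory


def read_measurement_set(directory) -> MeasurementSet:
    """Load and validate a measurement set directory."""
    directory = Path(directory)
    manifest_path = directory / MANIFEST_NAME
    if not manifest_path.exists():
        raise MeasurementFormatError(f"{directory}: no {MANIFEST_NAME} found")
    manifest = json.loads(manifest_path.read_text())
    energies = [float(e) for e in manifest["energies_MeV"]]
    duplicates = sorted({e for e in energies if energies.count(e) > 1})
    if duplicates:
        raise MeasurementFormatError(
            f"{manifest_path}: duplicate energy entries {duplicates}"
        )
    idcs = {}
    for energy in energies:
        key = f"{energy!r}"
        if key not in manifest["idc_files"]:
            raise MeasurementFormatError(
                f"{manifest_path}: no IDC file listed for energy {energy} MeV"
            )
        idc_path = directory / manifest["idc_files"][key]
        if not idc_path.exists():
            raise MeasurementFormatError(
                f"{idc_path}: missing IDC for energy {energy} MeV"
            )
        idcs[energy] = read_idc(idc_path)
    spots = read_spots(directory / manifest.get("spots_file", SPOTS_NAME))
    geometry = read_geometry(directory / manifest.get("geometry_file", GEOMETRY_NAME))
    return MeasurementSet(
        particle=ParticleSpec.from_dict(manifest["particle"]),
        geometry=geometry,
        energies=np.asarray(sorted(energies)),
        idcs=idcs,
        spots=spots,
    )


# ---------------------------------------------------------------------------
# Run configuration and reproducibility records
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Top-level pipeline configuration loaded from YAML or JSON."""

    measurements_dir: str = "measurements"
    output_dir: str = "output"
    tuning: TuningConfig = dataclasses.field(default_factory=TuningConfig)
    evaluation_energy_count: int = 5
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "measurements_dir": self.measurements_dir,
            "output_dir": self.output_dir,
            "tuning": dataclasses.asdict(self.tuning),
            "evaluation_energy_count": self.evaluation_energy_count,
            "log_level": self.log_level,
        }


def load_run_config(path) -> RunConfig:
    path = Path(path)
    text = path.read_text()
    data = (
        yaml.safe_load(text)
        if path.suffix in (".yml", ".yaml")
        else json.loads(text)
    )
    tuning = TuningConfig(**data.pop("tuning", {}))
    return RunConfig(tuning=tuning, **data)


def write_run_record(directory, stage: str, payload: dict) -> Path:
    """Persist a reproducibility record (config, seeds, package version)."""
    from . import __version__

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    record = {"stage": stage, "beamtune_version": __version__, **payload}
    path = directory / f"run_record_{stage}.json"
    path.write_text(json.dumps(record, indent=2, sort_keys=True, default=str))
    return path
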