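"""CSV and JSON readers/writers for curves and results.

CSV dialect: comma-separated UTF-8, ``#`` comment lines ignored. Curve
metadata (unstressed diameter, axial stretch, segment/quadrant) travels in
``# key = value`` comment lines so a write→read round-trip reproduces the
object. Headers are ``pressure_mmHg,outer_diameter_mm`` for inflation
curves and ``strain,stress_kPa`` for stress–strain curves.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .units import MMHG_TO_PA
from .vessel_mechanics import PressureDiameterCurve, StressStrainCurve

__all__ = [
    "write_pressure_diameter_csv",
    "read_pressure_diameter_csv",
    "write_stress_strain_csv",
    "read_stress_strain_csv",
    "write_json_report",
]

def _parse_csv(path: Path, expected_header: str) -> tuple[dict, np.ndarray]:
    if not path.exists():
        raise ConfigurationError(f"CSV file not found: {path}")
    meta: dict[str, str] = {}
    rows: list[tuple[float, float]] = []
    header_seen = False
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
            continue
        if not header_seen:
            if line.replace(" ", "") != expected_header:
                raise ConfigurationError(
                    f"{path}:{lineno}: expected header {expected_header!r}, "
                    f"got {line!r}"
                )
            header_seen = True
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise ConfigurationError(
                f"{path}:{lineno}: expected 2 comma-separated fields, got {line!r}"
            )
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError as exc:
            raise ConfigurationError(f"{path}:{lineno}: {exc}") from exc
    if not rows:
        raise ConfigurationError(f"{path}: no data rows")
    return meta, np.asarray(rows)


def write_pressure_diameter_csv(curve: PressureDiameterCurve, path: str | Path) -> None:
    path = Path(path)
    lines = [
        f"# D_o_mm = {curve.D_o * 1e3:.17g}",
        f"# axial_stretch = {curve.axial_stretch:.17g}",
        f"# segment = {curve.segment}",
        "pressure_mmHg,outer_diameter_mm",
    ]
    for p, d in zip(curve.pressures, curve.outer_diameters):
        lines.append(f"{p / MMHG_TO_PA:.17g},{d * 1e3:.17g}")
    path.write_text("\n".join(lines) + "\n")


def read_pressure_diameter_csv(path: str | Path) -> PressureDiameterCurve:
    path = Path(path)
    meta, data = _parse_csv(path, "pressure_mmHg,outer_diameter_mm")
    if "D_o_mm" not in meta:
        raise ConfigurationError(f"{path}: missing '# D_o_mm = ...' metadata line")
    return PressureDiameterCurve(
        pressures=data[:, 0] * MMHG_TO_PA,
        outer_diameters=data[:, 1] * 1e-3,
        D_o=float(meta["D_o_mm"]) * 1e-3,
        axial_stretch=float(meta.get("axial_stretch", 1.2)),
        segment=meta.get("segment", "ascending"),
    )


def write_stress_strain_csv(curve: StressStrainCurve, path: str | Path) -> None:
    path = Path(path)
    lines = [f"# quadrant = {curve.quadrant}", "strain,stress_kPa"]
    for e, s in zip(curve.strains, curve.stresses):
        lines.append(f"{e:.17g},{s / 1e3:.17g}")
    path.write_text("\n".join(lines) + "\n")


def read_stress_strain_csv(path: str | Path) -> StressStrainCurve:
    path = Path(path)
    meta, data = _parse_csv(path, "strain,stress_kPa")
    return StressStrainCurve(
        strains=data[:, 0],
        stresses=data[:, 1] * 1e3,
        quadrant=meta.get("quadrant", "mean"),
    )


def write_json_report(report: dict, path: str | Path) -> None:
    """Write a machine-readable result report (numbers at full precision)."""
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
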