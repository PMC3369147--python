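"""Reading and writing the package's file formats.

Meshes: PLY / STL / OBJ through trimesh (binary or ASCII). Rim curves:
JSON array of [x, y, z] points in mm, or CSV with x,y,z columns, ordered
counterclockwise as seen from the acetabular side. Landmarks: the JSON
schema of :class:`hipcov.radiograph2d.RadiographLandmarks`, or a CSV with
one named landmark per row. Coverage reports: JSON / CSV.
"""
from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import trimesh

from .coverage3d import RegionCoverage, RimCurve
from .radiograph2d import RadiographLandmarks


def load_mesh(path) -> trimesh.Trimesh:
    """Load and clean a surface mesh (merges duplicate vertices, drops
    degenerate faces, fixes winding)."""
    mesh = trimesh.load_mesh(str(path), process=True)
    if isinstance(mesh, trimesh.Scene):  # pragma: no cover - multi-body files
        mesh = trimesh.util.concatenate(list(mesh.geometry.values()))
    mesh.update_faces(mesh.nondegenerate_faces())
    mesh.remove_unreferenced_vertices()
    if len(mesh.faces) == 0:
        raise ValueError(f"no usable faces in {path}")
    return mesh


def save_mesh(mesh: trimesh.Trimesh, path) -> None:
    mesh.export(str(path))


def load_rim(path) -> RimCurve:
    path = Path(path)
    if path.suffix.lower() == ".json":
        pts = np.asarray(json.loads(path.read_text()), dtype=float)
    else:
        rows = []
        with open(path) as fh:
            for row in csv.reader(fh):
                if not row or not _is_number(row[0]):
                    continue  # header or blank
                rows.append([float(v) for v in row[:3]])
        pts = np.asarray(rows, dtype=float)
    return RimCurve(pts)


def save_rim(rim: RimCurve, path) -> None:
    Path(path).write_text(json.dumps(rim.points.tolist()))


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def load_landmarks(path) -> RadiographLandmarks:
    path = Path(path)
    if path.suffix.lower() == ".json":
        return RadiographLandmarks.from_json(path)
    # CSV: name,x[,y] per row; wall polylines as repeated rows
    points: dict[str, list] = {}
    scalars: dict[str, float] = {}
    side = "right"
    with open(path) as fh:
        for row in csv.reader(fh):
            if not row:
                continue
            name = row[0].strip()
            if name == "side":
                side = row[1].strip()
            elif len(row) >= 3 and _is_number(row[1]) and _is_number(row[2]):
                points.setdefault(name, []).append([float(row[1]), float(row[2])])
            elif len(row) >= 2 and _is_number(row[1]):
                scalars[name] = float(row[1])
    try:
        return RadiographLandmarks(
            head_center=points["head_center"][0],
            head_radius=scalars["head_radius"],
            lateral_sourcil=points["lateral_sourcil"][0],
            medial_sourcil=points["medial_sourcil"][0],
            teardrop=points["teardrop"][0],
            teardrop_contralateral=points["teardrop_contralateral"][0],
            lateral_rim=points["lateral_rim"][0],
            anterior_wall=points["anterior_wall"],
            posterior_wall=points["posterior_wall"],
            obturator_width_ipsi=scalars["obturator_width_ipsi"],
            obturator_width_contra=scalars["obturator_width_contra"],
            horizontal_ref=points["horizontal_ref"][0],
            side=side,
        )
    except KeyError as exc:
        raise ValueError(f"landmark file {path} is missing {exc}") from exc


def save_coverage_report(report: RegionCoverage, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(report.as_dict(), indent=2))
    else:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["region", "covered_mm2", "total_mm2", "percent"])
            for reg in report.percent:
                w.writerow(
                    [
                        reg,
                        f"{report.covered_mm2[reg]:.6g}",
                        f"{report.total_mm2[reg]:.6g}",
                        f"{report.percent[reg]:.6g}",
                    ]
                )
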