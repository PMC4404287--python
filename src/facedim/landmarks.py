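"""Landmark, mesh and cohort file IO.

Defines the on-disk dialects used throughout the package:

* landmark CSV — header ``landmark,x,y,z``, one Farkas landmark per row,
  coordinates in mm; or an equivalent JSON object keyed by landmark code;
* face meshes — Wavefront OBJ or ascii PLY triangulations;
* cohort CSV — header ``subject_id,sex,group,<distance columns...>``, one
  subject per row, feature columns in mm (facial_area in mm²).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: The closed 21-code Farkas landmark vocabulary. Paired landmarks carry
#: explicit _L/_R suffixes so sides never have to be inferred from geometry.
LANDMARK_CODES: tuple[str, ...] = (
    "Ft_L", "Ft_R",       # frontotemporale
    "Ex_L", "Ex_R",       # exocanthion
    "En_L", "En_R",       # endocanthion
    "N",                  # nasion
    "Prn",                # pronasale
    "Sn",                 # subnasale
    "Ls",                 # labiale superius
    "Sto",                # stomion
    "Li",                 # labiale inferius
    "Al_L", "Al_R",       # alare
    "Ch_L", "Ch_R",       # cheilion
    "Tr",                 # trichion
    "G",                  # glabella
    "Pg",                 # pogonion
    "Sbal_L", "Sbal_R",   # subalare
)

SEX_LABELS = ("male", "female")
GROUP_LABELS = ("low_AQ", "high_AQ")


class LandmarkError(ValueError):
    """Malformed or invalid landmark data."""


class MeshError(ValueError):
    """Malformed or invalid mesh data."""


class CohortError(ValueError):
    """Malformed or invalid cohort table."""


@dataclass
class LandmarkSet:
    """Named 3D facial landmarks for one subject, coordinates in mm."""

    subject_id: str
    points: dict[str, np.ndarray]
    source: str = ""

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for code, xyz in self.points.items():
            if code not in LANDMARK_CODES:
                raise LandmarkError(f"unknown landmark code {code!r}")
            arr = np.asarray(xyz, dtype=float)
            if arr.shape != (3,):
                raise LandmarkError(f"landmark {code!r}: expected 3 coordinates")
            if not np.all(np.isfinite(arr)):
                raise LandmarkError(f"landmark {code!r}: non-finite coordinate")
            clean[code] = arr
        self.points = clean

    def __len__(self) -> int:
        return len(self.points)

    def __contains__(self, code: str) -> bool:
        return code in self.points

    def __getitem__(self, code: str) -> np.ndarray:
        return self.points[code]


@dataclass
class FaceMesh:
    """Triangulated facial surface: vertices in mm, triangle vertex indices."""

    vertices: np.ndarray
    triangles: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=int)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must be an (n, 3) array")
        if self.vertices.shape[0] < 3:
            raise MeshError("mesh needs at least 3 vertices")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise MeshError("triangles must be an (m, 3) index array")
        if self.triangles.shape[0] < 1:
            raise MeshError("mesh needs at least 1 triangle")
        if self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices):
            raise MeshError("triangle index out of range")
        a, b, c = self.triangles.T
        if np.any((a == b) | (b == c) | (a == c)):
            raise MeshError("degenerate triangle with repeated vertex index")


def read_landmarks(path: str | Path, subject_id: str | None = None) -> LandmarkSet:
    """Read one subject's landmarks from CSV (``landmark,x,y,z``) or JSON.

    Unknown landmark codes are rejected; missing codes are permitted —
    downstream distance computation simply omits distances that need them.
    """
    path = Path(path)
    sid = subject_id if subject_id is not None else path.stem
    if path.suffix.lower() == ".json":
        obj = json.loads(path.read_text())
        points = {}
        for code, xyz in obj.items():
            try:
                points[code] = [float(v) for v in xyz]
            except (TypeError, ValueError) as exc:
                raise LandmarkError(f"{path}: landmark {code!r}: non-numeric coordinate") from exc
        return LandmarkSet(sid, points, source=str(path))

    points = {}
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip().lower() for h in header] != ["landmark", "x", "y", "z"]:
            raise LandmarkError(f"{path}: expected header 'landmark,x,y,z'")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            if len(row) != 4:
                raise LandmarkError(f"{path}:{lineno}: expected 4 fields, got {len(row)}")
            code = row[0].strip()
            try:
                xyz = [float(v) for v in row[1:]]
            except ValueError as exc:
                raise LandmarkError(f"{path}:{lineno}: non-numeric coordinate") from exc
            if code in points:
                raise LandmarkError(f"{path}:{lineno}: duplicate landmark {code!r}")
            points[code] = xyz
    return LandmarkSet(sid, points, source=str(path))


def write_landmarks(lm: LandmarkSet, path: str | Path) -> None:
    """Write a landmark set as CSV in vocabulary order."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["landmark", "x", "y", "z"])
        for code in LANDMARK_CODES:
            if code in lm.points:
                writer.writerow([code, *(repr(float(v)) for v in lm.points[code])])


def read_mesh(path: str | Path) -> FaceMesh:
    """Read a triangle mesh from Wavefront OBJ or ascii PLY.

    OBJ quad faces are triangulated by fan split. (trimesh-style loaders are
    deliberately not required: only the two plain-text dialects are needed.)
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".ply" or text.startswith("ply"):
        return _read_ply(text, path)
    return _read_obj(text, path)


def _read_obj(text: str, path: Path) -> FaceMesh:
    vertices: list[list[float]] = []
    triangles: list[list[int]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        parts = line.split()
        if not parts or parts[0].startswith("#"):
            continue
        if parts[0] == "v":
            if len(parts) < 4:
                raise MeshError(f"{path}:{lineno}: vertex needs 3 coordinates")
            vertices.append([float(v) for v in parts[1:4]])
        elif parts[0] == "f":
            # OBJ indices are 1-based; tokens may be v/vt/vn
            idx = [int(tok.split("/")[0]) - 1 for tok in parts[1:]]
            if len(idx) < 3:
                raise MeshError(f"{path}:{lineno}: face needs >= 3 vertices")
            for k in range(1, len(idx) - 1):  # fan triangulation
                triangles.append([idx[0], idx[k], idx[k + 1]])
    if not vertices or not triangles:
        raise MeshError(f"{path}: empty mesh")
    return FaceMesh(np.array(vertices), np.array(triangles))


def _read_ply(text: str, path: Path) -> FaceMesh:
    lines = iter(text.splitlines())
    if next(lines, "").strip() != "ply":
        raise MeshError(f"{path}: not a PLY file")
    n_vert = n_face = 0
    for line in lines:
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "format" and parts[1] != "ascii":
            raise MeshError(f"{path}: only ascii PLY is supported")
        if parts[0] == "element":
            if parts[1] == "vertex":
                n_vert = int(parts[2])
            elif parts[1] == "face":
                n_face = int(parts[2])
        if parts[0] == "end_header":
            break
    vertices = []
    for _ in range(n_vert):
        vertices.append([float(v) for v in next(lines).split()[:3]])
    triangles = []
    for _ in range(n_face):
        parts = [int(v) for v in next(lines).split()]
        count, idx = parts[0], parts[1:]
        for k in range(1, count - 1):
            triangles.append([idx[0], idx[k], idx[k + 1]])
    if not vertices or not triangles:
        raise MeshError(f"{path}: empty mesh")
    return FaceMesh(np.array(vertices), np.array(triangles))


def write_mesh(mesh: FaceMesh, path: str | Path) -> None:
    """Write a mesh as ascii PLY (``.ply``) or Wavefront OBJ (anything else)."""
    path = Path(path)
    if path.suffix.lower() == ".ply":
        with path.open("w") as fh:
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"element vertex {len(mesh.vertices)}\n")
            fh.write("property float x\nproperty float y\nproperty float z\n")
            fh.write(f"element face {len(mesh.triangles)}\n")
            fh.write("property list uchar int vertex_indices\nend_header\n")
            for v in mesh.vertices:
                fh.write(f"{float(v[0])!r} {float(v[1])!r} {float(v[2])!r}\n")
            for t in mesh.triangles:
                fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
    else:
        with path.open("w") as fh:
            for v in mesh.vertices:
                fh.write(f"v {float(v[0])!r} {float(v[1])!r} {float(v[2])!r}\n")
            for t in mesh.triangles:
                fh.write(f"f {t[0] + 1} {t[1] + 1} {t[2] + 1}\n")


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

_META_COLUMNS = ("subject_id", "sex", "group")


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Numeric feature columns of a cohort table (everything non-meta)."""
    return [c for c in table.columns if c not in _META_COLUMNS]


def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort table in place and return it.

    Requires subject_id and sex columns, closed-vocabulary labels, and
    strictly positive feature values. The group column is optional
    (study-1-style cohorts have none).
    """
    if len(table) == 0:
        raise CohortError("cohort table has no subjects")
    if "subject_id" not in table.columns or "sex" not in table.columns:
        raise CohortError("cohort table needs subject_id and sex columns")
    bad_sex = set(table["sex"].unique()) - set(SEX_LABELS)
    if bad_sex:
        raise CohortError(f"unknown sex label(s): {sorted(bad_sex)}")
    if "group" in table.columns:
        bad = set(table["group"].dropna().unique()) - set(GROUP_LABELS)
        if bad:
            raise CohortError(f"unknown group label(s): {sorted(bad)}")
    feats = feature_columns(table)
    if feats:
        values = table[feats].to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise CohortError("non-finite feature value in cohort table")
        if np.any(values <= 0):
            raise CohortError("feature values must be strictly positive")
    return table


def write_cohort(table: pd.DataFrame, path: str | Path) -> None:
    """Write a validated cohort table as CSV (full float precision)."""
    validate_cohort(table)
    table.to_csv(path, index=False, float_format="%.10g")


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV."""
    table = pd.read_csv(path)
    return validate_cohort(table)
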