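"""Inter-landmark distances and mesh surface area.

The 23 Farkas linear distances are straight-line 3D Euclidean distances
between pairs of the 21-landmark vocabulary (not geodesics along the skin
surface). Alar length is the mean of the left and right subalare–pronasale
distances so the measure is side-agnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .landmarks import FaceMesh, LandmarkSet

#: distance name -> tuple of endpoint pairs whose distances are averaged.
#: All but alar_length use a single pair.
DISTANCE_DEFINITIONS: dict[str, tuple[tuple[str, str], ...]] = {
    "forehead_width": (("Ft_L", "Ft_R"),),
    "outer_canthal_width": (("Ex_L", "Ex_R"),),
    "nasal_bridge_length": (("N", "Prn"),),
    "nasal_tip_protrusion": (("Sn", "Prn"),),
    "philtrum_length": (("Sn", "Ls"),),
    "nose_width": (("Al_L", "Al_R"),),
    "eye_fissure_length_left": (("Ex_L", "En_L"),),
    "eye_fissure_length_right": (("Ex_R", "En_R"),),
    "intercanthal_width": (("En_L", "En_R"),),
    "mouth_width": (("Ch_L", "Ch_R"),),
    "upper_facial_height": (("N", "Sto"),),
    "nose_height": (("N", "Sn"),),
    "nasal_root_height_left": (("En_L", "N"),),
    "nasal_root_height_right": (("En_R", "N"),),
    "upper_lip_height": (("Sn", "Sto"),),
    "upper_vermillion_height": (("Ls", "Sto"),),
    "lower_vermillion_height": (("Sto", "Li"),),
    "forehead_height": (("Tr", "G"),),
    "mandible_height": (("Sto", "Pg"),),
    "alar_base_width": (("Sbal_L", "Sbal_R"),),
    "alar_length": (("Sbal_L", "Prn"), ("Sbal_R", "Prn")),
    "upper_profile_height": (("Tr", "Prn"),),
    "lower_profile_height": (("Prn", "Pg"),),
}

DISTANCE_NAMES: tuple[str, ...] = tuple(DISTANCE_DEFINITIONS)

#: The six sexually dimorphic distances selected in study 1.
SELECTED_FEATURES: tuple[str, ...] = (
    "forehead_width",
    "outer_canthal_width",
    "nasal_bridge_length",
    "nasal_tip_protrusion",
    "philtrum_length",
    "nose_width",
)


@dataclass
class DistanceVector:
    """Named Farkas distances (mm) measured on one subject."""

    subject_id: str
    values: dict[str, float]


def euclidean_distance(p, q) -> float:
    """Straight-line distance between two 3D points in mm."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(q))):
        raise ValueError("non-finite coordinate")
    return float(np.linalg.norm(p - q))


def required_landmarks(feature: str) -> set[str]:
    """Landmark codes a named distance depends on."""
    return {code for pair in DISTANCE_DEFINITIONS[feature] for code in pair}


def compute_distances(lm: LandmarkSet) -> DistanceVector:
    """Measure every computable Farkas distance on a landmark set.

    Distances whose endpoint landmarks are missing are omitted with a
    warning rather than imputed; an entirely empty landmark set is an error.
    """
    if len(lm) == 0:
        raise ValueError(f"subject {lm.subject_id}: empty landmark set")
    values: dict[str, float] = {}
    missing: list[str] = []
    for name, pairs in DISTANCE_DEFINITIONS.items():
        if all(a in lm and b in lm for a, b in pairs):
            values[name] = float(
                np.mean([euclidean_distance(lm[a], lm[b]) for a, b in pairs])
            )
        else:
            missing.append(name)
    if missing:
        warnings.warn(
            f"subject {lm.subject_id}: missing landmarks, omitted {missing}",
            stacklevel=2,
        )
    if not values:
        raise ValueError(f"subject {lm.subject_id}: no computable distances")
    return DistanceVector(lm.subject_id, values)


def mesh_surface_area(mesh: FaceMesh) -> float:
    """Total surface area in mm²: half the cross-product magnitude per triangle.

    Zero-area (sliver) triangles contribute nothing and trigger a warning —
    real scan meshes contain them and should not hard-fail.
    """
    v = mesh.vertices
    tri = mesh.triangles
    cross = np.cross(v[tri[:, 1]] - v[tri[:, 0]], v[tri[:, 2]] - v[tri[:, 0]])
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    if np.any(areas == 0.0):
        warnings.warn(
            f"{int(np.sum(areas == 0.0))} degenerate zero-area triangle(s)",
            stacklevel=2,
        )
    return float(areas.sum())
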