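"""Synthetic cohort generation.

The study whose statistics this package reproduces did not deposit its raw
3D face images, so every analysis stage is exercised on synthetic cohorts
instead. Groups are multivariate normal in feature space with the printed
per-feature means/SDs and an exchangeable (single-ρ) inter-feature
correlation; landmark-level cohorts are produced by deforming a fabricated
bilaterally symmetric 21-point template face until its induced distances
match each subject's sampled distance vector.

A green test on these cohorts establishes that the statistical machinery
recovers the structure it was pointed at — not that real faces behave this
way (real inter-feature covariance is unknown; the normality is an
assumption consistent with t-tests and LDA).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .geometry import DISTANCE_DEFINITIONS, SELECTED_FEATURES, compute_distances
from .landmarks import FaceMesh, LandmarkSet, validate_cohort

__all__ = [
    "GroupSpec",
    "SyntheticCohortSpec",
    "TEMPLATE_FACE",
    "builtin_specs",
    "generate_distance_cohort",
    "generate_landmarks_for_targets",
    "generate_landmark_cohort",
    "generate_icosphere",
    "InfeasibleDistanceError",
]


class InfeasibleDistanceError(ValueError):
    """Target distances violate the geometry of the template face."""

    def __init__(self, subject_id: str, offending: list[str]):
        self.subject_id = subject_id
        self.offending = offending
        super().__init__(
            f"subject {subject_id}: infeasible target distances {offending}"
        )


@dataclass
class GroupSpec:
    """One simulated group: label, size and per-feature normal parameters.

    ``correlation`` is the common pairwise correlation ρ shared by every
    feature pair (exchangeable structure); the implied covariance is
    sd_i·sd_j·(ρ + (1−ρ)·[i==j]), checked positive definite on construction.
    """

    sex: str
    n: int
    means: dict[str, float]
    sds: dict[str, float]
    group: str | None = None
    correlation: float = 0.3

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be >= 2")
        if not 0.0 <= self.correlation <= 0.9:
            raise ValueError("correlation must lie in [0, 0.9]")
        if set(self.means) != set(self.sds):
            raise ValueError("means and sds must cover the same features")
        if any(sd <= 0 for sd in self.sds.values()):
            raise ValueError("sds must be strictly positive")
        np.linalg.cholesky(self.covariance())  # raises if not PD

    @property
    def label(self) -> str:
        return self.sex if self.group is None else f"{self.sex}-{self.group}"

    @property
    def features(self) -> list[str]:
        return list(self.means)

    def covariance(self) -> np.ndarray:
        sd = np.array([self.sds[f] for f in self.features])
        rho = self.correlation
        corr = np.full((len(sd), len(sd)), rho) + (1.0 - rho) * np.eye(len(sd))
        return np.outer(sd, sd) * corr


@dataclass
class SyntheticCohortSpec:
    """A named collection of groups plus the default seed."""

    name: str
    groups: list[GroupSpec]
    seed: int = 0
    suspect_features: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        labels = [g.label for g in self.groups]
        if len(labels) != len(set(labels)):
            raise ValueError("group labels must be unique")


# --- printed group parameters -------------------------------------------------

_STUDY1_MALE = {
    "forehead_width": (124.12, 5.27),
    "outer_canthal_width": (96.57, 4.54),
    "nasal_bridge_length": (47.34, 3.77),
    "nasal_tip_protrusion": (19.67, 1.95),
    "philtrum_length": (8.17, 2.44),
    "nose_width": (32.71, 2.58),
}
_STUDY1_FEMALE = {
    "forehead_width": (113.41, 5.53),
    "outer_canthal_width": (94.29, 4.20),
    "nasal_bridge_length": (42.12, 3.62),
    "nasal_tip_protrusion": (17.18, 1.94),
    "philtrum_length": (7.25, 1.94),
    "nose_width": (29.08, 2.35),
}

#: Fabricated non-dimorphic filler parameters for the 17 non-selected
#: distances (synthetic, NOT study values): identical in both sexes, so
#: they carry no class signal and only widen the feature-selection search
#: space to the full 23 distances. Means sit at anthropometrically
#: plausible magnitudes; SDs at ~5% of the mean.
FILLER_FEATURES: dict[str, tuple[float, float]] = {
    "eye_fissure_length_left": (31.0, 1.6),
    "eye_fissure_length_right": (31.0, 1.6),
    "intercanthal_width": (32.5, 2.2),
    "mouth_width": (50.0, 3.2),
    "upper_facial_height": (75.0, 4.0),
    "nose_height": (52.0, 3.3),
    "nasal_root_height_left": (18.0, 1.7),
    "nasal_root_height_right": (18.0, 1.7),
    "upper_lip_height": (22.0, 2.0),
    "upper_vermillion_height": (8.5, 1.3),
    "lower_vermillion_height": (10.5, 1.4),
    "forehead_height": (60.0, 5.5),
    "mandible_height": (47.0, 3.6),
    "alar_base_width": (35.0, 2.4),
    "alar_length": (22.0, 1.8),
    "upper_profile_height": (112.0, 6.0),
    "lower_profile_height": (65.0, 4.0),
}

_STUDY2_MALE_LOW = {
    "forehead_width": (126.01, 5.74),
    "outer_canthal_width": (98.38, 4.38),
    "nasal_bridge_length": (49.37, 4.38),
    "nasal_tip_protrusion": (21.62, 1.94),
    "philtrum_length": (22.99, 2.17),
    "nose_width": (32.81, 3.10),
    "facial_area": (24600.0, 1670.0),
}
_STUDY2_MALE_HIGH = {
    "forehead_width": (121.11, 5.69),
    "outer_canthal_width": (94.26, 4.47),
    "nasal_bridge_length": (46.17, 3.69),
    "nasal_tip_protrusion": (18.65, 2.29),
    "philtrum_length": (23.67, 3.05),
    "nose_width": (32.46, 2.42),
    "facial_area": (24500.0, 1870.0),
}
_STUDY2_FEMALE_LOW = {
    "forehead_width": (110.63, 5.11),
    "outer_canthal_width": (90.95, 3.61),
    "nasal_bridge_length": (43.83, 3.00),
    "nasal_tip_protrusion": (19.52, 2.10),
    "philtrum_length": (21.25, 2.49),
    "nose_width": (28.58, 2.10),
    "facial_area": (22800.0, 1620.0),
}
_STUDY2_FEMALE_HIGH = {
    "forehead_width": (116.53, 4.73),
    "outer_canthal_width": (96.59, 4.44),
    "nasal_bridge_length": (40.40, 3.64),
    "nasal_tip_protrusion": (19.90, 2.31),
    "philtrum_length": (21.62, 2.58),
    "nose_width": (30.38, 2.01),
    "facial_area": (23100.0, 1650.0),
}


def _split(params: dict[str, tuple[float, float]]):
    means = {k: v[0] for k, v in params.items()}
    sds = {k: v[1] for k, v in params.items()}
    return means, sds


def builtin_specs(rho: float = 0.3) -> dict[str, SyntheticCohortSpec]:
    """The built-in cohort presets.

    ``study1``: 107 males / 101 females, the six dimorphic distances at
    their printed means/SDs plus 17 fabricated non-dimorphic filler
    distances. ``study2-male`` / ``study2-female``: low-/high-AQ groups
    (n = 33/25 and 33/21) at the printed distance and facial-area
    parameters.

    The study-2 philtrum-length parameters (≈21–24 mm) are irreconcilable
    with the study-1 philtrum values (≈7–8 mm); they are stored verbatim
    but flagged suspect and excluded from landmark-closure checks.
    """
    s1m, s1m_sd = _split({**_STUDY1_MALE, **FILLER_FEATURES})
    s1f, s1f_sd = _split({**_STUDY1_FEMALE, **FILLER_FEATURES})
    specs = {
        "study1": SyntheticCohortSpec(
            "study1",
            [
                GroupSpec("male", 107, s1m, s1m_sd, correlation=rho),
                GroupSpec("female", 101, s1f, s1f_sd, correlation=rho),
            ],
        ),
        "study2-male": SyntheticCohortSpec(
            "study2-male",
            [
                GroupSpec("male", 33, *_split(_STUDY2_MALE_LOW), group="low_AQ", correlation=rho),
                GroupSpec("male", 25, *_split(_STUDY2_MALE_HIGH), group="high_AQ", correlation=rho),
            ],
            suspect_features=("philtrum_length",),
        ),
        "study2-female": SyntheticCohortSpec(
            "study2-female",
            [
                GroupSpec("female", 33, *_split(_STUDY2_FEMALE_LOW), group="low_AQ", correlation=rho),
                GroupSpec("female", 21, *_split(_STUDY2_FEMALE_HIGH), group="high_AQ", correlation=rho),
            ],
            suspect_features=("philtrum_length",),
        ),
    }
    return specs


def generate_distance_cohort(
    spec: SyntheticCohortSpec,
    seed: int | None = None,
    n_scale: float = 1.0,
) -> pd.DataFrame:
    """Draw a cohort table from a spec's group distributions.

    Each group's rows are multivariate normal with the spec covariance;
    rows containing a non-positive value (deep-tail draws) are redrawn so
    the cohort-table positivity invariant holds. ``n_scale`` multiplies
    every group size (rounded), for large-n convergence checks.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    frames = []
    for g in spec.groups:
        n = max(2, int(round(g.n * n_scale)))
        mean = np.array([g.means[f] for f in g.features])
        chol = np.linalg.cholesky(g.covariance())
        x = mean + rng.standard_normal((n, len(mean))) @ chol.T
        bad = np.any(x <= 0, axis=1)
        while np.any(bad):
            x[bad] = mean + rng.standard_normal((int(bad.sum()), len(mean))) @ chol.T
            bad = np.any(x <= 0, axis=1)
        frame = pd.DataFrame(x, columns=g.features)
        frame.insert(0, "subject_id", [f"{spec.name}-{g.label}-{i:05d}" for i in range(n)])
        frame.insert(1, "sex", g.sex)
        if g.group is not None:
            frame.insert(2, "group", g.group)
        frames.append(frame)
    table = pd.concat(frames, ignore_index=True)
    return validate_cohort(table)


# --- template face ------------------------------------------------------------

#: Fabricated bilaterally symmetric template landmarks (mm). The coordinate
#: frame is x lateral, y vertical (up), z anterior; only the distances the
#: template induces matter, and those sit near the printed cohort means.
TEMPLATE_FACE: dict[str, tuple[float, float, float]] = {
    "Tr": (0.0, 75.0, 90.0),
    "G": (0.0, 52.0, 102.0),
    "N": (0.0, 45.0, 98.0),
    "Prn": (0.0, 8.0, 118.0),
    "Sn": (0.0, 0.0, 100.0),
    "Ls": (0.0, -7.5, 101.0),
    "Sto": (0.0, -15.0, 98.0),
    "Li": (0.0, -24.0, 96.0),
    "Pg": (0.0, -50.0, 95.0),
    "Ft_L": (-59.4, 55.0, 70.0),
    "Ft_R": (59.4, 55.0, 70.0),
    "Ex_L": (-47.7, 42.0, 75.0),
    "Ex_R": (47.7, 42.0, 75.0),
    "En_L": (-16.2, 42.0, 88.0),
    "En_R": (16.2, 42.0, 88.0),
    "Al_L": (-15.4, 2.0, 100.0),
    "Al_R": (15.4, 2.0, 100.0),
    "Ch_L": (-25.0, -15.0, 92.0),
    "Ch_R": (25.0, -15.0, 92.0),
    "Sbal_L": (-17.5, -1.0, 99.0),
    "Sbal_R": (17.5, -1.0, 99.0),
}


def template_landmarks(subject_id: str = "template") -> LandmarkSet:
    """The template face as a LandmarkSet."""
    return LandmarkSet(subject_id, {k: np.array(v) for k, v in TEMPLATE_FACE.items()})


def generate_landmarks_for_targets(
    targets: dict[str, float],
    subject_id: str = "synthetic",
    tol: float = 0.05,
    strict: list[str] | None = None,
) -> LandmarkSet:
    """Deform the template so its induced distances hit ``targets``.

    All 63 landmark coordinates are free variables of a least-squares
    problem whose residuals are (induced − target) per named distance;
    the solver starts at the template, so the returned face is the nearby
    solution and a target set equal to the template's own distances is a
    fixed point.

    ``strict`` names the targets that must close to within ``tol`` mm
    (all of them when None); strict residuals carry a 1000× weight so
    soft targets — which may be mutually inconsistent when a full sampled
    distance vector is supplied — absorb the slack. Strict targets still
    off after convergence are geometrically infeasible (triangle-inequality
    violations) and raise :class:`InfeasibleDistanceError`.
    """
    unknown = set(targets) - set(DISTANCE_DEFINITIONS)
    if unknown:
        raise ValueError(f"unknown distance name(s): {sorted(unknown)}")
    strict_set = set(targets) if strict is None else set(strict) & set(targets)
    codes = list(TEMPLATE_FACE)
    index = {c: i for i, c in enumerate(codes)}
    x0 = np.array([TEMPLATE_FACE[c] for c in codes], dtype=float).ravel()
    names = sorted(targets)
    weights = np.array([1000.0 if n in strict_set else 1.0 for n in names])

    def misfit(x: np.ndarray) -> np.ndarray:
        pts = x.reshape(-1, 3)
        out = np.empty(len(names))
        for k, name in enumerate(names):
            pairs = DISTANCE_DEFINITIONS[name]
            d = np.mean(
                [np.linalg.norm(pts[index[a]] - pts[index[b]]) for a, b in pairs]
            )
            out[k] = d - targets[name]
        return out

    sol = least_squares(
        lambda x: weights * misfit(x), x0, xtol=1e-12, ftol=1e-12, gtol=1e-12
    )
    resid = np.abs(misfit(sol.x))
    offending = [
        names[k] for k in np.flatnonzero(resid > tol) if names[k] in strict_set
    ]
    if offending:
        raise InfeasibleDistanceError(subject_id, offending)
    pts = sol.x.reshape(-1, 3)
    return LandmarkSet(subject_id, {c: pts[index[c]] for c in codes})


def generate_landmark_cohort(
    spec: SyntheticCohortSpec,
    seed: int | None = None,
    n_scale: float = 1.0,
    tol: float = 0.05,
    targets: str = "selected",
) -> tuple[list[LandmarkSet], pd.DataFrame]:
    """Sample a distance cohort, then realise each subject as landmarks.

    Returns the landmark sets together with the sampled distance table
    (the generation targets). With ``targets="selected"`` (default) only
    the six dimorphic distances constrain the geometry — they form a
    cycle-free endpoint graph and are therefore always jointly realisable.
    ``targets="all"`` additionally feeds every other sampled Farkas
    distance as a soft target; a full independently-sampled distance
    vector is in general mutually inconsistent (e.g. outer canthal vs
    intercanthal width plus the eye fissures), so soft targets are met
    only in the least-squares sense. Features that are not Farkas
    distances (facial_area) or are flagged suspect in the spec are never
    used as targets. ``compute_distances`` on each returned face
    reproduces the strict targets to within ``tol`` mm.
    """
    if targets not in ("selected", "all"):
        raise ValueError("targets must be 'selected' or 'all'")
    table = generate_distance_cohort(spec, seed=seed, n_scale=n_scale)
    usable = [
        c
        for c in table.columns
        if c in DISTANCE_DEFINITIONS and c not in spec.suspect_features
    ]
    strict = [c for c in usable if c in SELECTED_FEATURES] or usable
    if targets == "selected":
        usable = strict
    faces = []
    for _, row in table.iterrows():
        subject_targets = {c: float(row[c]) for c in usable}
        faces.append(
            generate_landmarks_for_targets(
                subject_targets, subject_id=row["subject_id"], tol=tol, strict=strict
            )
        )
    return faces, table


# --- icosphere (area oracle for mesh_surface_area) ---------------------------


def generate_icosphere(radius: float, subdivisions: int) -> FaceMesh:
    """Icosahedron-based sphere triangulation with vertices on the sphere.

    Inscribed, so the surface area converges to 4πr² from below as the
    subdivision level grows.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if not 0 <= subdivisions <= 6:
        raise ValueError("subdivisions must be in 0..6")
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            (-1, phi, 0), (1, phi, 0), (-1, -phi, 0), (1, -phi, 0),
            (0, -1, phi), (0, 1, phi), (0, -1, -phi), (0, 1, -phi),
            (phi, 0, -1), (phi, 0, 1), (-phi, 0, -1), (-phi, 0, 1),
        ],
        dtype=float,
    )
    faces = [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ]
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    verts = list(verts)
    for _ in range(subdivisions):
        cache: dict[tuple[int, int], int] = {}

        def midpoint(i: int, j: int) -> int:
            key = (min(i, j), max(i, j))
            if key not in cache:
                m = verts[i] + verts[j]
                verts.append(m / np.linalg.norm(m))
                cache[key] = len(verts) - 1
            return cache[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        faces = new_faces
    return FaceMesh(radius * np.asarray(verts), np.array(faces))
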