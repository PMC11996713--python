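"""Synthetic cohorts of brain-like closed surfaces with known ground truth.

Real inputs to this kind of analysis are MRI-segmented cortical surfaces;
none are distributed here, so every pipeline stage is exercised on
generated cohorts instead: smooth closed base shapes (icosphere-derived
spheres and ellipsoids, optionally perturbed by a fixed low-order harmonic)
shared across specimens, differing by

* a per-specimen similarity transform (rotation, translation, uniform
  scale) — the nuisance the alignment must remove,
* localized "bump" deformations of known center, angular radius and
  magnitude — the regional shape variation the variance map must find,
* isotropic per-vertex Gaussian jitter — measurement noise, and
* optionally distinct vertex counts per specimen (random removal of a few
  percent of vertices, surface re-triangulated) — so nothing in the
  pipeline can silently assume fixed correspondence.

All randomness flows from one seeded generator in a fixed, documented
order (per specimen: rotation, translation, scale, vertex removal, bump
amplitudes, jitter), so identical specs and seeds give bitwise-identical
cohorts and adding specimens never shifts earlier draws.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import trimesh
from scipy.spatial import ConvexHull

from .mesh_io import TriangleMesh, write_ply
from .registration import SimilarityTransform

__all__ = [
    "Bump",
    "CohortSpec",
    "CohortGroundTruth",
    "generate_cohort",
    "write_manifest",
    "read_manifest",
    "filter_manifest",
    "assign_labels",
]


@dataclass
class Bump:
    """A localized radial deformation with Gaussian angular falloff.

    Vertices at angular distance θ from ``center`` (a direction on the
    base shape) are displaced along their outward normal by
    ``a · exp(−(θ/radius)²)`` where ``a`` is the realized amplitude.
    ``amplitude`` is either a scalar (every selected specimen gets exactly
    this displacement) or a distribution tuple ``("normal", mean, sd)`` /
    ``("uniform", lo, hi)`` drawn per specimen — only amplitude *variation*
    across specimens produces variance at the bump.  ``group_selector``
    restricts the bump to specimens whose labels match every listed
    key/value (None → all specimens).
    """

    center: tuple
    angular_radius_deg: float
    amplitude: object
    group_selector: dict | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.center, float)
        n = np.linalg.norm(c)
        if n == 0 or not np.all(np.isfinite(c)):
            raise ValueError("bump center must be a finite nonzero direction")
        self.center = tuple(c / n)
        if not 0.0 < self.angular_radius_deg < 90.0:
            raise ValueError("angular_radius_deg must be in (0, 90)")

    def realize_amplitude(self, rng: np.random.Generator) -> float:
        a = self.amplitude
        if isinstance(a, (int, float)):
            return float(a)
        kind = a[0]
        if kind == "normal":
            return float(rng.normal(a[1], a[2]))
        if kind == "uniform":
            return float(rng.uniform(a[1], a[2]))
        raise ValueError(f"unknown amplitude distribution {a!r}")

    def applies_to(self, labels: dict) -> bool:
        if not self.group_selector:
            return True
        return all(labels.get(k) == v for k, v in self.group_selector.items())


@dataclass
class CohortSpec:
    """Generative description of a synthetic cohort.

    Dimensionless quantities are fractions of the base-shape bounding-box
    diagonal: ``max_translation`` and ``noise_sigma``.  Defaults emulate a
    longitudinal scan cohort: modest pose differences (rotations up to
    20°, translations up to 10% of size, ±10% scale) and sub-percent
    surface noise.
    """

    n_specimens: int
    seed: int
    base_shape: str = "ellipsoid"
    radii: tuple = (1.2, 1.0, 0.8)
    harmonic_amplitude: float = 0.08
    subdivision_level: int = 3
    max_rotation_deg: float = 20.0
    max_translation: float = 0.1
    scale_range: tuple = (0.9, 1.1)
    noise_sigma: float = 0.005
    bumps: list = field(default_factory=list)
    vertex_count_jitter: bool = True
    removal_fraction: tuple = (0.01, 0.05)
    labels: list | None = None

    def __post_init__(self) -> None:
        problems = []
        if self.n_specimens < 1:
            problems.append("n_specimens must be >= 1")
        if self.seed is None:
            problems.append("seed is mandatory")
        if self.base_shape not in ("sphere", "ellipsoid", "perturbed_ellipsoid"):
            problems.append(f"unknown base_shape {self.base_shape!r}")
        if not all(r > 0 for r in self.radii):
            problems.append("radii must be positive")
        if self.noise_sigma < 0:
            problems.append("noise_sigma must be >= 0")
        if not 0 < self.scale_range[0] <= self.scale_range[1]:
            problems.append("scale_range must be positive and ordered")
        if self.labels is not None and len(self.labels) != self.n_specimens:
            problems.append("labels must have one entry per specimen")
        for b in self.bumps:
            if not isinstance(b, Bump):
                problems.append("bumps must be Bump instances")
        if problems:
            raise ValueError("invalid cohort spec: " + "; ".join(problems))


@dataclass
class CohortGroundTruth:
    """What the generator actually did, for parameter-recovery tests."""

    transforms: list  # SimilarityTransform per specimen
    bump_supports: list  # per specimen: list of vertex-index arrays, one per applied bump
    bump_amplitudes: list  # per specimen: list of realized amplitudes
    bump_centers: list  # per specimen: list of unit centers (base-shape frame)
    labels: list  # per specimen dict
    base_diameter: float


def _base_directions(level: int) -> tuple[np.ndarray, np.ndarray]:
    ico = trimesh.creation.icosphere(subdivisions=level, radius=1.0)
    return np.asarray(ico.vertices, float), np.asarray(ico.faces, np.int64)


def _shape_points(spec: CohortSpec, u: np.ndarray) -> np.ndarray:
    radii = np.asarray(spec.radii, float)
    if spec.base_shape == "sphere":
        radii = np.full(3, radii[0])
    pts = u * radii
    if spec.base_shape == "perturbed_ellipsoid":
        # fixed low-order harmonic modulation of the radius; the mixed terms
        # break every 180° flip symmetry so pose recovery is unambiguous
        h = (
            2.0 * u[:, 0] * u[:, 1]
            + 0.7 * u[:, 1] * u[:, 2]
            + (u[:, 2] ** 2 - 1.0 / 3.0)
        )
        pts = pts * (1.0 + spec.harmonic_amplitude * h)[:, None]
    return pts


def _hull_faces(u: np.ndarray) -> np.ndarray:
    """Outward-oriented triangulation of unit directions via their convex hull."""
    hull = ConvexHull(u)
    faces = hull.simplices.astype(np.int64)
    centers = u[faces].mean(axis=1)
    normals = np.cross(u[faces[:, 1]] - u[faces[:, 0]], u[faces[:, 2]] - u[faces[:, 0]])
    flip = np.einsum("ij,ij->i", normals, centers) < 0
    faces[flip] = faces[flip][:, [0, 2, 1]]
    return faces


def _random_rotation(rng: np.random.Generator, max_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(0.0, max_deg))
    K = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def generate_cohort(spec: CohortSpec) -> tuple[list, CohortGroundTruth]:
    """Generate the cohort described by ``spec``.

    Returns the list of meshes and the ground truth (applied transforms,
    per-bump affected vertex sets, realized amplitudes).  Bump support sets
    list the vertices within 1.5 × the bump's angular radius on that
    specimen's mesh.
    """
    rng = np.random.default_rng(spec.seed)
    u0, faces0 = _base_directions(spec.subdivision_level)
    base_pts = _shape_points(spec, u0)
    base = TriangleMesh(base_pts, faces0, "base")
    diam = base.diameter()
    sigma_abs = spec.noise_sigma * diam
    labels = spec.labels if spec.labels is not None else [{} for _ in range(spec.n_specimens)]

    meshes: list = []
    truth = CohortGroundTruth(
        transforms=[],
        bump_supports=[],
        bump_amplitudes=[],
        bump_centers=[],
        labels=[dict(l) for l in labels],
        base_diameter=diam,
    )
    for i in range(spec.n_specimens):
        # draw order per specimen is fixed: rotation, translation, scale,
        # vertex removal, bump amplitudes, jitter
        R = _random_rotation(rng, spec.max_rotation_deg)
        t = rng.uniform(-1.0, 1.0, size=3) * spec.max_translation * diam
        s = float(rng.uniform(*spec.scale_range))
        if spec.vertex_count_jitter:
            frac = float(rng.uniform(*spec.removal_fraction))
            k = int(round(frac * len(u0)))
            drop = rng.choice(len(u0), size=k, replace=False)
            keep = np.setdiff1d(np.arange(len(u0)), drop)
            u = u0[keep]
            faces = _hull_faces(u)
        else:
            u = u0
            faces = faces0
        pts = _shape_points(spec, u)
        normals = np.asarray(
            trimesh.Trimesh(pts, faces, process=False).vertex_normals, float
        )

        supports, amps, centers = [], [], []
        for bump in spec.bumps:
            if not bump.applies_to(labels[i]):
                continue
            a = bump.realize_amplitude(rng)
            c = np.asarray(bump.center, float)
            theta = np.degrees(np.arccos(np.clip(u @ c, -1.0, 1.0)))
            d = a * np.exp(-((theta / bump.angular_radius_deg) ** 2))
            pts = pts + d[:, None] * normals
            supports.append(np.flatnonzero(theta <= 1.5 * bump.angular_radius_deg))
            amps.append(a)
            centers.append(tuple(c))
        if sigma_abs > 0:
            pts = pts + rng.normal(0.0, sigma_abs, size=pts.shape)
        transform = SimilarityTransform(R, s, t)
        pts = transform.apply(pts)
        meshes.append(TriangleMesh(pts, faces, name=f"spec{i:03d}"))
        truth.transforms.append(transform)
        truth.bump_supports.append(supports)
        truth.bump_amplitudes.append(amps)
        truth.bump_centers.append(centers)
    return meshes, truth


def assign_labels(
    n: int,
    groups: tuple = ("naive", "practice"),
    timepoints: tuple = ("t1", "t2"),
    sexes: tuple = ("F", "M"),
) -> list:
    """Round-robin factorial label assignment (group × timepoint × sex)."""
    combos = [
        {"group": g, "timepoint": t, "sex": s}
        for g in groups
        for t in timepoints
        for s in sexes
    ]
    return [dict(combos[i % len(combos)]) for i in range(n)]


def acronym(labels: dict) -> str:
    """Subset acronym derived from labels, e.g. CTR_t1 or MB_t2_F."""
    grp = {"naive": "CTR", "practice": "MB"}.get(labels.get("group", ""), "ALL")
    parts = [grp]
    if labels.get("timepoint"):
        parts.append(labels["timepoint"])
    if labels.get("sex"):
        parts.append(labels["sex"])
    return "_".join(parts)


def write_manifest(
    spec: CohortSpec, meshes: list, truth: CohortGroundTruth, out_dir
) -> str:
    """Write PLYs, a TSV manifest and the ground truth JSON to ``out_dir``.

    Manifest columns: specimen, file, group, timepoint, sex.  Returns the
    manifest path.
    """
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for mesh, labels in zip(meshes, truth.labels):
        fname = f"{mesh.name}.ply"
        write_ply(mesh, os.path.join(out_dir, fname), dialect="binary")
        rows.append(
            (
                mesh.name,
                fname,
                labels.get("group", ""),
                labels.get("timepoint", ""),
                labels.get("sex", ""),
            )
        )
    manifest_path = os.path.join(out_dir, "manifest.tsv")
    with open(manifest_path, "w") as fh:
        fh.write("specimen\tfile\tgroup\ttimepoint\tsex\n")
        for r in rows:
            fh.write("\t".join(r) + "\n")
    truth_payload = {
        "base_diameter": truth.base_diameter,
        "specimens": [
            {
                "name": meshes[i].name,
                "transform": truth.transforms[i].to_dict(),
                "bump_amplitudes": truth.bump_amplitudes[i],
                "bump_centers": [list(c) for c in truth.bump_centers[i]],
                "bump_supports": [s.tolist() for s in truth.bump_supports[i]],
                "labels": truth.labels[i],
            }
            for i in range(len(meshes))
        ],
        "spec": _spec_json(spec),
    }
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(truth_payload, fh, indent=1)
    return manifest_path


def _spec_json(spec: CohortSpec) -> dict:
    d = asdict(spec)
    d["bumps"] = [
        {
            "center": list(b["center"]),
            "angular_radius_deg": b["angular_radius_deg"],
            "amplitude": b["amplitude"],
            "group_selector": b["group_selector"],
        }
        for b in d["bumps"]
    ]
    return d


def read_manifest(path) -> list:
    """Read a manifest TSV into a list of row dicts (file paths kept relative)."""
    rows = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        for line in fh:
            if not line.strip():
                continue
            vals = line.rstrip("\n").split("\t")
            rows.append(dict(zip(header, vals)))
    return rows


def filter_manifest(rows: list, subset: dict) -> list:
    """Rows matching every key/value of ``subset`` (keys: group/timepoint/sex)."""
    allowed = {"group", "timepoint", "sex"}
    bad = set(subset) - allowed
    if bad:
        raise ValueError(f"unknown subset fields: {sorted(bad)}")
    return [r for r in rows if all(r.get(k) == v for k, v in subset.items())]
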