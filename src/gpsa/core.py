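"""Generalized Procrustes surface alignment of a cohort of meshes.

The procedure extends generalized Procrustes analysis to whole surfaces:
every specimen is superimposed onto a *prototype* surface by symmetric ICP,
nearest-neighbor pairings against the prototype define point homology in
place of manually placed landmarks, the prototype is moved toward the
point-wise average of the paired specimen points (and near-duplicate points
merged), and the loop repeats until the prototype stops moving.  Shape
differences between superimposed surfaces are summarised by the Procrustes
Surface Metric (PSM),

    D(A, B) = sqrt( 1/(2 m_A) Σ_i ‖p_A,i − q_B,i‖²
                  + 1/(2 m_B) Σ_j ‖p_B,j − q_A,j‖² ),

where q is the nearest neighbor of p on the other surface and m the vertex
count — a symmetric RMS-type distance in which each surface contributes
equally regardless of its vertex count.  When the two surfaces have equal
counts and the nearest-neighbor pairing is the identity, D = P/√m with P
the ordinary Procrustes distance sqrt(Σ‖p_i − q_i‖²); PSM is not
guaranteed to satisfy the triangle inequality and is treated as a
dissimilarity, not a metric.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .mesh_io import TriangleMesh
from .registration import (
    CorrespondenceSet,
    ICPParams,
    SimilarityTransform,
    nearest_neighbors,
    symmetric_icp,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GPSAParams",
    "GPSAResult",
    "compute_psm",
    "compute_psm_squared",
    "select_prototype",
    "update_prototype",
    "merge_close_points",
    "run_gpsa",
    "mean_surface_of",
]


@dataclass
class GPSAParams:
    """Controls for the multi-surface alignment loop.

    ``duplicate_merge_radius`` is expressed as a fraction of the
    prototype's mean edge length; prototype points closer than this are
    merged to their centroid after each averaging step.  The outer loop
    stops early once the RMS prototype displacement falls below
    ``icp.convergence_tol`` × the prototype diameter.
    """

    outer_iterations: int = 10
    prototype_update: bool = True
    duplicate_merge_radius: float = 0.25
    icp: ICPParams = field(default_factory=ICPParams)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.outer_iterations < 1:
            raise ValueError("outer_iterations must be >= 1")
        if self.duplicate_merge_radius < 0:
            raise ValueError("duplicate_merge_radius must be >= 0")


@dataclass
class GPSAResult:
    """Superimposed cohort, mean surface, pairings and PSM distances."""

    prototype: TriangleMesh
    prototype_index: int | None
    names: list
    superimposed: list  # (n_i, 3) arrays, one per specimen
    transforms: list  # SimilarityTransform per specimen
    pairings: list  # CorrespondenceSet specimen -> final prototype
    psm_to_mean: np.ndarray
    pairwise_psm: np.ndarray
    outer_iterations_run: int = 0

    @property
    def n_specimens(self) -> int:
        return len(self.superimposed)


# ---------------------------------------------------------------------------
# PSM


def compute_psm_squared(A, B) -> float:
    """Squared Procrustes Surface Metric between two point sets or meshes."""
    a = A.vertices if isinstance(A, TriangleMesh) else np.asarray(A, float)
    b = B.vertices if isinstance(B, TriangleMesh) else np.asarray(B, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("point sets must be non-empty")
    d_ab, _ = cKDTree(b).query(a, k=1)
    d_ba, _ = cKDTree(a).query(b, k=1)
    return float(
        np.sum(d_ab**2) / (2.0 * len(a)) + np.sum(d_ba**2) / (2.0 * len(b))
    )


def compute_psm(A, B) -> float:
    """Procrustes Surface Metric D(A, B); symmetric, ≥ 0, in input units."""
    return float(np.sqrt(compute_psm_squared(A, B)))


# ---------------------------------------------------------------------------
# Prototype selection


def select_prototype(meshes: list, icp_params: ICPParams | None = None) -> int:
    """Index of the medoid specimen: minimal summed PSM to all others.

    Every unordered pair is superimposed by symmetric ICP before its PSM is
    measured, so the choice reflects shape, not pose or size.  This
    operationalises picking the least morphometrically atypical individual
    as the reference.  Ties break toward the lowest index.
    """
    n = len(meshes)
    if n < 1:
        raise ValueError("empty cohort")
    if n == 1:
        warnings.warn("cohort of one: prototype defaults to index 0")
        return 0
    if icp_params is None:
        icp_params = ICPParams()
    total = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            res = symmetric_icp(meshes[i], meshes[j], icp_params)
            d = float(np.sqrt(res.final_cost))
            total[i] += d
            total[j] += d
    return int(np.argmin(total))


# ---------------------------------------------------------------------------
# Prototype update


def update_prototype(
    prototype_points: np.ndarray,
    superimposed: list,
    pairings: list,
) -> np.ndarray:
    """Move each prototype point to the mean of the specimen points paired to it.

    "Paired to it" means specimen vertices whose nearest prototype point is
    this one (inbound pairings, pooled across the cohort).  A prototype
    point that attracted no specimen vertex falls back to the mean of its
    own nearest neighbors on each specimen (outbound pairings), so no point
    is ever left without an update.
    """
    proto = np.asarray(prototype_points, float)
    n = len(proto)
    acc = np.zeros((n, 3))
    cnt = np.zeros(n)
    for pts, corr in zip(superimposed, pairings):
        np.add.at(acc, corr.pairs_ab, pts)
        np.add.at(cnt, corr.pairs_ab, 1.0)
    out = np.empty_like(proto)
    has = cnt > 0
    out[has] = acc[has] / cnt[has, None]
    if not has.all():
        miss = np.flatnonzero(~has)
        fallback = np.zeros((len(miss), 3))
        for pts, corr in zip(superimposed, pairings):
            fallback += pts[corr.pairs_ba[miss]]
        out[miss] = fallback / len(superimposed)
    return out


def merge_close_points(
    points: np.ndarray, faces: np.ndarray, radius: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Merge points closer than ``radius`` to their cluster centroid.

    Clusters are connected components of the within-radius graph, processed
    in ascending index order (deterministic).  Returns (new_points,
    new_faces, index_map old→new); faces made degenerate by merging are
    dropped.
    """
    points = np.asarray(points, float)
    n = len(points)
    if radius <= 0 or n == 0:
        return points, np.asarray(faces), np.arange(n)
    tree = cKDTree(points)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in pairs:
        ri, rj = find(int(i)), find(int(j))
        if ri != rj:
            # lower index wins: cluster labels stay deterministic
            if ri < rj:
                parent[rj] = ri
            else:
                parent[ri] = rj
    roots = np.array([find(i) for i in range(n)])
    uniq, index_map = np.unique(roots, return_inverse=True)
    k = len(uniq)
    if k < n // 2:
        warnings.warn(
            f"duplicate merge collapsed {n - k} of {n} prototype points; "
            "merge radius may be too large"
        )
    new_points = np.zeros((k, 3))
    counts = np.zeros(k)
    np.add.at(new_points, index_map, points)
    np.add.at(counts, index_map, 1.0)
    new_points /= counts[:, None]
    new_faces = np.asarray(faces)
    if new_faces.size:
        new_faces = index_map[new_faces]
        ok = (
            (new_faces[:, 0] != new_faces[:, 1])
            & (new_faces[:, 1] != new_faces[:, 2])
            & (new_faces[:, 0] != new_faces[:, 2])
        )
        new_faces = new_faces[ok]
    return new_points, new_faces, index_map


# ---------------------------------------------------------------------------
# The generalized alignment loop


def run_gpsa(
    meshes: list,
    prototype: TriangleMesh | str = "auto",
    params: GPSAParams | None = None,
) -> GPSAResult:
    """Align a cohort of meshes and estimate the mean surface.

    ``prototype`` may be a mesh (e.g. a previously computed mean surface
    reused as the reference for a later round) or ``"auto"``, which selects
    the medoid specimen.  The run is fully deterministic given inputs and
    parameters.

    Per outer iteration every specimen is superimposed onto the current
    prototype by symmetric ICP; with ``prototype_update`` the prototype
    points are then averaged from the inbound pairings and near-duplicates
    merged.  Iteration stops when the RMS prototype displacement drops
    below ``icp.convergence_tol`` × prototype diameter, or after
    ``outer_iterations``.
    """
    if params is None:
        params = GPSAParams()
    if len(meshes) < 2:
        raise ValueError("need at least 2 meshes")
    for m in meshes:
        m.check()
    names = [m.name or f"specimen_{i}" for i, m in enumerate(meshes)]

    if isinstance(prototype, str):
        if prototype != "auto":
            raise ValueError("prototype must be a TriangleMesh or 'auto'")
        proto_idx: int | None = select_prototype(meshes, params.icp)
        proto_pts = meshes[proto_idx].vertices.copy()
        proto_faces = meshes[proto_idx].faces.copy()
        proto_name = f"prototype[{names[proto_idx]}]"
    else:
        prototype.check()
        proto_idx = None
        proto_pts = prototype.vertices.copy()
        proto_faces = prototype.faces.copy()
        proto_name = prototype.name or "prototype"

    diam = TriangleMesh(proto_pts, proto_faces, "p").diameter()
    superimposed: list = []
    transforms: list = []
    outer_run = 0
    for outer in range(1, params.outer_iterations + 1):
        outer_run = outer
        superimposed = []
        transforms = []
        pairings = []
        proto_mesh = TriangleMesh(proto_pts, proto_faces, proto_name)
        for mesh, name in zip(meshes, names):
            try:
                res = symmetric_icp(mesh, proto_mesh, params.icp)
            except Exception as exc:
                raise type(exc)(f"specimen {name!r}: {exc}") from exc
            superimposed.append(res.transform.apply(mesh.vertices))
            transforms.append(res.transform)
            pairings.append(res.correspondences)
        if not params.prototype_update:
            break
        new_pts = update_prototype(proto_pts, superimposed, pairings)
        rms = float(np.sqrt(np.mean(np.sum((new_pts - proto_pts) ** 2, axis=1))))
        mean_edge = TriangleMesh(new_pts, proto_faces, "p").mean_edge_length()
        new_pts, proto_faces, _ = merge_close_points(
            new_pts, proto_faces, params.duplicate_merge_radius * mean_edge
        )
        merged = len(new_pts) != len(proto_pts)
        proto_pts = new_pts
        logger.debug("outer %d: prototype RMS displacement %.3g", outer, rms)
        if not merged and rms < params.icp.convergence_tol * diam:
            break

    final_proto = TriangleMesh(proto_pts, proto_faces, proto_name)
    pairings = [nearest_neighbors(pts, proto_pts) for pts in superimposed]
    psm_to_mean = np.array(
        [compute_psm(pts, proto_pts) for pts in superimposed]
    )
    n = len(meshes)
    pairwise = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pairwise[i, j] = pairwise[j, i] = compute_psm(
                superimposed[i], superimposed[j]
            )
    return GPSAResult(
        prototype=final_proto,
        prototype_index=proto_idx,
        names=names,
        superimposed=superimposed,
        transforms=transforms,
        pairings=pairings,
        psm_to_mean=psm_to_mean,
        pairwise_psm=pairwise,
        outer_iterations_run=outer_run,
    )


def mean_surface_of(result: GPSAResult) -> TriangleMesh:
    """The final prototype as a mesh — the sample mean surface.

    Connectivity is inherited from the initial prototype mesh restricted to
    the points that survived duplicate merging; the mesh can be written out
    and reused as the prototype of a subsequent alignment round.
    """
    p = result.prototype
    return TriangleMesh(p.vertices.copy(), p.faces.copy(), name="mean_surface")
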