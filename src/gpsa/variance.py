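"""Per-point variance fields over the mean surface, and their heatmaps.

After alignment, each prototype point has one paired point per specimen
(its nearest neighbor on that specimen's superimposed surface).  The 3×3
sample covariance of that paired set measures how much the cohort varies
locally; its trace (total variance, rotation-invariant) or largest
eigenvalue (dominant directional variance) is mapped through a blue→red
palette onto the mean surface, highlighting "hot-spots" of shape
variation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .core import GPSAResult
from .mesh_io import ColoredMesh, TriangleMesh

logger = logging.getLogger(__name__)

__all__ = [
    "VarianceField",
    "ColorMapSpec",
    "DEFAULT_PALETTE",
    "variance_field",
    "colorize",
    "hotspot_report",
]

# blue → cyan → green → yellow → red, evenly spaced stops
DEFAULT_PALETTE: tuple = (
    (0, 0, 255),
    (0, 255, 255),
    (0, 255, 0),
    (255, 255, 0),
    (255, 0, 0),
)


@dataclass
class VarianceField:
    """One non-negative variance value per prototype point (squared units)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("variance values must be a 1-D array")
        if (self.values < 0).any():
            raise ValueError("variance values must be non-negative")

    @property
    def summary(self) -> dict:
        return {
            "min": float(self.values.min()),
            "max": float(self.values.max()),
            "mean": float(self.values.mean()),
        }


@dataclass
class ColorMapSpec:
    """How variance values are normalised and colored.

    ``normalization`` is ``"minmax"`` or ``"percentile"``; in percentile
    mode values are clipped to the (p_low, p_high) percentiles before
    scaling, which keeps single-vertex outliers from washing out the map.
    """

    normalization: str = "minmax"
    p_low: float = 2.0
    p_high: float = 98.0
    palette: tuple = DEFAULT_PALETTE

    def __post_init__(self) -> None:
        if self.normalization not in ("minmax", "percentile"):
            raise ValueError("normalization must be 'minmax' or 'percentile'")
        if self.normalization == "percentile" and not self.p_low < self.p_high:
            raise ValueError("p_low must be < p_high")
        if len(self.palette) < 2:
            raise ValueError("palette needs at least 2 stops")


def variance_field(result: GPSAResult, estimator: str = "trace") -> VarianceField:
    """Per-prototype-point variance of the paired specimen points.

    For each point on the mean surface the paired set holds one
    superimposed vertex per specimen (the point's nearest neighbor on that
    specimen).  The 3×3 sample covariance (n−1 denominator) of the set is
    summarised by its ``trace`` (default: total variance) or
    ``largest_eigenvalue``.
    """
    if estimator not in ("trace", "largest_eigenvalue"):
        raise ValueError("estimator must be 'trace' or 'largest_eigenvalue'")
    n_spec = result.n_specimens
    if n_spec < 2:
        raise ValueError("variance needs a cohort of >= 2 specimens")
    n_pts = result.prototype.n_vertices
    # stack: (n_specimens, n_proto_points, 3)
    stacked = np.stack(
        [
            pts[corr.pairs_ba]
            for pts, corr in zip(result.superimposed, result.pairings)
        ]
    )
    mean = stacked.mean(axis=0)
    dev = stacked - mean
    if estimator == "trace":
        values = np.einsum("spk,spk->p", dev, dev) / (n_spec - 1)
    else:
        cov = np.einsum("spi,spj->pij", dev, dev) / (n_spec - 1)
        values = np.linalg.eigvalsh(cov)[:, -1]
    values = np.maximum(values, 0.0)
    if len(values) != n_pts:
        raise AssertionError("variance field length mismatch")
    return VarianceField(values)


def _normalize(values: np.ndarray, spec: ColorMapSpec) -> np.ndarray:
    v = np.asarray(values, float)
    if spec.normalization == "percentile":
        lo, hi = np.percentile(v, [spec.p_low, spec.p_high])
    else:
        lo, hi = v.min(), v.max()
    if hi <= lo:
        # constant field: everything maps to the low end (blue)
        return np.zeros_like(v)
    return np.clip((v - lo) / (hi - lo), 0.0, 1.0)


def colorize(
    fld: VarianceField, mesh: TriangleMesh, spec: ColorMapSpec | None = None
) -> ColoredMesh:
    """Map a variance field to vertex colors on the mean surface."""
    if spec is None:
        spec = ColorMapSpec()
    if len(fld.values) != mesh.n_vertices:
        raise ValueError(
            f"field length {len(fld.values)} != vertex count {mesh.n_vertices}"
        )
    t = _normalize(fld.values, spec)
    stops = np.asarray(spec.palette, dtype=np.float64)
    k = len(stops) - 1
    x = t * k
    i = np.minimum(x.astype(int), k - 1)
    frac = x - i
    rgb = stops[i] * (1.0 - frac[:, None]) + stops[i + 1] * frac[:, None]
    colors = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)
    return ColoredMesh(mesh, colors)


def hotspot_report(
    fld: VarianceField, mesh: TriangleMesh, top_fraction: float = 0.01
) -> list:
    """Connected clusters of the highest-variance vertices.

    Vertices in the top ``top_fraction`` by value are clustered by
    mesh-edge connectivity; clusters are returned sorted by peak value
    (descending), each as a dict with ``size``, ``vertex_indices``,
    ``centroid``, ``peak_value`` and ``peak_vertex``.
    """
    if not 0.0 < top_fraction < 1.0:
        raise ValueError("top_fraction must be in (0, 1)")
    v = fld.values
    if len(v) != mesh.n_vertices:
        raise ValueError("field length does not match mesh")
    n_top = max(1, int(round(top_fraction * len(v))))
    order = np.argsort(-v, kind="stable")
    thresh = v[order[n_top - 1]]
    selected = np.flatnonzero(v >= thresh)
    sel_set = np.full(len(v), -1, dtype=np.int64)
    sel_set[selected] = np.arange(len(selected))
    # edges of the mesh restricted to selected vertices
    f = mesh.faces
    edges = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    keep = (sel_set[edges[:, 0]] >= 0) & (sel_set[edges[:, 1]] >= 0)
    e = sel_set[edges[keep]]
    m = len(selected)
    graph = coo_matrix(
        (np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(m, m)
    )
    n_comp, labels = connected_components(graph, directed=False)
    clusters = []
    for c in range(n_comp):
        idx = selected[labels == c]
        peak_local = idx[np.argmax(v[idx])]
        clusters.append(
            {
                "size": int(len(idx)),
                "vertex_indices": idx.tolist(),
                "centroid": mesh.vertices[idx].mean(axis=0).tolist(),
                "peak_value": float(v[idx].max()),
                "peak_vertex": int(peak_local),
            }
        )
    clusters.sort(key=lambda c: (-c["peak_value"], c["peak_vertex"]))
    return clusters
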