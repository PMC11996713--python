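"""Principal coordinate ordination of PSM distance matrices.

Classical (Gower) principal coordinate analysis embeds specimens in
Euclidean axes from a pairwise dissimilarity matrix: double-center the
squared distances, eigendecompose, and scale eigenvectors by the square
roots of the positive eigenvalues.  PSM matrices need not be Euclidean, so
negative eigenvalues can occur; they are reported (as total absolute mass)
but never used for scores, and variance proportions are taken over the
positive eigenvalues only.

Homologized vertex coordinates can additionally be regressed onto the axis
scores, turning each ordination axis into a per-vertex deformation field —
the surface analogue of plotting shape change along a principal component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "ShapeModes",
    "pcoa",
    "regress_shapes",
    "ordination_report",
]

_POS_EIG_REL_TOL = 1e-10


@dataclass
class DistanceMatrix:
    """Labelled square symmetric dissimilarity matrix with zero diagonal."""

    labels: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(self.labels) != v.shape[0]:
            raise ValueError("label count must match matrix size")
        if (v < 0).any():
            raise ValueError("distances must be non-negative")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric (1e-12)")
        if np.abs(np.diag(v)).max(initial=0.0) != 0.0:
            raise ValueError("distance matrix diagonal must be exactly zero")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class OrdinationResult:
    scores: np.ndarray  # (n_specimens, n_axes)
    eigenvalues: np.ndarray  # descending, positive ones only
    proportions: np.ndarray  # per retained axis, fraction of positive mass
    negative_eigenvalue_mass: float
    labels: list

    @property
    def n_axes(self) -> int:
        return self.scores.shape[1]


@dataclass
class ShapeModes:
    """Per-axis deformation fields over the prototype (slopes of an OLS fit)."""

    slopes: np.ndarray  # (n_axes, n_points, 3)
    intercept: np.ndarray  # (n_points, 3) — the mean configuration


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude loading of each column positive (reproducible)."""
    out = vectors.copy()
    for k in range(out.shape[1]):
        col = out[:, k]
        i = int(np.argmax(np.abs(col)))
        if col[i] < 0:
            out[:, k] = -col
    return out


def pcoa(D: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Classical principal coordinate analysis of a distance matrix.

    Scores reproduce the input distances exactly whenever the matrix is
    Euclidean and all positive axes are retained.  Axis signs are fixed
    deterministically (largest-magnitude loading positive).
    """
    n = D.n
    if n < 2:
        raise ValueError("need at least 2 specimens")
    d2 = D.values**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    B = (B + B.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    tol = _POS_EIG_REL_TOL * max(abs(eigvals[0]), abs(eigvals[-1]), 1e-300)
    positive = eigvals > tol
    pos_vals = eigvals[positive]
    pos_vecs = _fix_signs(eigvecs[:, positive])
    neg_mass = float(-eigvals[eigvals < -tol].sum())
    k = len(pos_vals) if n_axes is None else min(n_axes, len(pos_vals))
    scores = pos_vecs[:, :k] * np.sqrt(pos_vals[:k])
    total = pos_vals.sum()
    proportions = pos_vals[:k] / total if total > 0 else np.zeros(k)
    return OrdinationResult(
        scores=scores,
        eigenvalues=pos_vals[:k],
        proportions=proportions,
        negative_eigenvalue_mass=neg_mass,
        labels=list(D.labels),
    )


def regress_shapes(
    coords: np.ndarray, result: OrdinationResult, n_axes: int | None = None
) -> ShapeModes:
    """OLS of homologized vertex coordinates on ordination axis scores.

    ``coords`` is (n_specimens, n_points, 3): every specimen expressed on
    the prototype's points via the alignment pairings.  A multiple
    regression with intercept across the retained axes is fitted per point
    and coordinate; the slope field of axis k is the surface deformation
    associated with a unit increase of that axis score.
    """
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim != 3 or coords.shape[2] != 3:
        raise ValueError("coords must be (n_specimens, n_points, 3)")
    n_spec = coords.shape[0]
    if n_spec != len(result.labels):
        raise ValueError("specimen count must match ordination scores")
    k = result.n_axes if n_axes is None else min(n_axes, result.n_axes)
    if n_spec < k + 1:
        raise ValueError(
            f"rank-deficient design: {n_spec} specimens for {k} axes + intercept"
        )
    X = np.column_stack([np.ones(n_spec), result.scores[:, :k]])
    Y = coords.reshape(n_spec, -1)  # (n_spec, n_points*3)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    n_pts = coords.shape[1]
    intercept = beta[0].reshape(n_pts, 3)
    slopes = beta[1:].reshape(k, n_pts, 3)
    return ShapeModes(slopes=slopes, intercept=intercept)


def ordination_report(result: OrdinationResult, out_dir, basename: str = "pcoord") -> dict:
    """Write scores/eigenvalues TSVs and an axis-I/II scatter figure.

    Returns the paths written.  TSV output is deterministic (byte-identical
    across runs on identical input).
    """
    import os

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    scores_path = os.path.join(out_dir, f"{basename}_scores.tsv")
    with open(scores_path, "w") as fh:
        axes_hdr = "\t".join(f"axis_{k+1}" for k in range(result.n_axes))
        fh.write(f"specimen\t{axes_hdr}\n")
        for label, row in zip(result.labels, result.scores):
            vals = "\t".join(f"{v:.12g}" for v in row)
            fh.write(f"{label}\t{vals}\n")
    paths["scores"] = scores_path

    eig_path = os.path.join(out_dir, f"{basename}_eigenvalues.tsv")
    with open(eig_path, "w") as fh:
        fh.write("axis\teigenvalue\tproportion\n")
        for k, (ev, pr) in enumerate(zip(result.eigenvalues, result.proportions)):
            fh.write(f"{k+1}\t{ev:.12g}\t{pr:.12g}\n")
    paths["eigenvalues"] = eig_path

    if result.n_axes >= 2:
        fig, ax = plt.subplots(figsize=(6, 5))
        xs, ys = result.scores[:, 0], result.scores[:, 1]
        ax.scatter(xs, ys, c="tab:blue")
        for label, x, y in zip(result.labels, xs, ys):
            ax.annotate(str(label), (x, y), textcoords="offset points", xytext=(4, 4))
        p1 = round(100 * result.proportions[0])
        p2 = round(100 * result.proportions[1])
        ax.set_xlabel(f"Axis I ({p1:.0f}%)")
        ax.set_ylabel(f"Axis II ({p2:.0f}%)")
        ax.axhline(0, lw=0.5, color="gray")
        ax.axvline(0, lw=0.5, color="gray")
        fig.tight_layout()
        fig_path = os.path.join(out_dir, f"{basename}_scatter.png")
        fig.savefig(fig_path, dpi=150)
        plt.close(fig)
        paths["scatter"] = fig_path
    return paths
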