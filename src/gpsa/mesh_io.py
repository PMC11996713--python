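"""Triangulated-surface containers and PLY input/output.

Surfaces are exchanged in the Stanford polygon (PLY) format, the format in
which segmented cortical surfaces are typically exported.  Both the ASCII
and the binary-little-endian dialects are supported; big-endian files are
rejected with an explicit error because they are essentially absent from
modern tool chains.  Coordinates are held as float64 in memory and written
as float32, the conventional PLY vertex precision.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TriangleMesh",
    "ColoredMesh",
    "MeshFormatError",
    "MeshValidationError",
    "ValidationReport",
    "read_ply",
    "write_ply",
    "validate_mesh",
    "clean_mesh",
]


class MeshFormatError(ValueError):
    """A PLY file violates the subset of the format this package supports."""


class MeshValidationError(ValueError):
    """A mesh object violates the basic invariants required for analysis."""


@dataclass
class TriangleMesh:
    """A closed triangulated surface of one specimen.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex coordinates, in the length units of the input data
        (millimetres for MRI-derived surfaces).
    faces : (m, 3) int array
        Triangles as triples of vertex indices.
    name : str
        Specimen identifier used in tables and output file names.
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshValidationError("vertices must be an (n, 3) array")
        if self.faces.size and (self.faces.ndim != 2 or self.faces.shape[1] != 3):
            raise MeshValidationError("faces must be an (m, 3) array")
        if self.faces.size == 0:
            self.faces = self.faces.reshape(0, 3)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def check(self) -> "TriangleMesh":
        """Validate analysis invariants; return self so calls can chain."""
        if self.n_vertices < 4:
            raise MeshValidationError(
                f"mesh {self.name!r}: needs >= 4 vertices, has {self.n_vertices}"
            )
        if not np.all(np.isfinite(self.vertices)):
            raise MeshValidationError(f"mesh {self.name!r}: non-finite coordinates")
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= self.n_vertices:
                raise MeshValidationError(f"mesh {self.name!r}: face index out of range")
            same = (
                (self.faces[:, 0] == self.faces[:, 1])
                | (self.faces[:, 1] == self.faces[:, 2])
                | (self.faces[:, 0] == self.faces[:, 2])
            )
            if same.any():
                raise MeshValidationError(
                    f"mesh {self.name!r}: {int(same.sum())} faces with repeated indices"
                )
        return self

    def diameter(self) -> float:
        """Length of the axis-aligned bounding-box diagonal."""
        span = self.vertices.max(axis=0) - self.vertices.min(axis=0)
        return float(np.linalg.norm(span))

    def mean_edge_length(self) -> float:
        if not self.n_faces:
            return 0.0
        v = self.vertices
        f = self.faces
        e = np.concatenate(
            [
                np.linalg.norm(v[f[:, 0]] - v[f[:, 1]], axis=1),
                np.linalg.norm(v[f[:, 1]] - v[f[:, 2]], axis=1),
                np.linalg.norm(v[f[:, 2]] - v[f[:, 0]], axis=1),
            ]
        )
        return float(e.mean())


@dataclass
class ColoredMesh:
    """A TriangleMesh plus one uchar RGB triple per vertex (heatmap output)."""

    mesh: TriangleMesh
    vertex_colors: np.ndarray

    def __post_init__(self) -> None:
        self.vertex_colors = np.asarray(self.vertex_colors, dtype=np.uint8)
        if self.vertex_colors.shape != (self.mesh.n_vertices, 3):
            raise MeshValidationError(
                "vertex_colors must be (n_vertices, 3) uchar RGB"
            )


@dataclass
class ValidationReport:
    """Exact counts of the defect classes the validator recognises."""

    duplicate_vertices: int = 0
    unreferenced_vertices: int = 0
    degenerate_faces: int = 0
    details: dict = field(default_factory=dict)

    @property
    def clean(self) -> bool:
        return (
            self.duplicate_vertices == 0
            and self.unreferenced_vertices == 0
            and self.degenerate_faces == 0
        )


# ---------------------------------------------------------------------------
# PLY reading


def _parse_header(fh) -> tuple[str, list]:
    magic = fh.readline().strip()
    if magic != b"ply":
        raise MeshFormatError("not a PLY file (missing 'ply' magic)")
    fmt = None
    elements: list = []  # (name, count, [(prop_name, type) or ('list', ct, it, name)])
    while True:
        line = fh.readline()
        if not line:
            raise MeshFormatError("unexpected end of header (no end_header)")
        tokens = line.decode("ascii", errors="replace").strip().split()
        if not tokens or tokens[0] == "comment" or tokens[0] == "obj_info":
            continue
        if tokens[0] == "format":
            if tokens[1] == "ascii":
                fmt = "ascii"
            elif tokens[1] == "binary_little_endian":
                fmt = "binary"
            elif tokens[1] == "binary_big_endian":
                raise MeshFormatError(
                    "binary_big_endian PLY is not supported; convert to "
                    "ascii or binary_little_endian"
                )
            else:
                raise MeshFormatError(f"unknown PLY format {tokens[1]!r}")
        elif tokens[0] == "element":
            elements.append((tokens[1], int(tokens[2]), []))
        elif tokens[0] == "property":
            if not elements:
                raise MeshFormatError("property before any element")
            if tokens[1] == "list":
                elements[-1][2].append(("list", tokens[2], tokens[3], tokens[4]))
            else:
                elements[-1][2].append((tokens[2], tokens[1]))
        elif tokens[0] == "end_header":
            break
        else:
            raise MeshFormatError(f"unrecognised header line: {' '.join(tokens)}")
    if fmt is None:
        raise MeshFormatError("PLY header missing 'format' line")
    return fmt, elements


_PLY_SCALAR = {
    "char": "i1", "int8": "i1",
    "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2",
    "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4",
    "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4",
    "double": "f8", "float64": "f8",
}


def _scalar_dtype(ply_type: str) -> np.dtype:
    try:
        return np.dtype("<" + _PLY_SCALAR[ply_type])
    except KeyError:
        raise MeshFormatError(f"unsupported PLY scalar type {ply_type!r}") from None


def read_ply(path) -> TriangleMesh | ColoredMesh:
    """Read a triangulated surface from an ASCII or binary-little-endian PLY.

    Returns a :class:`ColoredMesh` when per-vertex uchar red/green/blue
    properties are present, otherwise a plain :class:`TriangleMesh`.  Vertex
    order is preserved from the file.  Non-triangular faces raise
    :class:`MeshFormatError`.
    """
    with open(path, "rb") as fh:
        fmt, elements = _parse_header(fh)
        vertices = colors = faces = None
        for name, count, props in elements:
            if name == "vertex":
                vertices, colors = _read_vertices(fh, fmt, count, props)
            elif name == "face":
                faces = _read_faces(fh, fmt, count, props)
            else:
                _skip_element(fh, fmt, count, props)
    if vertices is None:
        raise MeshFormatError("PLY file has no 'vertex' element")
    if faces is None:
        raise MeshFormatError("PLY file has no 'face' element")
    mesh = TriangleMesh(vertices, faces, name=_stem(path)).check()
    if colors is not None:
        return ColoredMesh(mesh, colors)
    return mesh


def _stem(path) -> str:
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]


def _read_vertices(fh, fmt, count, props):
    for p in props:
        if p[0] == "list":
            raise MeshFormatError("list property on vertex element is unsupported")
    names = [p[0] for p in props]
    for req in ("x", "y", "z"):
        if req not in names:
            raise MeshFormatError(f"vertex element lacks property {req!r}")
    has_color = all(c in names for c in ("red", "green", "blue"))
    if fmt == "binary":
        dtype = np.dtype([(n, "<" + _PLY_SCALAR[t]) for n, t in props])
        buf = fh.read(dtype.itemsize * count)
        if len(buf) != dtype.itemsize * count:
            raise MeshFormatError("truncated vertex data")
        rec = np.frombuffer(buf, dtype=dtype)
    else:
        rows = [fh.readline().split() for _ in range(count)]
        arr = np.array(rows, dtype=np.float64)
        if arr.shape != (count, len(props)):
            raise MeshFormatError("malformed ascii vertex data")
        # honor the declared property types (float32 text round-trips exactly
        # only when parsed back through float32)
        rec = {
            n: arr[:, i].astype(_scalar_dtype(t))
            for i, (n, t) in enumerate(props)
        }
    vertices = np.column_stack(
        [np.asarray(rec["x"], float), np.asarray(rec["y"], float), np.asarray(rec["z"], float)]
    )
    colors = None
    if has_color:
        colors = np.column_stack(
            [np.asarray(rec[c]) for c in ("red", "green", "blue")]
        ).astype(np.uint8)
    return vertices, colors


def _read_faces(fh, fmt, count, props):
    if len(props) != 1 or props[0][0] != "list" or props[0][3] not in (
        "vertex_indices",
        "vertex_index",
    ):
        raise MeshFormatError(
            "face element must have a single 'list ... vertex_indices' property"
        )
    _tag, count_t, index_t, _name = props[0]
    if fmt == "ascii":
        faces = np.empty((count, 3), dtype=np.int64)
        for i in range(count):
            tokens = fh.readline().split()
            if not tokens:
                raise MeshFormatError("truncated face data")
            k = int(tokens[0])
            if k != 3:
                raise MeshFormatError(
                    f"face {i} has {k} vertices; only triangles are supported"
                )
            faces[i] = [int(t) for t in tokens[1:4]]
        return faces
    cdt, idt = _scalar_dtype(count_t), _scalar_dtype(index_t)
    stride = cdt.itemsize + 3 * idt.itemsize
    buf = fh.read()
    if len(buf) < stride * count:
        raise MeshFormatError("truncated face data")
    counts = np.frombuffer(buf, dtype=cdt, count=count * (stride // cdt.itemsize))[
        :: stride // cdt.itemsize
    ] if stride % cdt.itemsize == 0 else None
    # Robust path: verify every list length is 3 before vectorised decode.
    if counts is None or not np.all(counts == 3):
        offset = 0
        for i in range(count):
            k = int(np.frombuffer(buf, dtype=cdt, count=1, offset=offset)[0])
            if k != 3:
                raise MeshFormatError(
                    f"face {i} has {k} vertices; only triangles are supported"
                )
            offset += stride
    rec = np.frombuffer(buf[: stride * count], dtype=np.dtype(
        [("n", cdt), ("idx", idt, (3,))]
    ))
    return rec["idx"].astype(np.int64)


def _skip_element(fh, fmt, count, props):
    if fmt == "ascii":
        for _ in range(count):
            fh.readline()
    else:
        if any(p[0] == "list" for p in props):
            raise MeshFormatError("cannot skip binary element with list properties")
        size = sum(_scalar_dtype(t).itemsize for _n, t in props)
        fh.read(size * count)


# ---------------------------------------------------------------------------
# PLY writing


def write_ply(mesh: TriangleMesh | ColoredMesh, path, dialect: str = "binary") -> None:
    """Write a mesh (optionally vertex-colored) as PLY.

    ``dialect`` is ``"ascii"`` or ``"binary"`` (binary little-endian).
    Coordinates are emitted as float32; colors as uchar red/green/blue,
    the most widely parsed PLY color convention.
    """
    if dialect not in ("ascii", "binary"):
        raise ValueError(f"dialect must be 'ascii' or 'binary', got {dialect!r}")
    if isinstance(mesh, ColoredMesh):
        colors = mesh.vertex_colors
        tri = mesh.mesh
    else:
        colors = None
        tri = mesh
    tri.check()
    verts = tri.vertices.astype("<f4")
    faces = tri.faces.astype("<i4")

    header = ["ply"]
    header.append(
        "format ascii 1.0" if dialect == "ascii" else "format binary_little_endian 1.0"
    )
    header.append(f"element vertex {tri.n_vertices}")
    header += ["property float x", "property float y", "property float z"]
    if colors is not None:
        header += [
            "property uchar red",
            "property uchar green",
            "property uchar blue",
        ]
    header.append(f"element face {tri.n_faces}")
    header.append("property list uchar int vertex_indices")
    header.append("end_header")

    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if dialect == "ascii":
            for i in range(tri.n_vertices):
                row = " ".join(f"{c:.9g}" for c in verts[i])
                if colors is not None:
                    row += " " + " ".join(str(int(c)) for c in colors[i])
                fh.write((row + "\n").encode("ascii"))
            for f in faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n".encode("ascii"))
        else:
            if colors is not None:
                rec = np.empty(
                    tri.n_vertices,
                    dtype=[("xyz", "<f4", (3,)), ("rgb", "u1", (3,))],
                )
                rec["xyz"] = verts
                rec["rgb"] = colors
                fh.write(rec.tobytes())
            else:
                fh.write(verts.tobytes())
            rec = np.empty(tri.n_faces, dtype=[("n", "u1"), ("idx", "<i4", (3,))])
            rec["n"] = 3
            rec["idx"] = faces
            fh.write(rec.tobytes())


# ---------------------------------------------------------------------------
# Validation / cleanup


def _face_areas(mesh: TriangleMesh) -> np.ndarray:
    v = mesh.vertices
    f = mesh.faces
    return 0.5 * np.linalg.norm(
        np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]]), axis=1
    )


def validate_mesh(mesh: TriangleMesh) -> ValidationReport:
    """Report duplicate vertices, unreferenced vertices and zero-area faces.

    This is the light-weight counterpart of the heavy interactive repair
    applied to real scan meshes; it only reports (and, via
    :func:`clean_mesh`, removes) defects that would bias nearest-neighbor
    statistics.  Self-intersections and non-manifold topology are out of
    scope.
    """
    report = ValidationReport()
    _uniq, inverse, counts = np.unique(
        mesh.vertices, axis=0, return_inverse=True, return_counts=True
    )
    report.duplicate_vertices = int((counts[counts > 1] - 1).sum())
    referenced = np.zeros(mesh.n_vertices, dtype=bool)
    if mesh.faces.size:
        referenced[mesh.faces.ravel()] = True
    report.unreferenced_vertices = int((~referenced).sum())
    if mesh.faces.size:
        report.degenerate_faces = int((_face_areas(mesh) == 0.0).sum())
    report.details["unreferenced_indices"] = np.flatnonzero(~referenced)
    return report


def clean_mesh(mesh: TriangleMesh) -> TriangleMesh:
    """Drop unreferenced vertices and zero-area faces, reindexing faces.

    Duplicate (coincident) vertices are kept: they may be intentional in
    meshes with boundary seams.  Idempotent.
    """
    faces = mesh.faces
    if faces.size:
        faces = faces[_face_areas(mesh) > 0.0]
    referenced = np.zeros(mesh.n_vertices, dtype=bool)
    if faces.size:
        referenced[faces.ravel()] = True
    else:
        referenced[:] = True
    remap = np.cumsum(referenced) - 1
    new_vertices = mesh.vertices[referenced]
    new_faces = remap[faces] if faces.size else faces
    return TriangleMesh(new_vertices, new_faces, name=mesh.name)
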