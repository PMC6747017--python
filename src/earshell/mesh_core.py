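"""Triangulated-surface primitives shared by every other module.

Geometry convention
-------------------
All meshes and point sets are in millimetres in a right-handed frame:
+X toward the right pre-auricular point, +Y toward the nasion, +Z up,
origin midway between the pre-auricular points.  Faces are 0-based index
triples wound counter-clockwise seen from outside, so face normals point
outward and the signed (divergence-theorem) volume of a valid closed
surface is positive.  Conversion to metres happens only inside the
physics code (:mod:`earshell.bem_forward`).
"""

from __future__ import annotations

import io as _io
import os
from dataclasses import dataclass, field

import numpy as np
import trimesh as _trimesh
from scipy.spatial import cKDTree

__all__ = [
    "TriMesh",
    "FiducialSet",
    "MeshFormatError",
    "MeshValidationError",
    "read_mesh",
    "write_mesh",
    "read_fiducials",
    "write_fiducials",
    "solid_angle",
    "triangle_solid_angles",
    "winding_number",
    "points_inside",
    "closest_point",
    "surface_distance",
    "remesh",
]

#: triangles smaller than this are considered degenerate and dropped at load
DEGENERATE_AREA_MM2 = 1e-6
#: vertices closer than this are merged at load
MERGE_TOL_MM = 1e-4


class MeshFormatError(ValueError):
    """File could not be parsed in the requested dialect."""


class MeshValidationError(ValueError):
    """Surface violates a TriMesh invariant (openness, orientation, ...)."""


# ---------------------------------------------------------------------------
# TriMesh
# ---------------------------------------------------------------------------


@dataclass
class TriMesh:
    """A closed triangulated surface in mm.

    Parameters
    ----------
    vertices : (n_v, 3) float array
        Vertex coordinates in mm.
    faces : (n_f, 3) int array
        0-based vertex index triples, wound counter-clockwise from outside.
    face_labels : (n_f,) str array, optional
        Region label per face; empty string means unlabeled.
    """

    vertices: np.ndarray
    faces: np.ndarray
    face_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshValidationError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshValidationError("faces must be (m, 3)")
        if self.face_labels is not None:
            self.face_labels = np.asarray(self.face_labels)
            if len(self.face_labels) != len(self.faces):
                raise MeshValidationError("face_labels length mismatch")

    # -- basic quantities ---------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def triangles(self) -> np.ndarray:
        """(n_f, 3, 3) corner coordinates."""
        return self.vertices[self.faces]

    @property
    def face_normals(self) -> np.ndarray:
        """Unit outward normals, (n_f, 3)."""
        t = self.triangles
        n = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return n / norm

    @property
    def face_areas(self) -> np.ndarray:
        t = self.triangles
        return 0.5 * np.linalg.norm(
            np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1
        )

    @property
    def face_centroids(self) -> np.ndarray:
        return self.triangles.mean(axis=1)

    @property
    def area(self) -> float:
        return float(self.face_areas.sum())

    @property
    def volume(self) -> float:
        """Signed enclosed volume (mm^3) by the divergence theorem."""
        t = self.triangles
        return float(np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])).sum() / 6.0)

    @property
    def vertex_normals(self) -> np.ndarray:
        """Area-weighted unit vertex normals."""
        t = self.triangles
        fn = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])  # 2*area-weighted
        vn = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(vn, self.faces[:, k], fn)
        norm = np.linalg.norm(vn, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return vn / norm

    @property
    def edges_unique(self) -> np.ndarray:
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        return np.unique(np.sort(e, axis=1), axis=0)

    @property
    def euler_number(self) -> int:
        return self.n_vertices - len(self.edges_unique) + self.n_faces

    # -- validation ---------------------------------------------------------

    def boundary_edges(self) -> np.ndarray:
        """Edges not shared by exactly two faces, (k, 2)."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        es = np.sort(e, axis=1)
        uniq, counts = np.unique(es, axis=0, return_counts=True)
        return uniq[counts != 2]

    def is_winding_consistent(self) -> bool:
        """Each undirected edge must be traversed once in each direction."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        if (counts != 1).any():
            return False
        # every directed edge must have its reverse present
        fwd = {(int(a), int(b)) for a, b in uniq}
        return all((b, a) in fwd for a, b in fwd)

    def validate(self, name: str = "mesh") -> "TriMesh":
        """Check all TriMesh invariants, raising :class:`MeshValidationError`."""
        if not np.isfinite(self.vertices).all():
            raise MeshValidationError(f"{name}: non-finite vertex coordinates")
        if self.faces.min(initial=0) < 0 or self.faces.max(initial=-1) >= self.n_vertices:
            raise MeshValidationError(f"{name}: face index out of range")
        bad = self.boundary_edges()
        if len(bad):
            shown = ", ".join(f"({a},{b})" for a, b in bad[:10])
            raise MeshValidationError(
                f"{name}: surface not closed; {len(bad)} boundary edges: {shown}"
            )
        if not self.is_winding_consistent():
            raise MeshValidationError(f"{name}: inconsistent face winding")
        if self.volume <= 0:
            raise MeshValidationError(
                f"{name}: signed volume {self.volume:.3g} <= 0 (normals point inward?)"
            )
        if (self.face_areas < DEGENERATE_AREA_MM2).any():
            raise MeshValidationError(f"{name}: degenerate (zero-area) faces present")
        return self

    def is_valid(self) -> bool:
        try:
            self.validate()
            return True
        except MeshValidationError:
            return False

    # -- helpers ------------------------------------------------------------

    def copy(self) -> "TriMesh":
        return TriMesh(
            self.vertices.copy(),
            self.faces.copy(),
            None if self.face_labels is None else self.face_labels.copy(),
        )

    def to_trimesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    @classmethod
    def from_trimesh(cls, m: _trimesh.Trimesh) -> "TriMesh":
        return cls(np.asarray(m.vertices, float), np.asarray(m.faces, np.int64))

    def cleaned(self) -> "TriMesh":
        """Merge near-duplicate vertices and drop degenerate faces."""
        return _clean(self.vertices, self.faces, self.face_labels)


def _clean(vertices, faces, labels=None) -> TriMesh:
    """Merge near-duplicate vertices and collapse degenerate faces.

    Zero-area faces are removed by collapsing their shortest edge (never
    by deletion, which would open the surface).
    """
    verts = np.asarray(vertices, float).copy()
    faces = np.asarray(faces, np.int64).copy()
    labels = None if labels is None else np.asarray(labels)

    # union-find vertex merging
    parent = np.arange(len(verts))

    def find(a):
        root = a
        while parent[root] != root:
            root = parent[root]
        while parent[a] != root:
            parent[a], a = root, parent[a]
        return root

    key = np.round(verts / MERGE_TOL_MM).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    for a, b in zip(np.arange(len(verts)), first[inverse]):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for _ in range(20):
        mapping = np.array([find(i) for i in range(len(verts))])
        f = mapping[faces]
        ok = (f[:, 0] != f[:, 1]) & (f[:, 1] != f[:, 2]) & (f[:, 0] != f[:, 2])
        t = verts[f]
        areas = 0.5 * np.linalg.norm(np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1)
        tiny = ok & (areas < DEGENERATE_AREA_MM2)
        if not tiny.any():
            faces = f[ok]
            if labels is not None:
                labels = labels[ok]
            break
        # collapse the shortest edge of each tiny face
        for fi in np.where(tiny)[0]:
            a, b, c = f[fi]
            pairs = [(a, b), (b, c), (a, c)]
            lengths = [np.linalg.norm(verts[x] - verts[y]) for x, y in pairs]
            x, y = pairs[int(np.argmin(lengths))]
            rx, ry = find(x), find(y)
            if rx != ry:
                verts[ry] = 0.5 * (verts[rx] + verts[ry])
                parent[rx] = ry
    else:
        raise MeshValidationError("could not resolve degenerate faces")

    # drop unreferenced vertices
    used = np.unique(faces)
    remap = -np.ones(len(verts), np.int64)
    remap[used] = np.arange(len(used))
    return TriMesh(verts[used], remap[faces], labels)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_FORMATS = {"stl", "ply", "off"}


def _infer_format(path, fmt: str | None) -> str:
    if fmt is None:
        fmt = os.path.splitext(str(path))[1].lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in _FORMATS:
        raise MeshFormatError(f"unsupported mesh format {fmt!r}; use one of {sorted(_FORMATS)}")
    return fmt


def read_mesh(path, fmt: str | None = None, validate: bool = True) -> TriMesh:
    """Read an STL (binary or ASCII), PLY or OFF surface, in mm.

    The loaded surface is cleaned (duplicate vertices merged within
    ``1e-4`` mm, zero-area faces dropped) and, by default, checked against
    the closed-2-manifold invariants.
    """
    fmt = _infer_format(path, fmt)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        loaded = _trimesh.load(str(path), file_type=fmt, process=False, force="mesh")
    except Exception as exc:  # byte offset is the best diagnostic we can give
        size = os.path.getsize(path)
        raise MeshFormatError(
            f"could not parse {path} as {fmt} (file size {size} bytes): {exc}"
        ) from exc
    if not isinstance(loaded, _trimesh.Trimesh) or len(loaded.faces) == 0:
        raise MeshFormatError(f"{path}: no triangulated geometry found")
    mesh = _clean(np.asarray(loaded.vertices, float), np.asarray(loaded.faces, np.int64))
    if validate:
        mesh.validate(name=str(path))
    return mesh


def write_mesh(mesh: TriMesh, path, fmt: str | None = None) -> None:
    """Write a TriMesh; binary STL, ASCII PLY, or OFF.

    Binary STL stores float32 coordinates; PLY and OFF store full
    precision text.
    """
    fmt = _infer_format(path, fmt)
    tm = mesh.to_trimesh()
    if fmt == "ply":
        data = tm.export(file_type="ply", encoding="ascii")
    else:
        data = tm.export(file_type=fmt)
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)


# ---------------------------------------------------------------------------
# Fiducial / electrode point files:  "label x y z"  (mm), '#' comments
# ---------------------------------------------------------------------------


@dataclass
class FiducialSet:
    """Labeled 3D points in mm (fiducials, landmarks or electrodes)."""

    labels: list[str] = field(default_factory=list)
    points: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))

    def __post_init__(self):
        self.labels = list(self.labels)
        self.points = np.atleast_2d(np.asarray(self.points, float)).reshape(-1, 3)
        if len(self.labels) != len(self.points):
            raise ValueError("labels and points length mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate labels in FiducialSet")
        if not np.isfinite(self.points).all():
            raise ValueError("non-finite coordinates in FiducialSet")

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, label: str) -> bool:
        return label in self.labels

    def __getitem__(self, label: str) -> np.ndarray:
        try:
            return self.points[self.labels.index(label)]
        except ValueError:
            raise KeyError(f"no point labeled {label!r}") from None

    def subset(self, labels) -> "FiducialSet":
        return FiducialSet(list(labels), np.array([self[s] for s in labels]))

    def transformed(self, transform) -> "FiducialSet":
        return FiducialSet(list(self.labels), transform.apply(self.points))

    def spans_volume(self, tol_mm: float = 1.0) -> bool:
        """True when the points are non-coplanar beyond ``tol_mm``.

        Measured as the smallest singular value of the centred coordinates
        (an RMS extent along the thinnest axis).
        """
        if len(self) < 4:
            return False
        c = self.points - self.points.mean(axis=0)
        s = np.linalg.svd(c, compute_uv=False)
        return bool(s[-1] / np.sqrt(len(self)) > tol_mm)


def read_fiducials(path) -> FiducialSet:
    labels, pts = [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{ln}: expected 'label x y z', got {line!r}")
            labels.append(parts[0])
            pts.append([float(v) for v in parts[1:]])
    return FiducialSet(labels, np.asarray(pts))


def write_fiducials(fids: FiducialSet, path, comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        for lab, (x, y, z) in zip(fids.labels, fids.points):
            fh.write(f"{lab} {x:.6f} {y:.6f} {z:.6f}\n")


# ---------------------------------------------------------------------------
# Solid angles and containment
# ---------------------------------------------------------------------------


def triangle_solid_angles(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Signed solid angle of each triangle seen from each point.

    Uses the van Oosterom & Strackee arctangent formula.  Positive when
    the triangle's outward normal faces away from the point, so a closed
    outward-oriented surface sums to ``4*pi`` for interior points and
    ``0`` for exterior points.

    Parameters
    ----------
    points : (n, 3)
    triangles : (m, 3, 3)

    Returns
    -------
    (n, m) array of solid angles in steradians.
    """
    points = np.atleast_2d(np.asarray(points, float))
    v1 = triangles[np.newaxis, :, 0, :] - points[:, np.newaxis, :]
    v2 = triangles[np.newaxis, :, 1, :] - points[:, np.newaxis, :]
    v3 = triangles[np.newaxis, :, 2, :] - points[:, np.newaxis, :]
    l1 = np.linalg.norm(v1, axis=-1)
    l2 = np.linalg.norm(v2, axis=-1)
    l3 = np.linalg.norm(v3, axis=-1)
    triple = np.einsum("nmi,nmi->nm", v1, np.cross(v2, v3))
    denom = (
        l1 * l2 * l3
        + np.einsum("nmi,nmi->nm", v1, v2) * l3
        + np.einsum("nmi,nmi->nm", v2, v3) * l1
        + np.einsum("nmi,nmi->nm", v1, v3) * l2
    )
    return 2.0 * np.arctan2(triple, denom)


def solid_angle(point, mesh_or_triangle, tol_mm: float = 1e-6, warn_near: bool = True):
    """Total signed solid angle of a surface (or one triangle) from a point.

    Raises a warning through :mod:`warnings` when the point lies within
    ``tol_mm`` of the surface (the formula is near-singular there).
    """
    import warnings

    point = np.asarray(point, float).reshape(3)
    if isinstance(mesh_or_triangle, TriMesh):
        tris = mesh_or_triangle.triangles
    else:
        tris = np.asarray(mesh_or_triangle, float).reshape(-1, 3, 3)
    if warn_near:
        d, _, tri_id = _point_triangle_distance(point[np.newaxis], tris)
        if d[0] < tol_mm:
            warnings.warn(
                f"point within {tol_mm} mm of surface (triangle {tri_id[0]}); "
                "solid angle is near-singular",
                RuntimeWarning,
                stacklevel=2,
            )
    return float(triangle_solid_angles(point[np.newaxis], tris).sum())


def winding_number(points, mesh: TriMesh, chunk: int = 2 ** 22) -> np.ndarray:
    """Generalized winding number (1 inside, 0 outside) of each point."""
    points = np.atleast_2d(np.asarray(points, float))
    tris = mesh.triangles
    out = np.empty(len(points))
    step = max(1, chunk // max(len(tris), 1))
    for i in range(0, len(points), step):
        out[i : i + step] = triangle_solid_angles(points[i : i + step], tris).sum(axis=1)
    return out / (4.0 * np.pi)


def points_inside(points, mesh: TriMesh, tol: float = 0.5) -> np.ndarray:
    """Boolean strict-inside test via the generalized winding number."""
    return winding_number(points, mesh) > tol


# ---------------------------------------------------------------------------
# Exact closest-point / distance queries (no rtree dependency)
# ---------------------------------------------------------------------------


def _point_triangle_closest(p: np.ndarray, tri: np.ndarray):
    """Closest points on triangles to query points (vectorized, exact).

    Parameters
    ----------
    p : (n, 3) query points
    tri : (n, 3, 3) one triangle per query point

    Returns
    -------
    closest : (n, 3)
    """
    # Ericson, "Real-Time Collision Detection", closest-point-on-triangle
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    out = np.empty_like(p)
    done = np.zeros(len(p), bool)

    def set_where(mask, value):
        m = mask & ~done
        out[m] = value[m] if value.shape == out.shape else value
        done[m] = True

    set_where((d1 <= 0) & (d2 <= 0), a)  # vertex A
    set_where((d3 >= 0) & (d4 <= d3), b)  # vertex B
    set_where((d6 >= 0) & (d5 <= d6), c)  # vertex C

    v = np.where(np.abs(d1 - d3) > 0, d1 / np.where(d1 - d3 == 0, 1, d1 - d3), 0.0)
    set_where((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v[:, None] * ab)  # edge AB
    w = np.where(np.abs(d2 - d6) > 0, d2 / np.where(d2 - d6 == 0, 1, d2 - d6), 0.0)
    set_where((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w[:, None] * ac)  # edge AC
    den_bc = (d4 - d3) + (d5 - d6)
    wbc = np.where(den_bc != 0, (d4 - d3) / np.where(den_bc == 0, 1, den_bc), 0.0)
    set_where((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0), b + wbc[:, None] * (c - b))

    # interior
    denom = va + vb + vc
    denom = np.where(denom == 0, 1.0, denom)
    vv = (vb / denom)[:, None]
    ww = (vc / denom)[:, None]
    set_where(np.ones(len(p), bool), a + vv * ab + ww * ac)
    return out


def _point_triangle_distance(points: np.ndarray, tris: np.ndarray, k: int = 24):
    """Distance from each point to the nearest triangle of a soup.

    KD-tree on triangle centroids prunes candidates; the pruning radius is
    enlarged by the largest triangle circumradius so the result is exact.

    Returns
    -------
    dist : (n,), closest : (n, 3), tri_index : (n,)
    """
    points = np.atleast_2d(points)
    cent = tris.mean(axis=1)
    # max distance centroid->corner per triangle, used to make pruning safe
    spread = np.linalg.norm(tris - cent[:, None, :], axis=2).max()
    tree = cKDTree(cent)
    k = min(k, len(tris))
    d_cent, idx = tree.query(points, k=k)
    d_cent = np.atleast_2d(d_cent.T).T.reshape(len(points), k)
    idx = idx.reshape(len(points), k)
    best_d = np.full(len(points), np.inf)
    best_p = np.zeros((len(points), 3))
    best_i = np.zeros(len(points), np.int64)
    for j in range(k):
        cand = idx[:, j]
        cp = _point_triangle_closest(points, tris[cand])
        d = np.linalg.norm(points - cp, axis=1)
        better = d < best_d
        best_d[better] = d[better]
        best_p[better] = cp[better]
        best_i[better] = cand[better]
    # exactness check: candidates beyond the k-th centroid distance minus the
    # triangle spread cannot beat best_d; re-query the unsafe points deeper
    unsafe = best_d > d_cent[:, -1] - spread
    while unsafe.any() and k < len(tris):
        k = min(4 * k, len(tris))
        sub = np.where(unsafe)[0]
        d_cent_u, idx_u = tree.query(points[sub], k=k)
        d_cent_u = d_cent_u.reshape(len(sub), k)
        idx_u = idx_u.reshape(len(sub), k)
        for j in range(k):
            cand = idx_u[:, j]
            cp = _point_triangle_closest(points[sub], tris[cand])
            d = np.linalg.norm(points[sub] - cp, axis=1)
            better = d < best_d[sub]
            bs = sub[better]
            best_d[bs] = d[better]
            best_p[bs] = cp[better]
            best_i[bs] = cand[better]
        unsafe[sub] = best_d[sub] > d_cent_u[:, -1] - spread
        if k == len(tris):
            break
    return best_d, best_p, best_i


def closest_point(mesh: TriMesh, points):
    """Closest point on the surface for each query point.

    Returns
    -------
    closest : (n, 3), distance : (n,), face_index : (n,)
    """
    points = np.atleast_2d(np.asarray(points, float))
    d, cp, fi = _point_triangle_distance(points, mesh.triangles)
    return cp, d, fi


def _pseudonormals(mesh: TriMesh):
    """Angle-weighted vertex and edge pseudonormals (Baerentzen-Aanaes).

    Returns (face_normals, vertex_normals, edge_keys_sorted, edge_normals)
    where edge keys are ``min*n_v + max`` for fast lookup.
    """
    fn = mesh.face_normals
    tris = mesh.triangles
    vert_pn = np.zeros((mesh.n_vertices, 3))
    for k in range(3):
        e1 = tris[:, (k + 1) % 3] - tris[:, k]
        e2 = tris[:, (k + 2) % 3] - tris[:, k]
        cosang = np.einsum("ij,ij->i", e1, e2) / (
            np.linalg.norm(e1, axis=1) * np.linalg.norm(e2, axis=1)
        )
        ang = np.arccos(np.clip(cosang, -1.0, 1.0))
        np.add.at(vert_pn, mesh.faces[:, k], fn * ang[:, None])
    norm = np.linalg.norm(vert_pn, axis=1, keepdims=True)
    vert_pn /= np.where(norm == 0, 1, norm)

    nv = mesh.n_vertices
    e = np.vstack([mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]], mesh.faces[:, [2, 0]]])
    keys = np.sort(e, axis=1) @ np.array([nv, 1], dtype=np.int64)
    order = np.argsort(keys, kind="stable")
    keys_sorted = keys[order]
    fn3 = np.tile(fn, (3, 1))[order]
    uniq, start = np.unique(keys_sorted, return_index=True)
    edge_pn = np.add.reduceat(fn3, start, axis=0)
    norm = np.linalg.norm(edge_pn, axis=1, keepdims=True)
    edge_pn /= np.where(norm == 0, 1, norm)
    return fn, vert_pn, uniq, edge_pn


def signed_distance(mesh: TriMesh, points):
    """Exact signed distance to a watertight surface (negative inside).

    The sign comes from the angle-weighted pseudonormal of the closest
    surface feature (face, edge or vertex), which is provably correct for
    closed outward-oriented 2-manifolds.

    Returns
    -------
    sdist : (n,) signed distances in mm
    closest : (n, 3) closest surface points
    face_index : (n,)
    """
    points = np.atleast_2d(np.asarray(points, float))
    d, cp, fi = _point_triangle_distance(points, mesh.triangles)
    fn, vert_pn, edge_keys, edge_pn = _pseudonormals(mesh)

    # barycentric coordinates of the closest point in its triangle
    tri = mesh.triangles[fi]
    ab = tri[:, 1] - tri[:, 0]
    ac = tri[:, 2] - tri[:, 0]
    ap = cp - tri[:, 0]
    d00 = np.einsum("ij,ij->i", ab, ab)
    d01 = np.einsum("ij,ij->i", ab, ac)
    d11 = np.einsum("ij,ij->i", ac, ac)
    d20 = np.einsum("ij,ij->i", ap, ab)
    d21 = np.einsum("ij,ij->i", ap, ac)
    denom = d00 * d11 - d01 * d01
    denom = np.where(np.abs(denom) < 1e-30, 1.0, denom)
    v = (d11 * d20 - d01 * d21) / denom
    w = (d00 * d21 - d01 * d20) / denom
    u = 1.0 - v - w
    bary = np.stack([u, v, w], axis=1)

    eps = 1e-9
    zero = bary < eps
    n_zero = zero.sum(axis=1)
    normal = fn[fi].copy()  # default: face interior
    faces = mesh.faces[fi]
    nv = mesh.n_vertices

    vert_case = n_zero == 2
    if vert_case.any():
        corner = np.argmax(bary[vert_case], axis=1)
        vidx = faces[vert_case, corner]
        normal[vert_case] = vert_pn[vidx]
    edge_case = n_zero == 1
    if edge_case.any():
        miss = np.argmax(zero[edge_case], axis=1)  # the ~0 barycentric corner
        other = np.array([[1, 2], [0, 2], [0, 1]])[miss]
        va = faces[edge_case][np.arange(other.shape[0]), other[:, 0]]
        vb = faces[edge_case][np.arange(other.shape[0]), other[:, 1]]
        key = np.minimum(va, vb) * np.int64(nv) + np.maximum(va, vb)
        pos = np.searchsorted(edge_keys, key)
        normal[edge_case] = edge_pn[pos]

    sign = np.where(np.einsum("ij,ij->i", points - cp, normal) < 0, -1.0, 1.0)
    return sign * d, cp, fi


def _segment_segment_distance(p1, q1, p2, q2):
    """Min distance between segment batches [p1,q1] and [p2,q2], (n,)."""
    # Ericson 5.1.9, vectorized
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = np.einsum("ij,ij->i", d1, d1)
    e = np.einsum("ij,ij->i", d2, d2)
    f = np.einsum("ij,ij->i", d2, r)
    c = np.einsum("ij,ij->i", d1, r)
    b = np.einsum("ij,ij->i", d1, d2)
    denom = a * e - b * b
    s = np.where(denom > 1e-30, (b * f - c * e) / np.where(denom <= 1e-30, 1, denom), 0.0)
    s = np.clip(s, 0.0, 1.0)
    t = np.where(e > 1e-30, (b * s + f) / np.where(e <= 1e-30, 1, e), 0.0)
    tc = np.clip(t, 0.0, 1.0)
    clamped = t != tc
    s_re = np.clip((b * tc - c) / np.where(a <= 1e-30, 1, a), 0.0, 1.0)
    s = np.where(clamped, s_re, s)
    t = tc
    c1 = p1 + s[:, None] * d1
    c2 = p2 + t[:, None] * d2
    return np.linalg.norm(c1 - c2, axis=1), c1, c2


def surface_distance(mesh_a: TriMesh, mesh_b: TriMesh):
    """Exact minimum distance between two triangulated surfaces.

    Considers vertex-to-face and edge-to-edge contacts in both directions.

    Returns
    -------
    dist : float (mm)
    pair : (point_on_a, point_on_b) closest point pair
    """
    # vertex(A) -> triangles(B) and vertex(B) -> triangles(A)
    d_ab, cp_ab, _ = _point_triangle_distance(mesh_a.vertices, mesh_b.triangles)
    d_ba, cp_ba, _ = _point_triangle_distance(mesh_b.vertices, mesh_a.triangles)
    ia = int(np.argmin(d_ab))
    ib = int(np.argmin(d_ba))
    best = (d_ab[ia], mesh_a.vertices[ia], cp_ab[ia])
    if d_ba[ib] < best[0]:
        best = (d_ba[ib], cp_ba[ib], mesh_b.vertices[ib])

    # edge-edge: prune with KD-tree on edge midpoints
    ea = mesh_a.edges_unique
    eb = mesh_b.edges_unique
    pa, qa = mesh_a.vertices[ea[:, 0]], mesh_a.vertices[ea[:, 1]]
    pb, qb = mesh_b.vertices[eb[:, 0]], mesh_b.vertices[eb[:, 1]]
    ma, mb = 0.5 * (pa + qa), 0.5 * (pb + qb)
    half_a = 0.5 * np.linalg.norm(qa - pa, axis=1)
    half_b = 0.5 * np.linalg.norm(qb - pb, axis=1)
    radius = best[0] + half_a.max() + half_b.max()
    tree_b = cKDTree(mb)
    pairs = tree_b.query_ball_point(ma, r=radius)
    ii = np.repeat(np.arange(len(ea)), [len(p) for p in pairs])
    jj = np.concatenate(pairs).astype(np.int64) if len(ii) else np.zeros(0, np.int64)
    if len(ii):
        for lo in range(0, len(ii), 2 ** 20):
            sl = slice(lo, lo + 2 ** 20)
            d, c1, c2 = _segment_segment_distance(pa[ii[sl]], qa[ii[sl]], pb[jj[sl]], qb[jj[sl]])
            kk = int(np.argmin(d))
            if d[kk] < best[0]:
                best = (d[kk], c1[kk], c2[kk])
    return float(best[0]), (best[1].copy(), best[2].copy())


# ---------------------------------------------------------------------------
# Remeshing: loop subdivision up + quadric edge-collapse down
# ---------------------------------------------------------------------------


def _quadric_decimate(mesh: TriMesh, target_faces: int, protected: np.ndarray | None = None) -> TriMesh:
    """Garland-Heckbert quadric edge-collapse to ``target_faces``.

    ``protected`` marks faces whose edges are never collapsed (used to
    keep a labelled region dense).  Collapses that would break the link
    condition, flip a face normal, or create a degenerate face are
    rejected, so a closed 2-manifold input stays closed.
    """
    import heapq

    V = mesh.vertices.copy()
    F = mesh.faces.copy()
    nf_alive = len(F)
    if nf_alive <= target_faces:
        return mesh.copy()

    labels = mesh.face_labels
    prot_v = np.zeros(len(V), bool)
    if protected is not None and protected.any():
        prot_v[np.unique(F[protected])] = True

    # plane quadrics per vertex (area weighted)
    tris = V[F]
    n = np.cross(tris[:, 1] - tris[:, 0], tris[:, 2] - tris[:, 0])
    area2 = np.linalg.norm(n, axis=1)
    nn = n / np.where(area2[:, None] == 0, 1, area2[:, None])
    d = -np.einsum("ij,ij->i", nn, tris[:, 0])
    plane = np.hstack([nn, d[:, None]])  # (m,4)
    Kf = plane[:, :, None] * plane[:, None, :] * (0.5 * area2)[:, None, None]
    Q = np.zeros((len(V), 4, 4))
    for k in range(3):
        np.add.at(Q, F[:, k], Kf)

    # adjacency
    vert_faces: list[set] = [set() for _ in range(len(V))]
    for fi, f in enumerate(F):
        for v in f:
            vert_faces[v].add(fi)
    face_alive = np.ones(len(F), bool)

    def neighbors(v):
        s = set()
        for fi in vert_faces[v]:
            s.update(F[fi])
        s.discard(v)
        return s

    def edge_cost(u, v):
        Qe = Q[u] + Q[v]
        A = Qe[:3, :3]
        b = -Qe[:3, 3]
        try:
            pos = np.linalg.solve(A + 1e-9 * np.trace(A) / 3 * np.eye(3), b)
        except np.linalg.LinAlgError:
            pos = 0.5 * (V[u] + V[v])
        h = np.append(pos, 1.0)
        return float(h @ Qe @ h), pos

    heap = []
    version = {}

    def push(u, v):
        if u > v:
            u, v = v, u
        if prot_v[u] and prot_v[v]:
            return
        cost, pos = edge_cost(u, v)
        ver = version.get((u, v), 0)
        heapq.heappush(heap, (cost, u, v, ver, pos))

    seen = set()
    for f in F:
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            key = (min(a, b), max(a, b))
            if key not in seen:
                seen.add(key)
                push(a, b)
    del seen

    vert_alive = np.ones(len(V), bool)

    while nf_alive > target_faces and heap:
        cost, u, v, ver, pos = heapq.heappop(heap)
        if not (vert_alive[u] and vert_alive[v]):
            continue
        if version.get((u, v), 0) != ver:
            continue
        shared = vert_faces[u] & vert_faces[v]
        if len(shared) != 2:
            continue
        # link condition: common neighbors must be exactly the two opposite verts
        common = neighbors(u) & neighbors(v)
        opposite = set()
        for fi in shared:
            opposite.update(F[fi])
        opposite -= {u, v}
        if common != opposite:
            continue
        # simulate: check normal flips / degeneracy
        affected = (vert_faces[u] | vert_faces[v]) - shared
        ok = True
        for fi in affected:
            f = F[fi].copy()
            old = np.cross(V[f[1]] - V[f[0]], V[f[2]] - V[f[0]])
            f[f == v] = u
            p0, p1, p2 = (pos if f[0] == u else V[f[0]],
                          pos if f[1] == u else V[f[1]],
                          pos if f[2] == u else V[f[2]])
            new = np.cross(p1 - p0, p2 - p0)
            na = np.linalg.norm(new)
            if na < 2 * DEGENERATE_AREA_MM2 or np.dot(old, new) <= 0:
                ok = False
                break
        if not ok:
            continue
        # commit: collapse v into u at pos
        V[u] = pos
        Q[u] = Q[u] + Q[v]
        vert_alive[v] = False
        prot_v[u] = prot_v[u] or prot_v[v]
        for fi in shared:
            face_alive[fi] = False
            for w in F[fi]:
                vert_faces[w].discard(fi)
            nf_alive -= 1
        for fi in vert_faces[v]:
            F[fi][F[fi] == v] = u
            vert_faces[u].add(fi)
        vert_faces[v] = set()
        # re-queue edges around u
        for w in neighbors(u):
            a, b = (u, w) if u < w else (w, u)
            version[(a, b)] = version.get((a, b), 0) + 1
            push(a, b)

    F = F[face_alive]
    lab = labels[face_alive] if labels is not None else None
    used = np.unique(F)
    remap = -np.ones(len(V), np.int64)
    remap[used] = np.arange(len(used))
    return TriMesh(V[used], remap[F], lab)


def _subdivide(mesh: TriMesh) -> TriMesh:
    """Midpoint (1-to-4) subdivision of every face."""
    from trimesh.remesh import subdivide as _sub

    v, f = _sub(mesh.vertices, mesh.faces)
    labels = None
    if mesh.face_labels is not None:
        labels = np.repeat(mesh.face_labels, 4)
    return _clean(np.asarray(v), np.asarray(f, np.int64), labels)


def remesh(
    mesh: TriMesh,
    target_faces: int,
    dense_region: str | None = None,
    density_ratio: float = 4.0,
) -> TriMesh:
    """Resample a closed surface to approximately ``target_faces`` faces.

    Faces labelled ``dense_region`` are kept at (at least) ``density_ratio``
    times the area density of the rest of the surface: the dense region is
    midpoint-subdivided as needed and excluded from edge collapses, while
    the remainder is decimated with a quadric error metric.

    Raises
    ------
    MeshValidationError
        If the result would not be a closed 2-manifold; the input is then
        returned unmodified by the caller's choice (the error carries it).
    """
    if target_faces < 100:
        raise ValueError("target_faces must be >= 100")
    work = mesh.copy()
    if work.face_labels is None:
        work.face_labels = np.array([""] * work.n_faces, dtype=object)

    if dense_region is not None:
        dense = work.face_labels == dense_region
        if not dense.any():
            raise ValueError(f"no faces labelled {dense_region!r}")
        # subdivide globally until the dense region is fine enough, then
        # decimate only the rest; global subdivision keeps the mesh conforming
        mean_other = work.face_areas[~dense].mean()
        while work.face_areas[work.face_labels == dense_region].mean() > mean_other / density_ratio:
            work = _subdivide(work)
        dense = work.face_labels == dense_region
        n_dense = int(dense.sum())
        if n_dense >= target_faces:
            raise ValueError("dense region alone exceeds target_faces")
        out = _quadric_decimate(work, target_faces, protected=dense)
    else:
        while work.n_faces < target_faces:
            work = _subdivide(work)
        out = _quadric_decimate(work, target_faces)

    try:
        out.validate("remeshed")
    except MeshValidationError as exc:
        raise MeshValidationError(f"remesh failed, input left unmodified: {exc}") from exc
    if abs(out.n_faces - target_faces) > 0.1 * target_faces:
        raise MeshValidationError(
            f"remesh reached {out.n_faces} faces, outside 10% of target {target_faces}"
        )
    return out
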