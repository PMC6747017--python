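"""Ear carving and nested-surface bookkeeping for 4-compartment head models.

A head model is the ordered surface stack [scalp, outer skull, inner
skull, brain] with a conductivity per compartment.  Ear-impression
solids registered into the head frame are subtracted from the scalp
surface (the concha bowl and ear canal become part of the outer
boundary), after which a 1 mm minimum inter-surface distance is enforced
sequentially from the scalp inward so the BEM never sees touching
boundaries.

The boolean difference is evaluated on a signed-distance lattice and
re-triangulated with marching cubes, which is watertight by
construction; deep concave features such as the ear canal are
represented exactly as well as the lattice resolution allows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .mesh_core import (
    MeshValidationError,
    TriMesh,
    _clean,
    _point_triangle_distance,
    points_inside,
    surface_distance,
    winding_number,
)

__all__ = [
    "HeadModel",
    "PAPER_CONDUCTIVITIES",
    "SURFACE_NAMES",
    "signed_distance_grid",
    "mesh_from_sdf",
    "carve_ears",
    "enforce_min_distance",
    "check_nesting",
]

SURFACE_NAMES = ("scalp", "outer_skull", "inner_skull", "brain")

#: compartment conductivities in S/m, ordered like SURFACE_NAMES
#: (scalp-to-outer-skull, skull, CSF, inside brain)
PAPER_CONDUCTIVITIES = (0.33, 0.0132, 1.79, 0.33)


@dataclass
class HeadModel:
    """Nested tissue boundaries with compartment conductivities.

    ``surfaces`` is ordered outside-in: scalp, outer skull, inner skull,
    brain.  ``conductivities[i]`` (S/m) is the conductivity of the
    compartment immediately inside ``surfaces[i]``.
    """

    surfaces: list
    conductivities: tuple = PAPER_CONDUCTIVITIES
    min_distance: float = 1.0

    def __post_init__(self):
        if len(self.surfaces) != len(self.conductivities):
            raise ValueError("one conductivity per surface required")
        self.conductivities = tuple(float(s) for s in self.conductivities)
        if any(s <= 0 for s in self.conductivities):
            raise ValueError("conductivities must be positive")

    @property
    def scalp(self) -> TriMesh:
        return self.surfaces[0]

    @property
    def brain(self) -> TriMesh:
        return self.surfaces[-1]

    def validate(self) -> "HeadModel":
        for name, surf in zip(SURFACE_NAMES, self.surfaces):
            surf.validate(name)
        report = check_nesting(self)
        if not report["ok"]:
            raise MeshValidationError("head model nesting violated: " + report["summary"])
        return self

    def save(self, directory) -> None:
        """Write four STL files plus a YAML manifest."""
        import os

        import yaml

        from .mesh_core import write_mesh

        os.makedirs(directory, exist_ok=True)
        manifest = {
            "surfaces": [],
            "conductivities_S_per_m": dict(zip(SURFACE_NAMES, self.conductivities)),
            "min_distance_mm": self.min_distance,
            "units": "mm",
            "frame": "+X right pre-auricular, +Y nasion, +Z up",
        }
        for name, surf in zip(SURFACE_NAMES, self.surfaces):
            fname = f"{name}.stl"
            write_mesh(surf, os.path.join(directory, fname))
            manifest["surfaces"].append(fname)
        with open(os.path.join(directory, "headmodel.yaml"), "w") as fh:
            yaml.safe_dump(manifest, fh)

    @classmethod
    def load(cls, directory) -> "HeadModel":
        import os

        import yaml

        from .mesh_core import read_mesh

        with open(os.path.join(directory, "headmodel.yaml")) as fh:
            manifest = yaml.safe_load(fh)
        surfs = [read_mesh(os.path.join(directory, f)) for f in manifest["surfaces"]]
        cond = tuple(manifest["conductivities_S_per_m"][n] for n in SURFACE_NAMES)
        return cls(surfs, cond, manifest.get("min_distance_mm", 1.0))


# ---------------------------------------------------------------------------
# Signed-distance lattice + marching cubes
# ---------------------------------------------------------------------------


def signed_distance_grid(mesh: TriMesh, origin, spacing: float, shape) -> np.ndarray:
    """Signed distance (negative inside, mm) sampled on a regular lattice.

    The distance is exact (point-to-triangle) within a narrow band around
    the surface and clamped to ``+-band`` beyond it; signs away from the
    band come from flood-filling lattice components, with one winding
    number evaluation per ambiguous component.  That is all marching
    cubes needs to reproduce the surface at second order.
    """
    from .mesh_core import signed_distance

    origin = np.asarray(origin, float)
    shape = tuple(int(s) for s in shape)
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    pts = origin + spacing * np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)

    # upper bound on distance: nearest vertex (within max_edge of the truth)
    tree = cKDTree(mesh.vertices)
    d_vert, _ = tree.query(pts)
    edges = mesh.edges_unique
    max_edge = float(
        np.linalg.norm(mesh.vertices[edges[:, 0]] - mesh.vertices[edges[:, 1]], axis=1).max()
    )
    band = 2.5 * spacing

    sdf = np.full(len(pts), band)
    refine = d_vert <= band + max_edge  # superset of {true distance <= band}
    if refine.any():
        sd, _, _ = signed_distance(mesh, pts[refine])
        sdf[refine] = np.clip(sd, -band, band)

    # off-band cells carry only a sign; flood-fill connected components and
    # settle each with a single winding-number evaluation
    known = refine.reshape(shape)
    labels, n_lab = ndimage.label(~known)
    flat_labels = labels.reshape(-1)
    for lab in range(1, n_lab + 1):
        member = flat_labels == lab
        rep = int(np.argmax(member))
        inside = bool(points_inside(pts[rep][np.newaxis], mesh)[0])
        if inside:
            sdf[member] = -band
    return sdf.reshape(shape)


def mesh_from_sdf(sdf: np.ndarray, origin, spacing: float) -> TriMesh:
    """Triangulate the zero level set; keeps the largest closed component."""
    from skimage.measure import marching_cubes

    verts, faces, _, _ = marching_cubes(sdf, level=0.0, spacing=(spacing,) * 3)
    mesh = _clean(verts + np.asarray(origin, float), faces.astype(np.int64))
    mesh = _largest_component(mesh)
    if mesh.volume < 0:
        mesh = TriMesh(mesh.vertices, mesh.faces[:, ::-1], mesh.face_labels)
    return mesh


def _largest_component(mesh: TriMesh) -> TriMesh:
    """Largest face-connected component (marching cubes can emit crumbs)."""
    n = mesh.n_faces
    edge_map: dict = {}
    parent = np.arange(n)

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for fi, f in enumerate(mesh.faces):
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            key = (a, b) if a < b else (b, a)
            other = edge_map.pop(key, None)
            if other is None:
                edge_map[key] = fi
            else:
                ra, rb = find(fi), find(other)
                if ra != rb:
                    parent[ra] = rb
    roots = np.array([find(i) for i in range(n)])
    _, counts = np.unique(roots, return_counts=True)
    keep_root = np.unique(roots)[np.argmax(counts)]
    keep = roots == keep_root
    labels = mesh.face_labels[keep] if mesh.face_labels is not None else None
    return _clean(mesh.vertices, mesh.faces[keep], labels)


# ---------------------------------------------------------------------------
# Carving
# ---------------------------------------------------------------------------


def carve_ears(
    scalp: TriMesh,
    impressions,
    resolution: float = 1.5,
    target_faces: int | None = None,
) -> TriMesh:
    """Subtract registered ear-impression solids from the scalp surface.

    The boolean volume difference ``scalp - union(impressions)`` is
    evaluated as ``max(sdf_scalp, -sdf_impression)`` on a lattice of the
    given ``resolution`` (mm) and re-triangulated.  Faces of the result
    lying on the carved surface are labelled ``"ear"``.

    Impressions entirely outside the scalp volume are ignored with a
    warning.  The result is decimated back to approximately the input
    face count (or ``target_faces``) with the ear region protected, so
    the carved detail survives.
    """
    scalp.validate("scalp")
    if isinstance(impressions, TriMesh):
        impressions = [impressions]
    active = []
    for i, imp in enumerate(impressions):
        imp.validate(f"impression[{i}]")
        d, _ = surface_distance(scalp, imp)
        intersects = (
            points_inside(imp.vertices[:1], scalp)[0]
            or points_inside(scalp.vertices[:1], imp)[0]
            or d == 0.0
        )
        # robust overlap test: any impression vertex inside scalp volume
        if not intersects:
            intersects = points_inside(imp.vertices, scalp).any()
        if intersects:
            active.append(imp)
        else:
            warnings.warn(
                f"impression[{i}] lies entirely outside the scalp; ignored",
                RuntimeWarning,
                stacklevel=2,
            )
    if not active:
        return scalp.copy()

    lo = scalp.vertices.min(axis=0) - 3 * resolution
    hi = scalp.vertices.max(axis=0) + 3 * resolution
    shape = np.ceil((hi - lo) / resolution).astype(int) + 1
    sdf = signed_distance_grid(scalp, lo, resolution, shape)
    for imp in active:
        sdf_imp = signed_distance_grid(imp, lo, resolution, shape)
        sdf = np.maximum(sdf, -sdf_imp)
    carved = mesh_from_sdf(sdf, lo, resolution)

    # label the freshly carved region: faces whose centroid is inside (or
    # hugging) one of the impression solids
    cent = carved.face_centroids
    ear = np.zeros(carved.n_faces, bool)
    for imp in active:
        lo_i = imp.vertices.min(axis=0) - 3 * resolution
        hi_i = imp.vertices.max(axis=0) + 3 * resolution
        in_box = np.all((cent >= lo_i) & (cent <= hi_i), axis=1)
        if not in_box.any():
            continue
        d_imp, _, _ = _point_triangle_distance(cent[in_box], imp.triangles)
        wn = winding_number(cent[in_box], imp)
        ear[in_box] |= (wn > 0.5) | (d_imp < 1.5 * resolution)
    labels = np.where(ear, "ear", "").astype(object)
    carved = TriMesh(carved.vertices, carved.faces, labels)

    if target_faces is None:
        target_faces = max(scalp.n_faces, int(ear.sum() * 2))
    if carved.n_faces > target_faces:
        from .mesh_core import _quadric_decimate

        carved = _quadric_decimate(carved, target_faces, protected=ear)
    try:
        carved.validate("carved scalp")
    except MeshValidationError as exc:
        raise MeshValidationError(f"carve produced an invalid surface: {exc}") from exc
    if carved.volume >= scalp.volume:
        raise MeshValidationError("carve did not reduce the scalp volume")
    return carved


# ---------------------------------------------------------------------------
# Minimum-distance enforcement and nesting checks
# ---------------------------------------------------------------------------


def _diffuse_displacement(
    mesh: TriMesh, delta: np.ndarray, pinned: np.ndarray, iterations: int = 5
) -> np.ndarray:
    """Spread a displacement field from pinned vertices into their rings.

    The pinned (constraint-violating) vertices keep their exact
    displacement; neighbours pick up the ring average, which moves each
    patch coherently instead of creasing single vertices.
    """
    edges = mesh.edges_unique
    n = mesh.n_vertices
    out = delta.copy()
    for _ in range(iterations):
        acc = np.zeros((n, 3))
        cnt = np.zeros(n)
        np.add.at(acc, edges[:, 0], out[edges[:, 1]])
        np.add.at(acc, edges[:, 1], out[edges[:, 0]])
        np.add.at(cnt, edges[:, 0], 1)
        np.add.at(cnt, edges[:, 1], 1)
        mean = acc / np.maximum(cnt, 1)[:, None]
        out = np.where(pinned[:, None], delta, 0.5 * (out + mean))
    out[pinned] = delta[pinned]
    return out


def enforce_min_distance(model: HeadModel, dmin: float | None = None) -> HeadModel:
    """Push nested surfaces inward until adjacent gaps are >= ``dmin`` mm.

    Surfaces are processed outside-in (scalp first, brain last): the
    outer surface of each pair is held fixed and offending vertices of
    the inner surface are displaced inward along their outward vertex
    normals, followed by a few Laplacian smoothing sweeps restricted to
    the displaced patch.  A model that already satisfies the constraint
    is returned unchanged.
    """
    if dmin is None:
        dmin = model.min_distance
    surfaces = [model.surfaces[0]]
    changed_any = False
    for k in range(1, len(model.surfaces)):
        outer = surfaces[-1]
        inner = model.surfaces[k].copy()
        tris = outer.triangles
        changed = False
        for _ in range(60):
            # sample the gap at vertices, edge midpoints and face centroids:
            # coarse faces can violate the clearance between their vertices
            edges = inner.edges_unique
            samples = np.vstack(
                [
                    inner.vertices,
                    0.5 * (inner.vertices[edges[:, 0]] + inner.vertices[edges[:, 1]]),
                    inner.face_centroids,
                ]
            )
            owners = (
                [np.array([i]) for i in range(inner.n_vertices)]
                + [e for e in edges]
                + [f for f in inner.faces]
            )
            d, cp, _ = _point_triangle_distance(samples, tris)
            # samples poking outside the outer surface count as negative gap
            out_mask = ~points_inside(samples, outer)
            gap = np.where(out_mask, -d, d)
            bad = gap < dmin

            # reverse direction: fine outer-surface detail (e.g. the carved
            # ear canal) can graze a coarse inner face between its samples
            d_r, cp_r, fi_r = _point_triangle_distance(
                outer.vertices, inner.triangles
            )
            in_mask_r = points_inside(outer.vertices, inner)
            gap_r = np.where(in_mask_r, -d_r, d_r)
            bad_r = gap_r < dmin

            if not bad.any() and not bad_r.any():
                break
            changed = True
            delta = np.zeros_like(inner.vertices)

            def accumulate(vec, verts):
                for vi in verts:
                    if np.linalg.norm(vec) > np.linalg.norm(delta[vi]):
                        delta[vi] = vec

            # move along the local gap direction (away from the fixed outer
            # surface, into the interior) -- unlike the vertex normal this
            # also clears lateral features such as ear-canal walls;
            # aim slightly past dmin so the loop terminates cleanly
            target = dmin + 0.25
            if bad.any():
                g = samples[bad] - cp[bad]
                norm = np.linalg.norm(g, axis=1, keepdims=True)
                ghat = np.where(norm > 1e-9, g / np.where(norm == 0, 1, norm), 0.0)
                ghat[out_mask[bad]] *= -1.0
                push = (target - gap[bad])[:, None] * ghat
                for vec, si in zip(push, np.where(bad)[0]):
                    accumulate(vec, owners[si])
            if bad_r.any():
                g = cp_r[bad_r] - outer.vertices[bad_r]
                norm = np.linalg.norm(g, axis=1, keepdims=True)
                ghat = np.where(norm > 1e-9, g / np.where(norm == 0, 1, norm), 0.0)
                ghat[in_mask_r[bad_r]] *= -1.0
                push = (target - gap_r[bad_r])[:, None] * ghat
                for vec, fi in zip(push, fi_r[bad_r]):
                    accumulate(vec, inner.faces[fi])

            pinned = np.linalg.norm(delta, axis=1) > 0
            delta = _diffuse_displacement(inner, delta, pinned, iterations=5)
            inner.vertices += delta
        else:
            raise MeshValidationError(
                f"could not enforce {dmin} mm gap between "
                f"{SURFACE_NAMES[k - 1]} and {SURFACE_NAMES[k]}"
            )
        if changed:
            if inner.volume <= 0:
                raise MeshValidationError(
                    f"{SURFACE_NAMES[k]} inverted while enforcing the minimum distance"
                )
            changed_any = True
            surfaces.append(inner)
        else:
            surfaces.append(model.surfaces[k])
    if not changed_any:
        return model
    out = HeadModel(surfaces, model.conductivities, dmin)
    report = check_nesting(out)
    if not report["ok"]:
        raise MeshValidationError(
            "minimum-distance enforcement broke nesting: " + report["summary"]
        )
    return out


def check_nesting(model: HeadModel, dmin: float | None = None) -> dict:
    """Per-surface-pair nesting and minimum-distance report.

    Returns a dict with ``ok`` (bool), ``pairs`` (list of per-pair
    dicts: nested flag, min distance, worst vertex) and ``summary``.
    """
    if dmin is None:
        dmin = model.min_distance
    pairs = []
    ok = True
    for k in range(len(model.surfaces) - 1):
        outer, inner = model.surfaces[k], model.surfaces[k + 1]
        inside = points_inside(inner.vertices, outer)
        nested = bool(inside.all())
        worst = None if nested else int(np.argmin(inside))
        d, _ = surface_distance(outer, inner)
        entry = {
            "pair": (SURFACE_NAMES[k], SURFACE_NAMES[k + 1]),
            "nested": nested,
            "worst_vertex": worst,
            "min_distance_mm": d,
            "distance_ok": bool(d >= dmin),
        }
        ok = ok and nested and entry["distance_ok"]
        pairs.append(entry)
    summary = "; ".join(
        f"{p['pair'][0]}->{p['pair'][1]}: nested={p['nested']}, "
        f"d={p['min_distance_mm']:.2f}mm" for p in pairs
    )
    return {"ok": ok, "pairs": pairs, "summary": summary}
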