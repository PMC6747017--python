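"""Boundary-element forward solver with the isolated problem approach.

The potential on the tissue boundaries of a piecewise-homogeneous head
model satisfies the Geselowitz surface integral equation.  It is
discretized here by vertex collocation with linear shape functions and
the analytic per-triangle potential integrals of de Munck (1992); the
singular free constant is removed by rank-one deflation.

The skull conductivity is ~25x lower than its neighbours, which makes
the plain collocation solution inaccurate for sources near the inner
skull.  The isolated problem approach (IPA) of Hamalainen & Sarvas
splits the solution into the solution of an "isolated" sub-problem --
the volume bounded by the inner skull with zero conductivity outside --
plus a smooth correction, which removes most of the numerical error of
the conductivity jump.  The implementation generalizes the classical
three-surface formulation to the four-surface (scalp, outer skull,
inner skull, brain) models used here, with the isolated sub-problem
spanning the inner-skull and brain surfaces.

Geometry enters in mm and is converted to metres on assembly, so lead
fields are in volts per A*m of dipole moment.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla

from .head_carving import HeadModel
from .mesh_core import TriMesh, closest_point, points_inside

__all__ = [
    "Dipole",
    "SourceGrid",
    "BemSystem",
    "LeadFieldMatrix",
    "infinite_potential",
    "assemble",
    "solve",
    "build_source_grid",
    "compute_leadfield",
    "rereference",
    "rdm",
    "mag",
]

MM = 1e-3  # mm -> m


@dataclass(frozen=True)
class Dipole:
    """Equivalent current dipole: position in mm, moment in A*m."""

    position: np.ndarray
    moment: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, float).reshape(3))
        object.__setattr__(self, "moment", np.asarray(self.moment, float).reshape(3))


@dataclass
class SourceGrid:
    """Axis-aligned dipole lattice clipped to the brain volume.

    ``nodes`` are in mm; ``near_boundary`` flags nodes closer than the
    requested margin to the brain surface (kept, but flagged so accuracy
    claims can exclude them).  ``ijk`` holds the lattice coordinates of
    every node and ``origin`` the lattice origin, which together support
    trilinear lead-field interpolation between nodes.
    """

    nodes: np.ndarray
    spacing: float
    near_boundary: np.ndarray
    ijk: np.ndarray
    origin: np.ndarray
    shape: tuple
    node_lookup: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        if self.node_lookup is None:
            lut = -np.ones(self.shape, np.int64)
            lut[tuple(self.ijk.T)] = np.arange(len(self.nodes))
            self.node_lookup = lut

    def __len__(self):
        return len(self.nodes)


# ---------------------------------------------------------------------------
# Infinite-medium potential (the BEM source term)
# ---------------------------------------------------------------------------


def infinite_potential(dipole: Dipole, points, sigma: float) -> np.ndarray:
    """Potential of a current dipole in an unbounded homogeneous medium.

    ``v = q . (r - r0) / (4 pi sigma |r - r0|^3)`` with positions in mm
    and ``sigma`` in S/m; returns volts.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    r = np.atleast_2d(np.asarray(points, float)) * MM
    r0 = dipole.position * MM
    d = r - r0
    d2 = np.einsum("ij,ij->i", d, d)
    if (d2 == 0).any():
        raise ValueError("observation point coincides with the dipole position")
    return d @ dipole.moment / (4.0 * np.pi * sigma * d2 * np.sqrt(d2))


def _raw_inf_pots(vertices_m: np.ndarray, positions_m: np.ndarray) -> np.ndarray:
    """Unscaled source terms ``(r - r0)/|r - r0|^3`` for unit moments.

    Returns (n_vertices, n_sources, 3); the dot with a moment gives
    ``4 pi sigma`` times the infinite-medium potential.
    """
    d = vertices_m[:, None, :] - positions_m[None, :, :]
    d2 = np.einsum("vsi,vsi->vs", d, d)
    return d / (d2 * np.sqrt(d2))[:, :, None]


# ---------------------------------------------------------------------------
# Linear collocation coefficients (de Munck 1992)
# ---------------------------------------------------------------------------


def _lin_coeff_block(obs, tri_xyz, tri_nn, tri_area, skip_mask):
    """Linear-shape-function potential integrals for one obs x tri block.

    Parameters
    ----------
    obs : (p, 3) observation points
    tri_xyz : (m, 3, 3) triangle corners
    tri_nn : (m, 3) unit normals
    tri_area : (m,)
    skip_mask : (p, m) bool or None
        Pairs to zero (triangles incident to the observation vertex).

    Returns
    -------
    omega : (p, m, 3) solid-angle weight of each corner's shape function.
    """
    v1 = tri_xyz[None, :, 0, :] - obs[:, None, :]
    v2 = tri_xyz[None, :, 1, :] - obs[:, None, :]
    v3 = tri_xyz[None, :, 2, :] - obs[:, None, :]
    l1 = np.linalg.norm(v1, axis=-1)
    l2 = np.linalg.norm(v2, axis=-1)
    l3 = np.linalg.norm(v3, axis=-1)
    triple = np.einsum("pmi,pmi->pm", v1, np.cross(v2, v3))
    ss = (
        l1 * l2 * l3
        + np.einsum("pmi,pmi->pm", v1, v2) * l3
        + np.einsum("pmi,pmi->pm", v2, v3) * l1
        + np.einsum("pmi,pmi->pm", v1, v3) * l2
    )
    half_solid = np.arctan2(triple, ss)  # = solid angle / 2

    bad = np.abs(half_solid) < np.pi / 1e6
    for arr in (l1, l2, l3):
        arr[bad] = 1.0

    def beta(rk, lk, rk1, lk1):
        e = rk1 - rk
        le = np.linalg.norm(e, axis=-1)
        le = np.where(le == 0, 1.0, le)
        eh = e / le[..., None]
        num = lk + np.einsum("pmi,pmi->pm", rk, eh)
        den = lk1 + np.einsum("pmi,pmi->pm", rk1, eh)
        num = np.where(num <= 0, 1e-30, num)
        den = np.where(den <= 0, 1e-30, den)
        return np.log(num / den) / le

    b12 = beta(v1, l1, v2, l2)
    b23 = beta(v2, l2, v3, l3)
    b31 = beta(v3, l3, v1, l1)
    vec_omega = (
        (b31 - b12)[..., None] * v1
        + (b12 - b23)[..., None] * v2
        + (b23 - b31)[..., None] * v3
    )

    area2 = 2.0 * tri_area
    n2 = 1.0 / (area2 * area2)
    omega = np.empty(half_solid.shape + (3,))
    vs = (v1, v2, v3)
    for k in range(3):
        vk1 = vs[(k + 1) % 3]
        vk2 = vs[(k + 2) % 3]
        zdot = np.einsum("pmi,pmi->pm", np.cross(vk1, vk2), tri_nn[None, :, :])
        diff = vk2 - vk1
        omega[..., k] = -n2[None, :] * (
            area2[None, :] * zdot * 2.0 * half_solid
            - triple * np.einsum("pmi,pmi->pm", diff, vec_omega)
        )
    omega[bad] = 0.0
    if skip_mask is not None:
        omega[skip_mask] = 0.0
    return omega


def _surface_coeff(obs_surfaces, src_surface, self_index, chunk: int = 192):
    """Collocation column block of one source surface for stacked observers.

    ``self_index`` marks the observation surface identical to the source
    surface; its vertices skip their own incident triangles (the
    singular self terms are restored afterwards by the auto-element
    correction).
    """
    verts_s, faces_s = src_surface
    tri_xyz = verts_s[faces_s]
    e1 = tri_xyz[:, 1] - tri_xyz[:, 0]
    e2 = tri_xyz[:, 2] - tri_xyz[:, 0]
    nn = np.cross(e1, e2)
    area2 = np.linalg.norm(nn, axis=1)
    nn = nn / area2[:, None]
    area = 0.5 * area2

    n_rows = sum(len(v) for v, _ in obs_surfaces)
    block = np.zeros((n_rows, len(verts_s)))
    row0 = 0
    for si, (verts_o, _) in enumerate(obs_surfaces):
        for lo in range(0, len(verts_o), chunk):
            obs = verts_o[lo : lo + chunk]
            if si == self_index:
                idx = np.arange(lo, lo + len(obs))
                skip = (faces_s[None, :, :] == idx[:, None, None]).any(axis=2)
            else:
                skip = None
            om = _lin_coeff_block(obs, tri_xyz, nn, area, skip)
            sub = block[row0 + lo : row0 + lo + len(obs)]
            for k in range(3):
                np.subtract.at(sub, (slice(None), faces_s[:, k]), om[:, :, k])
        row0 += len(verts_o)
    return block


def _correct_auto_elements(block, faces, row0):
    """Self-block row-sum correction: each vertex row of the self block
    must total 2*pi; half of the missing angle goes to the vertex, the
    rest is split among its triangle-ring neighbours."""
    n = block.shape[1]
    sub = block[row0 : row0 + n, :]
    misses = 2.0 * np.pi - sub.sum(axis=1)
    flat = faces.ravel()
    order = np.argsort(flat, kind="stable")
    sorted_v = flat[order]
    starts = np.searchsorted(sorted_v, np.arange(n))
    ends = np.searchsorted(sorted_v, np.arange(n) + 1)
    for j in range(n):
        members = order[starts[j] : ends[j]]
        n_memb = len(members)
        if n_memb == 0:
            continue
        sub[j, j] += misses[j] / 2.0
        share = misses[j] / (4.0 * n_memb)
        for m in members:
            fi, corner = divmod(int(m), 3)
            sub[j, faces[fi, (corner + 1) % 3]] += share
            sub[j, faces[fi, (corner + 2) % 3]] += share


# ---------------------------------------------------------------------------
# System assembly
# ---------------------------------------------------------------------------


class BemSystem:
    """Factorized boundary operator for a head model.

    Holds the deflated collocation solution of the full surface stack
    and the isolated sub-problem pieces needed for IPA-corrected solves.
    """

    def __init__(self, model: HeadModel, touch_tol_mm: float = 0.1):
        from .head_carving import check_nesting

        nest = check_nesting(model, dmin=touch_tol_mm)
        if not nest["ok"]:
            raise ValueError(
                "surfaces touch or are not nested (run enforce_min_distance "
                "first): " + nest["summary"]
            )

        self.model = model
        self.surfaces_m = [(s.vertices * MM, s.faces) for s in model.surfaces]
        self.nps = [len(v) for v, _ in self.surfaces_m]
        self.offsets = np.concatenate([[0], np.cumsum(self.nps)])
        self.n_total = int(self.offsets[-1])
        sigma_in = np.asarray(model.conductivities, float)
        sigma_out = np.concatenate([[0.0], sigma_in[:-1]])
        self.sigma_in, self.sigma_out = sigma_in, sigma_out
        # gamma[i, j] = (sig_in(j) - sig_out(j)) / (sig_in(i) + sig_out(i))
        self.gamma = (sigma_in - sigma_out)[None, :] / (sigma_in + sigma_out)[:, None]
        # RHS scaling per surface: 2 / (4 pi (sig_in + sig_out))
        self.source_mult = 2.0 / (4.0 * np.pi * (sigma_in + sigma_out))

        coeff = self._assemble_coeff(self.surfaces_m)

        if len(self.nps) == 1:
            # homogeneous conductor: no inner layer to isolate
            A = self._system_matrix(coeff, self.gamma, self.nps)
            del coeff
            self._lu = sla.lu_factor(A, overwrite_a=True, check_finite=False)
            self.iso_index = None
            self.use_ipa_default = False
            return

        # isolate below the strongest outward conductivity drop (the skull)
        ratios = sigma_out[1:] / sigma_in[1:]
        t = int(np.argmin(ratios)) + 1
        self.iso_index = t
        self.use_ipa_default = bool(ratios[t - 1] <= 0.1)
        jlo = int(self.offsets[t])
        self.iso_slice = slice(jlo, self.n_total)

        A = self._system_matrix(coeff, self.gamma, self.nps)
        del coeff
        self._lu = sla.lu_factor(A, overwrite_a=True, check_finite=False)
        del A

        # isolated sub-problem: surfaces from t inward, sigma = 0 outside
        iso_sin = sigma_in[t:]
        iso_sout = np.concatenate([[0.0], iso_sin[:-1]])
        self.iso_gamma = (iso_sin - iso_sout)[None, :] / (iso_sin + iso_sout)[:, None]
        self.iso_source_mult = 2.0 / (4.0 * np.pi * (iso_sin + iso_sout))
        iso_coeff = self._assemble_coeff(self.surfaces_m[t:])
        A_iso = self._system_matrix(iso_coeff, self.iso_gamma, self.nps[t:])
        del iso_coeff
        self._iso_lu = sla.lu_factor(A_iso, overwrite_a=True, check_finite=False)
        del A_iso

        # IPA bookkeeping.  With mu = sigma_out/sigma_in at the isolation
        # surface, the corrected solution is  v = u + A v0  where v0 is the
        # isolated solution (zero outside), A = 1 on the isolation surface
        # and (1 - mu) on the surfaces inside it, and u solves the full
        # system with the residual source  mu*b - (2mu/(1+mu)) v0  on the
        # isolation rows.  The large isolated potential therefore never
        # passes through the discrete operator across the skull -- the
        # exterior representation identity replaces that term exactly --
        # which is what removes the conductivity-jump error.
        s_in_t, s_out_t = sigma_in[t], sigma_out[t]
        self.ip_mult = s_out_t / s_in_t
        a_diag = np.full(len(self.nps) - t, 1.0 - self.ip_mult)
        a_diag[0] = 1.0
        self._iso_scale = np.repeat(a_diag, self.nps[t:])
        self._iso_src_factor = -2.0 * self.ip_mult / (1.0 + self.ip_mult)

    # -- pieces -------------------------------------------------------------

    @staticmethod
    def _assemble_coeff(surfaces):
        nps = [len(v) for v, _ in surfaces]
        offsets = np.concatenate([[0], np.cumsum(nps)])
        cols = []
        for sj, src in enumerate(surfaces):
            block = _surface_coeff(surfaces, src, self_index=sj)
            _correct_auto_elements(block, src[1], int(offsets[sj]))
            cols.append(block)
        return np.hstack(cols)

    @staticmethod
    def _system_matrix(coeff, gamma, nps):
        n = coeff.shape[0]
        offsets = np.concatenate([[0], np.cumsum(nps)])
        A = np.empty((n, n))
        defl = 1.0 / n
        for i in range(len(nps)):
            for j in range(len(nps)):
                si = slice(int(offsets[i]), int(offsets[i + 1]))
                sj = slice(int(offsets[j]), int(offsets[j + 1]))
                A[si, sj] = defl - coeff[si, sj] * (gamma[i, j] / (2.0 * np.pi))
        A[np.diag_indices_from(A)] += 1.0
        return A

    # -- source terms -------------------------------------------------------

    def _check_dipole(self, dipole: Dipole):
        brain = self.model.brain
        if not points_inside(dipole.position[None], brain)[0]:
            raise ValueError("dipole position is outside the brain surface")
        from .mesh_core import _point_triangle_distance

        d, _, _ = _point_triangle_distance(dipole.position[None], brain.triangles)
        if d[0] < 1.0:
            warnings.warn(
                f"dipole within {d[0]:.2f} mm of the brain surface; "
                "BEM accuracy degrades near the boundary",
                RuntimeWarning,
                stacklevel=3,
            )

    def _rhs_raw(self, positions_mm: np.ndarray) -> np.ndarray:
        """(n_total, n_src, 3) unit-moment source terms on all vertices."""
        pos_m = np.atleast_2d(positions_mm) * MM
        parts = [_raw_inf_pots(verts, pos_m) for verts, _ in self.surfaces_m]
        return np.concatenate(parts, axis=0)

    # -- solves -------------------------------------------------------------

    def solve_raw(self, dipole: Dipole, use_ipa: bool = True) -> np.ndarray:
        """Boundary potentials (V) at every vertex of every surface."""
        self._check_dipole(dipole)
        raw = self._rhs_raw(dipole.position[None])[:, 0, :]
        s = raw @ dipole.moment
        mults = np.repeat(self.source_mult, self.nps)
        if not use_ipa or self.iso_index is None:
            return sla.lu_solve(self._lu, mults * s, check_finite=False)
        t = self.iso_index
        jlo = int(self.offsets[t])
        iso_mults = np.repeat(self.iso_source_mult, self.nps[t:])
        v0 = sla.lu_solve(self._iso_lu, iso_mults * s[jlo:], check_finite=False)
        b = self.ip_mult * (mults * s)
        b[jlo : jlo + self.nps[t]] += self._iso_src_factor * v0[: self.nps[t]]
        u = sla.lu_solve(self._lu, b, check_finite=False)
        u[jlo:] += self._iso_scale * v0
        return u

    def transfer_matrix(self, interp: np.ndarray, use_ipa: bool = True) -> np.ndarray:
        """Electrode transfer matrix W with ``phi = W @ raw_source_terms``.

        ``interp`` is (n_elec, n_total), typically barycentric weights on
        scalp vertices.  W folds in the solver (IPA or plain), deflation
        and all conductivity scalings, so the electrode potentials of any
        dipole reduce to one matrix product with the raw infinite-medium
        source terms of its position.
        """
        T = sla.lu_solve(self._lu, interp.T, trans=1, check_finite=False).T
        mults = np.repeat(self.source_mult, self.nps)
        if not use_ipa or self.iso_index is None:
            return T * mults[None, :]
        t = self.iso_index
        jlo = int(self.offsets[t])
        thi = int(self.offsets[t + 1])
        W = self.ip_mult * T * mults[None, :]
        # G maps the isolated solution v0 to electrode potentials: the
        # residual source on the isolation rows plus the direct A v0 term
        # wherever the interpolator touches isolated surfaces
        G = np.zeros((T.shape[0], self.n_total - jlo))
        G[:, : self.nps[t]] = self._iso_src_factor * T[:, jlo:thi]
        G += interp[:, jlo:] * self._iso_scale[None, :]
        iso_mults = np.repeat(self.iso_source_mult, self.nps[t:])
        GM = sla.lu_solve(self._iso_lu, G.T, trans=1, check_finite=False).T
        W[:, jlo:] += GM * iso_mults[None, :]
        return W


def assemble(model: HeadModel) -> BemSystem:
    """Assemble and factorize the boundary operator of a head model.

    Raises if surfaces touch (closer than 0.1 mm); run
    :func:`earshell.head_carving.enforce_min_distance` first.
    """
    return BemSystem(model)


def solve(system: BemSystem, dipole: Dipole, use_ipa: bool = True):
    """Boundary potentials for one dipole, as a list per surface (V)."""
    v = system.solve_raw(dipole, use_ipa=use_ipa)
    return [
        v[system.offsets[i] : system.offsets[i + 1]] for i in range(len(system.nps))
    ]


# ---------------------------------------------------------------------------
# Source grid
# ---------------------------------------------------------------------------


def build_source_grid(brain: TriMesh, spacing: float = 4.0, margin: float = 4.0) -> SourceGrid:
    """Cartesian lattice of candidate source locations inside the brain.

    Nodes lie on multiples of ``spacing`` (mm) in the head frame and are
    kept only when strictly inside the brain surface; nodes within
    ``margin`` of the surface are flagged ``near_boundary``.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    from .head_carving import signed_distance_grid

    lo = np.floor(brain.vertices.min(axis=0) / spacing - 1) * spacing
    hi = brain.vertices.max(axis=0) + spacing
    shape = tuple((np.ceil((hi - lo) / spacing).astype(int) + 1).tolist())
    sdf = signed_distance_grid(brain, lo, spacing, shape)
    inside = sdf < 0.0
    ijk = np.argwhere(inside)
    nodes = lo + spacing * ijk
    near = -sdf[inside] <= margin
    return SourceGrid(
        nodes=nodes,
        spacing=float(spacing),
        near_boundary=near,
        ijk=ijk,
        origin=lo,
        shape=shape,
    )


# ---------------------------------------------------------------------------
# Lead fields
# ---------------------------------------------------------------------------


@dataclass
class LeadFieldMatrix:
    """Electrode x source x orientation forward gains (V per A*m).

    ``reference`` is ``"raw"`` for the unreferenced BEM potential (an
    "infinite" reference), an electrode label for a common reference, or
    ``"average"``.
    """

    values: np.ndarray
    labels: list
    positions: np.ndarray
    grid: SourceGrid
    reference: str = "raw"

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        self.labels = list(self.labels)
        if self.values.shape != (len(self.labels), len(self.grid), 3):
            raise ValueError("lead field shape mismatch")
        self.positions = np.asarray(self.positions, float).reshape(len(self.labels), 3)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"electrode {label!r} not in lead field") from None

    def gain(self, node: int) -> np.ndarray:
        """(n_elec, 3) gain matrix of one source node."""
        return self.values[:, node, :]

    def potentials(self, node: int, moment) -> np.ndarray:
        return self.values[:, node, :] @ np.asarray(moment, float)

    def subset(self, labels) -> "LeadFieldMatrix":
        idx = [self.index(s) for s in labels]
        return LeadFieldMatrix(
            self.values[idx], [self.labels[i] for i in idx],
            self.positions[idx], self.grid, self.reference,
        )

    def save(self, path_prefix: str) -> None:
        """Write ``<prefix>.npy`` (values) and ``<prefix>.json`` sidecar."""
        np.save(path_prefix + ".npy", self.values)
        sidecar = {
            "labels": list(self.labels),
            "positions_mm": self.positions.tolist(),
            "reference": self.reference,
            "units": "V per A*m",
            "grid": {
                "spacing_mm": self.grid.spacing,
                "origin_mm": self.grid.origin.tolist(),
                "shape": list(self.grid.shape),
                "ijk": self.grid.ijk.tolist(),
                "near_boundary": self.grid.near_boundary.astype(int).tolist(),
            },
        }
        with open(path_prefix + ".json", "w") as fh:
            json.dump(sidecar, fh)

    @classmethod
    def load(cls, path_prefix: str) -> "LeadFieldMatrix":
        values = np.load(path_prefix + ".npy")
        with open(path_prefix + ".json") as fh:
            meta = json.load(fh)
        g = meta["grid"]
        ijk = np.asarray(g["ijk"], np.int64)
        origin = np.asarray(g["origin_mm"])
        grid = SourceGrid(
            nodes=origin + g["spacing_mm"] * ijk,
            spacing=g["spacing_mm"],
            near_boundary=np.asarray(g["near_boundary"], bool),
            ijk=ijk,
            origin=origin,
            shape=tuple(g["shape"]),
        )
        return cls(
            values, list(meta["labels"]), np.asarray(meta["positions_mm"]),
            grid, meta["reference"],
        )


def _electrode_interpolator(system: BemSystem, labels, positions_mm, max_dist=10.0):
    """Barycentric interpolation matrix from scalp vertices to electrodes."""
    scalp = system.model.scalp
    pos = np.atleast_2d(np.asarray(positions_mm, float))
    cp, d, fi = closest_point(scalp, pos)
    far = d > max_dist
    if far.any():
        bad = [labels[i] for i in np.where(far)[0]]
        raise ValueError(
            f"electrodes farther than {max_dist} mm from the scalp surface: {bad}"
        )
    tri = scalp.triangles[fi]
    ab = tri[:, 1] - tri[:, 0]
    ac = tri[:, 2] - tri[:, 0]
    ap = cp - tri[:, 0]
    d00 = np.einsum("ij,ij->i", ab, ab)
    d01 = np.einsum("ij,ij->i", ab, ac)
    d11 = np.einsum("ij,ij->i", ac, ac)
    d20 = np.einsum("ij,ij->i", ap, ab)
    d21 = np.einsum("ij,ij->i", ap, ac)
    den = d00 * d11 - d01 * d01
    v = (d11 * d20 - d01 * d21) / den
    w = (d00 * d21 - d01 * d20) / den
    u = 1.0 - v - w
    E = np.zeros((len(pos), system.n_total))
    faces = scalp.faces[fi]  # scalp is surface 0, so vertex ids need no offset
    rows = np.arange(len(pos))
    for k, coef in enumerate((u, v, w)):
        E[rows, faces[:, k]] += coef
    return E, cp


def compute_leadfield(
    system: BemSystem,
    grid: SourceGrid,
    labels,
    positions_mm,
    use_ipa: bool = True,
    chunk: int = 512,
) -> LeadFieldMatrix:
    """Lead field matrix for a set of electrodes on the scalp surface.

    Electrodes are snapped to the nearest scalp-surface point (error
    beyond 10 mm) and their potentials interpolated linearly over the
    containing triangle.  The three unit-moment solves per grid node are
    folded into one precomputed transfer matrix, so the cost is a single
    dense product per chunk of nodes.  The result is tagged ``raw``
    (infinite reference); see :func:`rereference`.
    """
    labels = list(labels)
    E, snapped = _electrode_interpolator(system, labels, positions_mm)
    W = system.transfer_matrix(E, use_ipa=use_ipa)
    n_src = len(grid)
    values = np.empty((len(labels), n_src, 3))
    for lo in range(0, n_src, chunk):
        raw = system._rhs_raw(grid.nodes[lo : lo + chunk])  # (n_total, c, 3)
        values[:, lo : lo + chunk, :] = np.einsum("en,nci->eci", W, raw)
    return LeadFieldMatrix(values, labels, snapped, grid, reference="raw")


def rereference(lfm: LeadFieldMatrix, mode: str) -> LeadFieldMatrix:
    """Re-reference a lead field to a common electrode or the average.

    ``mode`` is an electrode label or ``"average"``.  Differences between
    electrodes are invariant; a common-reference electrode's row becomes
    exactly zero.
    """
    vals = lfm.values
    if mode == "average":
        vals = vals - vals.mean(axis=0, keepdims=True)
    else:
        idx = lfm.index(mode)
        vals = vals - vals[idx : idx + 1]
    return LeadFieldMatrix(
        vals, list(lfm.labels), lfm.positions.copy(), lfm.grid, reference=mode
    )


# ---------------------------------------------------------------------------
# Forward-accuracy metrics
# ---------------------------------------------------------------------------


def rdm(v1, v2) -> float:
    """Relative difference measure between two potential topographies.

    Both vectors are average-referenced before normalization so the
    arbitrary potential constant does not enter the shape comparison.
    """
    a = np.asarray(v1, float)
    b = np.asarray(v2, float)
    a = a - a.mean()
    b = b - b.mean()
    return float(np.linalg.norm(a / np.linalg.norm(a) - b / np.linalg.norm(b)))


def mag(v1, v2) -> float:
    """Magnitude ratio ||v1|| / ||v2|| of average-referenced topographies."""
    a = np.asarray(v1, float)
    b = np.asarray(v2, float)
    a = a - a.mean()
    b = b - b.mean()
    return float(np.linalg.norm(a) / np.linalg.norm(b))
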