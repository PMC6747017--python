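"""Synthetic heads, electrode layouts and the analytic sphere oracle.

This module plays two roles.  First, it is the package's independent
oracle: :func:`analytic_sphere_potential` evaluates the Legendre-series
solution for a current dipole inside concentric isotropic shells, which
is the classical closed-form benchmark for BEM solvers.  Second, it
generates synthetic study material: four-shell sphere heads, an
ear-augmented head whose scalp carries parametric concha/ear-canal
concavities on both sides, electrode layouts (15 in-ear electrodes per
ear, 10 periauricular electrodes per ear, 128 scalp electrodes), and
multichannel recordings built as dipole sources projected through a
computed lead field plus noise, with the ground-truth mixing returned.

The ear carve is a revolved bowl-plus-cylinder solid.  It is not
anatomically faithful, but it reproduces the property the in-ear montage
exploits: electrodes in a concavity span a volume rather than a plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh as _trimesh

from .bem_forward import Dipole, LeadFieldMatrix
from .head_carving import (
    PAPER_CONDUCTIVITIES,
    HeadModel,
    carve_ears,
    enforce_min_distance,
)
from .mesh_core import FiducialSet, TriMesh, closest_point, remesh

__all__ = [
    "SphereSpec",
    "EarSpec",
    "ElectrodeLayout",
    "make_sphere_head",
    "make_ear_head",
    "make_ear_impression",
    "analytic_sphere_potential",
    "homogeneous_sphere_potential",
    "simulate_sources",
]

MM = 1e-3


@dataclass(frozen=True)
class SphereSpec:
    """Four concentric shells: radii ascending (brain, inner skull,
    outer skull, scalp) in mm; conductivities per compartment in the
    same ascending order (inside brain, CSF, skull, scalp) in S/m."""

    radii: tuple = (78.0, 80.0, 86.0, 92.0)
    conductivities: tuple = (
        PAPER_CONDUCTIVITIES[3],  # brain
        PAPER_CONDUCTIVITIES[2],  # CSF
        PAPER_CONDUCTIVITIES[1],  # skull
        PAPER_CONDUCTIVITIES[0],  # scalp
    )
    faces_per_shell: int = 2000

    def __post_init__(self):
        r = np.asarray(self.radii, float)
        if (np.diff(r) < 1.0).any():
            raise ValueError("shell radii must ascend with gaps >= 1 mm")
        if len(self.radii) != len(self.conductivities):
            raise ValueError("one conductivity per shell required")

    @property
    def head_conductivities(self) -> tuple:
        """Conductivities in HeadModel order (outermost compartment first)."""
        return tuple(self.conductivities[::-1])


@dataclass(frozen=True)
class EarSpec:
    """Parametric concha bowl + ear-canal carve and electrode counts."""

    concha_radius: float = 10.0
    concha_depth: float = 5.0
    canal_radius: float = 4.0
    canal_depth: float = 6.0
    in_ear_electrodes: int = 15
    periauricular_electrodes: int = 10
    scalp_electrodes: int = 128

    def __post_init__(self):
        for name in ("in_ear_electrodes", "periauricular_electrodes", "scalp_electrodes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def carve_depth(self) -> float:
        return self.concha_depth + self.canal_depth


@dataclass
class ElectrodeLayout:
    """Electrode positions split into the study's channel groups."""

    in_ear_left: FiducialSet
    in_ear_right: FiducialSet
    periauricular: FiducialSet
    scalp: FiducialSet

    @property
    def all(self) -> FiducialSet:
        labels, pts = [], []
        for fs in (self.in_ear_left, self.in_ear_right, self.periauricular, self.scalp):
            labels.extend(fs.labels)
            pts.append(fs.points)
        return FiducialSet(labels, np.vstack(pts))

    def groups(self) -> dict:
        return {
            "left_ear": list(self.in_ear_left.labels),
            "right_ear": list(self.in_ear_right.labels),
            "periauricular": list(self.periauricular.labels),
            "scalp": list(self.scalp.labels),
        }


# ---------------------------------------------------------------------------
# Sphere fixtures
# ---------------------------------------------------------------------------


def _icosphere(radius_mm: float, target_faces: int) -> TriMesh:
    sub = 0
    while 20 * 4 ** sub < target_faces:
        sub += 1
    m = _trimesh.creation.icosphere(subdivisions=sub, radius=radius_mm)
    mesh = TriMesh(np.asarray(m.vertices, float), np.asarray(m.faces, np.int64))
    if abs(mesh.n_faces - target_faces) > 0.1 * target_faces:
        mesh = remesh(mesh, target_faces)
        # decimation moves vertices slightly off the sphere; re-project so
        # the shell radius is exact
        r = np.linalg.norm(mesh.vertices, axis=1, keepdims=True)
        mesh.vertices *= radius_mm / r
    return mesh


def make_sphere_head(spec: SphereSpec) -> HeadModel:
    """Four nested icosphere shells with the study conductivities."""
    surfs = [
        _icosphere(r, spec.faces_per_shell) for r in spec.radii[::-1]
    ]  # outermost first
    model = HeadModel(surfs, spec.head_conductivities, min_distance=1.0)
    return model


# ---------------------------------------------------------------------------
# Ear-augmented head
# ---------------------------------------------------------------------------


def make_ear_impression(
    spec: EarSpec, scalp_radius: float, side: str, segments: int = 48
) -> TriMesh:
    """Revolved bowl-plus-cylinder solid emulating a scanned ear impression.

    The solid points along the ear axis (+X for the right ear, -X for
    the left), its tip ``concha_depth + canal_depth`` mm below the scalp
    surface and its outer end 6 mm proud of it.
    """
    rc, rk = spec.concha_radius, spec.canal_radius
    stub = 6.0
    # axial stations (a grows outward) and radii
    a_tip = 0.0
    a_canal = spec.canal_depth
    a_bowl = spec.canal_depth + spec.concha_depth
    a_end = a_bowl + stub
    n_prof = 40
    a = np.concatenate(
        [
            rk * (1 - np.cos(np.linspace(0, np.pi / 2, 8))) * 0.35,  # rounded tip
            np.linspace(rk * 0.35, a_canal, 8)[1:],
            np.linspace(a_canal, a_bowl, 12)[1:],
            np.linspace(a_bowl, a_end, 6)[1:],
        ]
    )
    r = np.empty_like(a)
    tipzone = a <= rk * 0.35
    r[tipzone] = rk * np.sqrt(1 - ((rk * 0.35 - a[tipzone]) / (rk * 0.35)) ** 2 * 0.99)
    canalzone = (a > rk * 0.35) & (a <= a_canal)
    r[canalzone] = rk
    trans = (a > a_canal) & (a <= a_bowl)
    tt = (a[trans] - a_canal) / (a_bowl - a_canal)
    r[trans] = rk + (rc - rk) * (3 * tt ** 2 - 2 * tt ** 3)  # smoothstep
    outer = a > a_bowl
    r[outer] = rc
    del n_prof

    theta = np.linspace(0, 2 * np.pi, segments, endpoint=False)
    ring = np.stack([np.cos(theta), np.sin(theta)], axis=1)
    verts = [np.array([[a_tip, 0.0, 0.0]])]
    for ai, ri in zip(a, r):
        verts.append(np.column_stack([np.full(segments, ai), ri * ring]))
    verts.append(np.array([[a_end, 0.0, 0.0]]))
    verts = np.vstack(verts)

    faces = []
    # tip fan (outward normals -> wind so that +a side is outside)
    for s in range(segments):
        faces.append([0, 1 + (s + 1) % segments, 1 + s])
    for j in range(len(a) - 1):
        base = 1 + j * segments
        for s in range(segments):
            s1 = (s + 1) % segments
            faces.append([base + s, base + s1, base + segments + s])
            faces.append([base + s1, base + segments + s1, base + segments + s])
    top = 1 + (len(a) - 1) * segments
    last = len(verts) - 1
    for s in range(segments):
        faces.append([last, top + s, top + (s + 1) % segments])
    mesh = TriMesh(verts, np.asarray(faces, np.int64))
    if mesh.volume < 0:
        mesh = TriMesh(mesh.vertices, mesh.faces[:, ::-1])
    mesh.validate("ear impression")

    # place: local +a axis along +X (right) or -X (left), tip below surface
    sign = +1.0 if side == "right" else -1.0
    out = mesh.copy()
    x_local = out.vertices[:, 0].copy()
    out.vertices[:, 0] = sign * (scalp_radius - spec.carve_depth + x_local)
    if side == "left":
        out = TriMesh(out.vertices, out.faces[:, ::-1], out.face_labels)
    return out


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit directions (golden-angle spiral)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1 + 5 ** 0.5) * i
    z = 1 - 2 * i / n
    s = np.sqrt(1 - z ** 2)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def _snap(surface: TriMesh, points: np.ndarray) -> np.ndarray:
    cp, _, _ = closest_point(surface, points)
    return cp


def _in_ear_positions(spec: EarSpec, scalp_radius: float, side: str, rng) -> np.ndarray:
    """Target in-ear electrode sites: rings in the canal and concha."""
    sign = +1.0 if side == "right" else -1.0
    x_tip = scalp_radius - spec.carve_depth
    sites = []
    n = spec.in_ear_electrodes
    # allocate ~half to the canal (two rings), the rest to the concha bowl
    n_canal = max(2, n // 2)
    n_concha = n - n_canal
    ring1 = n_canal // 2
    ring2 = n_canal - ring1
    for count, depth_frac in ((ring1, 0.25), (ring2, 0.75)):
        xa = x_tip + spec.canal_depth * depth_frac
        ang = np.linspace(0, 2 * np.pi, count, endpoint=False) + rng.uniform(0, np.pi)
        for t in ang:
            sites.append([xa, spec.canal_radius * np.cos(t), spec.canal_radius * np.sin(t)])
    xa = x_tip + spec.canal_depth + 0.6 * spec.concha_depth
    rr = 0.75 * spec.concha_radius
    ang = np.linspace(0, 2 * np.pi, n_concha, endpoint=False) + rng.uniform(0, np.pi)
    for t in ang:
        sites.append([xa, rr * np.cos(t), rr * np.sin(t)])
    sites = np.asarray(sites)
    sites[:, 0] *= sign
    return sites


def make_ear_head(
    sphere: SphereSpec | None = None,
    ears: EarSpec | None = None,
    seed: int = 0,
    carve_resolution: float = 2.0,
):
    """Ear-augmented four-shell head with the full electrode montage.

    Carves a parametric concha/canal solid into both sides of the scalp
    shell, re-enforces the 1 mm inter-surface distance, and returns
    ``(HeadModel, ElectrodeLayout)``.  All randomness (electrode jitter,
    ring phases) flows from ``seed``; the same seed reproduces identical
    electrode positions.
    """
    sphere = sphere or SphereSpec()
    ears = ears or EarSpec()
    rng = np.random.default_rng(seed)
    scalp_r = sphere.radii[-1]
    skull_gap = sphere.radii[-1] - sphere.radii[-2]
    if ears.carve_depth >= scalp_r - sphere.radii[0] + 10.0:
        raise ValueError("carve depth infeasible for this sphere spec")
    del skull_gap

    model = make_sphere_head(sphere)
    imp_r = make_ear_impression(ears, scalp_r, "right")
    imp_l = make_ear_impression(ears, scalp_r, "left")
    carved = carve_ears(model.scalp, [imp_l, imp_r], resolution=carve_resolution)
    model = HeadModel(
        [carved] + model.surfaces[1:], model.conductivities, model.min_distance
    )
    model = enforce_min_distance(model, 1.0)

    scalp = model.scalp
    jitter = lambda pts: pts + rng.normal(0, 0.3, pts.shape)  # noqa: E731

    pos_r = _snap(scalp, jitter(_in_ear_positions(ears, scalp_r, "right", rng)))
    pos_l = _snap(scalp, jitter(_in_ear_positions(ears, scalp_r, "left", rng)))
    in_r = FiducialSet([f"ER{i + 1:02d}" for i in range(len(pos_r))], pos_r)
    in_l = FiducialSet([f"EL{i + 1:02d}" for i in range(len(pos_l))], pos_l)

    # periauricular rings (cEEGrid-like C shapes around each carve)
    peri_labels, peri_pts = [], []
    ring_angle = np.arcsin((ears.concha_radius + 8.0) / scalp_r)
    for side, sgn, tag in (("left", -1.0, "cEL"), ("right", +1.0, "cER")):
        ang = np.linspace(0, 2 * np.pi, ears.periauricular_electrodes, endpoint=False)
        ang = ang + rng.uniform(0, np.pi / 8)
        axis_x = sgn * np.cos(ring_angle) * scalp_r
        rr = np.sin(ring_angle) * scalp_r
        pts = np.column_stack(
            [np.full_like(ang, axis_x), rr * np.cos(ang), rr * np.sin(ang)]
        )
        pts = _snap(scalp, jitter(pts))
        peri_pts.append(pts)
        peri_labels.extend(f"{tag}{i + 1:02d}" for i in range(len(ang)))
    peri = FiducialSet(peri_labels, np.vstack(peri_pts))

    # quasi-uniform scalp cap, avoiding the ear regions and the "neck"
    cand = _fibonacci_sphere(ears.scalp_electrodes * 3) * scalp_r
    keep = cand[:, 2] > -0.35 * scalp_r
    for sgn in (-1.0, 1.0):
        axis = np.array([sgn * scalp_r, 0.0, 0.0])
        keep &= np.linalg.norm(cand - axis, axis=1) > (ears.concha_radius + 12.0)
    cand = cand[keep]
    if len(cand) < ears.scalp_electrodes:
        raise ValueError("not enough admissible scalp sites")
    pick = np.linspace(0, len(cand) - 1, ears.scalp_electrodes).astype(int)
    scalp_pts = _snap(scalp, jitter(cand[pick]))
    cap = FiducialSet(
        [f"S{i + 1:03d}" for i in range(ears.scalp_electrodes)], scalp_pts
    )

    layout = ElectrodeLayout(in_l, in_r, peri, cap)
    return model, layout


# ---------------------------------------------------------------------------
# Analytic concentric-shell potentials (the BEM oracle)
# ---------------------------------------------------------------------------


def _legendre_tables(x: np.ndarray, nmax: int):
    """P_n(x) and P_n^1(x) for n = 0..nmax, shapes (nmax+1, len(x)).

    Uses the standard three-term recurrences; P_n^1 follows the
    Condon-Shortley convention (P_1^1 = -sqrt(1-x^2)), matching
    ``scipy.special.lpmv``.
    """
    x = np.asarray(x, float)
    P = np.empty((nmax + 1, len(x)))
    P1 = np.zeros((nmax + 1, len(x)))
    P[0] = 1.0
    if nmax >= 1:
        P[1] = x
        s = np.sqrt(np.clip(1.0 - x * x, 0.0, None))
        P1[1] = -s
    for n in range(1, nmax):
        P[n + 1] = ((2 * n + 1) * x * P[n] - n * P[n - 1]) / (n + 1)
        P1[n + 1] = ((2 * n + 1) * x * P1[n] - (n + 1) * P1[n - 1]) / n
    return P, P1


def _shell_coefficients(radii_m, sigmas, b_m, q_r, q_t, nmax):
    """Per-degree outer-layer coefficients (a_L, b_L) for both families.

    Solves, for every degree n, the small linear system expressing
    potential and radial-current continuity at each interface plus the
    zero-current condition at the outer boundary, with per-layer scaled
    basis functions for conditioning.  Returns two (nmax+1, 2) arrays
    (radial family, tangential family) of the outermost-layer
    coefficients, plus the source coefficients.
    """
    R = np.asarray(radii_m, float)
    sig = np.asarray(sigmas, float)
    L = len(R)
    n_unk = 2 * L - 1  # a_1, (a_j, b_j) j=2..L

    out_rad = np.zeros((nmax + 1, 2))
    out_tan = np.zeros((nmax + 1, 2))
    beta1 = b_m / R[0]
    for n in range(1, nmax + 1):
        # source coefficients: V_src = S * (R_1/r)^(n+1) * angular
        common = beta1 ** (n - 1) / (4.0 * np.pi * sig[0] * R[0] ** 2)
        S_rad = q_r * n * common
        S_tan = -q_t * common

        A = np.zeros((n_unk, n_unk))
        rhs = np.zeros((n_unk, 2))

        def a_col(j):  # unknown index of a_j (layer j, 1-based)
            return 0 if j == 1 else 2 * j - 3

        def b_col(j):
            return 2 * j - 2

        row = 0
        for j in range(1, L):  # interface at R_j between layers j, j+1
            Rj = R[j - 1]
            # potential continuity
            A[row, a_col(j)] = 1.0  # (R_j / R_j)^n
            if j > 1:
                A[row, b_col(j)] = (R[j - 2] / Rj) ** (n + 1)
            A[row, a_col(j + 1)] = -((Rj / R[j]) ** n)
            A[row, b_col(j + 1)] = -1.0
            if j == 1:
                rhs[row, 0] -= S_rad
                rhs[row, 1] -= S_tan
            row += 1
            # radial current continuity (times R_j)
            A[row, a_col(j)] = sig[j - 1] * n
            if j > 1:
                A[row, b_col(j)] = -sig[j - 1] * (n + 1) * (R[j - 2] / Rj) ** (n + 1)
            A[row, a_col(j + 1)] = -sig[j] * n * (Rj / R[j]) ** n
            A[row, b_col(j + 1)] = sig[j] * (n + 1)
            if j == 1:
                rhs[row, 0] += sig[0] * (n + 1) * S_rad
                rhs[row, 1] += sig[0] * (n + 1) * S_tan
            row += 1
        # outer boundary: zero radial current at R_L
        A[row, a_col(L)] = n
        if L > 1:
            A[row, b_col(L)] = -(n + 1) * (R[L - 2] / R[L - 1]) ** (n + 1)
        else:
            rhs[row, 0] += (n + 1) * S_rad
            rhs[row, 1] += (n + 1) * S_tan

        sol = np.linalg.solve(A, rhs)
        if L > 1:
            out_rad[n] = (sol[a_col(L), 0], sol[b_col(L), 0])
            out_tan[n] = (sol[a_col(L), 1], sol[b_col(L), 1])
        else:
            out_rad[n] = (sol[0, 0], 0.0)
            out_tan[n] = (sol[0, 1], 0.0)
    return out_rad, out_tan, (S_rad, S_tan)


def analytic_sphere_potential(
    dipole: Dipole, surface_points, spec: SphereSpec, max_degree: int = 100
) -> np.ndarray:
    """Series solution for a dipole in concentric isotropic shells.

    Evaluates the Legendre expansion of the surface potential (V) at
    points in the outermost compartment (typically on the scalp shell).
    ``max_degree`` terms are summed; at source eccentricities up to 0.8
    the default 100 terms converge far beyond the accuracy of any mesh
    discretization.
    """
    radii_m = np.asarray(spec.radii, float) * MM
    sig = np.asarray(spec.conductivities, float)
    pos_m = dipole.position * MM
    b = float(np.linalg.norm(pos_m))
    if b >= radii_m[0]:
        raise ValueError("dipole eccentricity >= 1 (outside the innermost shell)")
    pts_m = np.atleast_2d(np.asarray(surface_points, float)) * MM

    # local frame: z along the dipole position, x along the tangential moment
    if b > 1e-12:
        ez = pos_m / b
    else:
        ez = np.array([0.0, 0.0, 1.0])
    q = dipole.moment
    q_r = float(q @ ez)
    qt_vec = q - q_r * ez
    q_t = float(np.linalg.norm(qt_vec))
    if q_t > 1e-300:
        ex = qt_vec / q_t
    else:
        ex = np.array([1.0, 0.0, 0.0])
        if abs(ez @ ex) > 0.9:
            ex = np.array([0.0, 1.0, 0.0])
        ex = ex - (ez @ ex) * ez
        ex /= np.linalg.norm(ex)
    ey = np.cross(ez, ex)

    r_obs = np.linalg.norm(pts_m, axis=1)
    u = np.clip(pts_m @ ez / r_obs, -1.0, 1.0)
    cphi = pts_m @ ex
    sphi = pts_m @ ey
    norm = np.hypot(cphi, sphi)
    cosphi = np.where(norm > 0, cphi / np.where(norm == 0, 1, norm), 1.0)

    out_rad, out_tan, _ = _shell_coefficients(
        radii_m, sig, b, q_r, q_t, max_degree
    )
    P, P1 = _legendre_tables(u, max_degree)

    RL = radii_m[-1]
    Rin = radii_m[-2] if len(radii_m) > 1 else b if b > 0 else RL
    n_arr = np.arange(max_degree + 1)
    with np.errstate(divide="ignore"):
        grow = (r_obs[None, :] / RL) ** n_arr[:, None]
        decay = (Rin / r_obs[None, :]) ** (n_arr[:, None] + 1)
    if len(radii_m) == 1:
        # single shell: the b-coefficient column is the source itself
        beta1 = b / radii_m[0]
        src = np.zeros((max_degree + 1, 2))
        common = beta1 ** (n_arr[1:] - 1) / (4.0 * np.pi * sig[0] * radii_m[0] ** 2)
        src_rad = q_r * n_arr[1:] * common
        src_tan = -q_t * common
        decay_src = (radii_m[0] / r_obs[None, :]) ** (n_arr[:, None] + 1)
        v = (
            (out_rad[:, 0:1] * grow)[1:] * P[1:]
            + src_rad[:, None] * decay_src[1:] * P[1:]
            + ((out_tan[:, 0:1] * grow)[1:] * P1[1:]) * cosphi[None, :]
            + (src_tan[:, None] * decay_src[1:] * P1[1:]) * cosphi[None, :]
        ).sum(axis=0)
        return v

    v = (
        (out_rad[:, 0:1] * grow + out_rad[:, 1:2] * decay)[1:] * P[1:]
    ).sum(axis=0)
    v += (
        ((out_tan[:, 0:1] * grow + out_tan[:, 1:2] * decay)[1:] * P1[1:]).sum(axis=0)
        * cosphi
    )
    return v


def homogeneous_sphere_potential(dipole: Dipole, surface_points, radius_mm, sigma):
    """Closed-form surface potential of a dipole in a homogeneous sphere.

    Generating-function summation of the classical series (the
    Wilson-Bayley / Frank solution); independent of the per-degree
    linear solves used by :func:`analytic_sphere_potential`, so the two
    cross-check each other in the single-shell limit.
    """
    R = float(radius_mm) * MM
    pos_m = dipole.position * MM
    b = float(np.linalg.norm(pos_m))
    if b >= R:
        raise ValueError("dipole outside the sphere")
    pts_m = np.atleast_2d(np.asarray(surface_points, float)) * MM
    # evaluate on the surface radius (the closed form assumes |r| = R)
    pts_m = pts_m * (R / np.linalg.norm(pts_m, axis=1))[:, None]

    if b > 1e-12:
        ez = pos_m / b
    else:
        ez = np.array([0.0, 0.0, 1.0])
        b = 1e-12
    q = dipole.moment
    q_r = float(q @ ez)
    qt_vec = q - q_r * ez
    q_t = float(np.linalg.norm(qt_vec))
    ex = qt_vec / q_t if q_t > 1e-300 else np.array([1.0, 0.0, 0.0])
    if q_t <= 1e-300:
        if abs(ez @ ex) > 0.9:
            ex = np.array([0.0, 1.0, 0.0])
        ex = ex - (ez @ ex) * ez
        ex /= np.linalg.norm(ex)
    ey = np.cross(ez, ex)

    u = np.clip(pts_m @ ez / R, -1.0, 1.0)
    cphi = pts_m @ ex
    sphi = pts_m @ ey
    norm = np.hypot(cphi, sphi)
    cosphi = np.where(norm > 0, cphi / np.where(norm == 0, 1, norm), 1.0)
    s = np.sqrt(np.clip(1 - u * u, 0.0, None))

    x = b / R
    F = 1.0 / np.sqrt(1.0 - 2.0 * x * u + x * x)
    radial_sum = 2.0 * (u - x) * F ** 3 + (F - 1.0) / x
    G = ((x - u) * F + u) / np.where(s > 0, 1.0 - u * u, 1.0)
    tang_sum = np.where(s > 0, s * (2.0 * F ** 3 + G / x), 0.0)
    return (q_r * radial_sum + q_t * cosphi * tang_sum) / (
        4.0 * np.pi * sigma * R ** 2
    )


# ---------------------------------------------------------------------------
# Synthetic recordings with ground-truth mixing
# ---------------------------------------------------------------------------


def simulate_sources(
    lfm: LeadFieldMatrix,
    sources,
    noise_sd: float,
    duration: float,
    rate: float,
    seed: int = 0,
    trigger_hz: float | None = None,
):
    """Project dipole sources through a lead field into a noisy recording.

    Parameters
    ----------
    sources : list of (node_index, moment, timecourse)
        ``node_index`` picks a source-grid node of ``lfm``; ``moment``
        is the dipole orientation/amplitude in A*m; ``timecourse`` is
        either an array of ``round(duration*rate)`` samples (unitless
        modulation) or a dict like ``{"sine": f_hz}``.
    noise_sd : float
        White sensor noise standard deviation (V).
    trigger_hz : float, optional
        Adds a synthetic trigger track at this rate.

    Returns
    -------
    recording : :class:`earshell.inverse_eval.Recording`
    mixing : :class:`earshell.inverse_eval.MixingModel`
        Ground truth: column m of the inverse mixing matrix is the
        lead-field projection of source m.
    """
    from .inverse_eval import MixingModel, Recording

    if duration <= 0 or rate <= 0:
        raise ValueError("duration and rate must be positive")
    rng = np.random.default_rng(seed)
    n_samp = int(round(duration * rate))
    t = np.arange(n_samp) / rate

    cols = []
    timecourses = []
    for node, moment, tc in sources:
        gain = lfm.values[:, int(node), :] @ np.asarray(moment, float)
        if isinstance(tc, dict):
            if "sine" in tc:
                u = np.sin(2 * np.pi * tc["sine"] * t + tc.get("phase", 0.0))
            else:
                raise ValueError(f"unknown timecourse spec {tc}")
        else:
            u = np.asarray(tc, float)
            if len(u) != n_samp:
                raise ValueError("timecourse length mismatch")
        cols.append(gain)
        timecourses.append(u)
    W_inv = np.column_stack(cols) if cols else np.zeros((len(lfm.labels), 0))
    U = np.vstack(timecourses) if timecourses else np.zeros((0, n_samp))

    data = W_inv @ U + rng.normal(0.0, noise_sd, (len(lfm.labels), n_samp))
    triggers = np.array([], np.int64)
    if trigger_hz:
        triggers = np.arange(0, n_samp, int(round(rate / trigger_hz)))
    rec = Recording(
        data=data, rate=float(rate), labels=list(lfm.labels), triggers=triggers
    )
    mix = MixingModel(inverse_mixing=W_inv, timecourses=U, labels=list(lfm.labels))
    return rec, mix
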