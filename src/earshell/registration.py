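"""Rigid alignment of digitized points, ear impressions and earpiece CAD frames.

The registration chain mirrors the head-model construction workflow:

1. earpiece fiducials P1-P5 are defined in the earpiece CAD frame,
2. anatomical landmarks (nasion, left/right pre-auricular) align the
   digitizer frame to the head-model frame,
3. the digitized P1-P5 positions then carry each ear-impression mesh and
   its electrode positions into the head frame by a least-squares rigid
   fit.

Correspondence is always known (labeled fiducials), so the closed-form
Kabsch solution is used; there is no scaling term and no ICP refinement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .mesh_core import FiducialSet, TriMesh

__all__ = [
    "RigidTransform",
    "DegenerateConfigurationError",
    "fit_rigid",
    "align_head_coordinates",
    "place_earpiece",
]

EARPIECE_FIDUCIAL_LABELS = ("P1", "P2", "P3", "P4", "P5")
ANATOMICAL_LANDMARKS = ("nasion", "lpa", "rpa")


class DegenerateConfigurationError(ValueError):
    """Point configuration does not determine a unique rigid transform."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform ``x -> R @ x + t`` (rotation + translation, mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, float).reshape(3, 3)
        t = np.asarray(self.translation, float).reshape(3)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation has determinant -1 (reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, float)
        return pts @ self.rotation.T + self.translation

    def apply_mesh(self, mesh: TriMesh) -> TriMesh:
        out = mesh.copy()
        out.vertices = self.apply(out.vertices)
        return out

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m


def _as_matched_points(source, target):
    if isinstance(source, FiducialSet) and isinstance(target, FiducialSet):
        common = [s for s in source.labels if s in target]
        if len(common) < 3:
            raise DegenerateConfigurationError(
                f"need >= 3 shared labels, found {len(common)}"
            )
        return (
            np.array([source[s] for s in common]),
            np.array([target[s] for s in common]),
        )
    src = np.atleast_2d(np.asarray(source, float))
    tgt = np.atleast_2d(np.asarray(target, float))
    if src.shape != tgt.shape:
        raise ValueError("source and target point arrays differ in shape")
    return src, tgt


def fit_rigid(source, target) -> tuple[RigidTransform, float]:
    """Least-squares rigid transform mapping ``source`` onto ``target``.

    Closed-form Kabsch solution: SVD of the cross-covariance of the
    centred point sets, with the determinant sign corrected so the result
    is a proper rotation (no reflection, no scaling).

    Parameters
    ----------
    source, target : (n, 3) arrays or FiducialSet
        Corresponding points (matched by row, or by label for
        FiducialSets); ``n >= 3`` and non-collinear.

    Returns
    -------
    transform : RigidTransform
    rmse : float
        Root-mean-square residual of the fitted points in mm.
    """
    src, tgt = _as_matched_points(source, target)
    if len(src) < 3:
        raise DegenerateConfigurationError("need at least 3 point pairs")
    c_src = src.mean(axis=0)
    c_tgt = tgt.mean(axis=0)
    a = src - c_src
    b = tgt - c_tgt
    # collinearity: second singular value of the centred cloud ~ 0
    s_src = np.linalg.svd(a, compute_uv=False)
    if s_src[1] < 1e-9 * max(s_src[0], 1.0):
        raise DegenerateConfigurationError("source points are (near-)collinear")
    H = a.T @ b
    U, _, Vt = np.linalg.svd(H)
    d = np.linalg.det(Vt.T @ U.T)
    if d < 0:
        warnings.warn(
            "optimal orthogonal map is a reflection; corrected to a proper "
            "rotation (check fiducial labels for left/right swaps)",
            RuntimeWarning,
            stacklevel=2,
        )
    D = np.diag([1.0, 1.0, np.sign(d)])
    R = Vt.T @ D @ U.T
    t = c_tgt - R @ c_src
    tf = RigidTransform(R, t)
    resid = tf.apply(src) - tgt
    rmse = float(np.sqrt((resid ** 2).sum(axis=1).mean()))
    return tf, rmse


def align_head_coordinates(
    digitized_landmarks: FiducialSet, mesh_landmarks: FiducialSet
) -> RigidTransform:
    """Map the digitizer frame into the head-model frame.

    Uses the three anatomical landmarks (``nasion``, ``lpa``, ``rpa``).
    A left/right pre-auricular swap produces mirror geometry; it is
    detected through the reflection check of :func:`fit_rigid` and raised
    as an error rather than silently corrected.
    """
    for lab in ANATOMICAL_LANDMARKS:
        if lab not in digitized_landmarks:
            raise KeyError(f"digitized landmarks missing {lab!r}")
        if lab not in mesh_landmarks:
            raise KeyError(f"mesh landmarks missing {lab!r}")
    src = digitized_landmarks.subset(ANATOMICAL_LANDMARKS)
    tgt = mesh_landmarks.subset(ANATOMICAL_LANDMARKS)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        tf, rmse = fit_rigid(src, tgt)
    if any("reflection" in str(w.message) for w in caught):
        raise DegenerateConfigurationError(
            "landmark sets are mirror images of each other; left and right "
            "pre-auricular labels are probably swapped"
        )
    del rmse
    return tf


def place_earpiece(
    impression_mesh: TriMesh,
    model_fiducials: FiducialSet,
    digitized_fiducials: FiducialSet,
    electrode_positions_cad: FiducialSet | None = None,
    coplanar_tol_mm: float = 1.0,
):
    """Carry an ear-impression mesh and its electrodes into the head frame.

    Parameters
    ----------
    impression_mesh : TriMesh
        3D-scanned ear impression in the earpiece CAD frame.
    model_fiducials : FiducialSet
        P1-P5 in the CAD frame.
    digitized_fiducials : FiducialSet
        The same five fiducials digitized with the earpiece in the ear,
        already expressed in the head frame.
    electrode_positions_cad : FiducialSet, optional
        Electrode positions from the earpiece CAD model.

    Returns
    -------
    mesh : TriMesh in head frame
    electrodes : FiducialSet in head frame (or None)
    rmse : float, fiducial fit residual in mm
    """
    for lab in EARPIECE_FIDUCIAL_LABELS:
        if lab not in model_fiducials or lab not in digitized_fiducials:
            raise KeyError(f"earpiece fiducial {lab!r} missing")
    cad = model_fiducials.subset(EARPIECE_FIDUCIAL_LABELS)
    if not cad.spans_volume(tol_mm=coplanar_tol_mm / 10.0):
        warnings.warn(
            "P1-P5 nearly coplanar: rotation about the plane normal is "
            "ill-constrained",
            RuntimeWarning,
            stacklevel=2,
        )
    dig = digitized_fiducials.subset(EARPIECE_FIDUCIAL_LABELS)
    tf, rmse = fit_rigid(cad, dig)
    mesh = tf.apply_mesh(impression_mesh)
    electrodes = None
    if electrode_positions_cad is not None:
        electrodes = electrode_positions_cad.transformed(tf)
    return mesh, electrodes, rmse
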