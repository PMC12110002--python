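"""Starting transforms: geometric centering and landmark-based rigid fit.

Intensity-based refinement of a cone-beam CT / MRI pair only converges from
a good start because the two modalities share little anatomy. Two
initializers are provided: a centered initializer that superimposes the two
volume centers (identity rotation), and a closed-form least-squares rigid
fit to corresponding landmarks (Kabsch/Horn), which is the clinical-protocol
path — paired points on structures visible in both modalities, such as the
semicircular canals.
"""

from __future__ import annotations

import numpy as np

from .errors import (
    DegenerateConfigurationError,
    InsufficientLandmarksError,
    PairingError,
)
from .landmarks import LandmarkSet, check_label_correspondence
from .transforms import RigidTransform
from .volume import Volume3D

__all__ = ["centered_initializer", "landmark_rigid_fit"]


def centered_initializer(fixed: Volume3D, moving: Volume3D) -> RigidTransform:
    """Identity-rotation transform mapping the fixed FOV center onto the moving one.

    The rotation center is the fixed grid's physical centroid, so subsequent
    rotation parameters act about the anatomy rather than the world origin.
    """
    fixed_center = fixed.physical_center()
    moving_center = moving.physical_center()
    return RigidTransform(
        translation=moving_center - fixed_center,
        center=fixed_center,
    )


def landmark_rigid_fit(fixed_pts: LandmarkSet, moving_pts: LandmarkSet) -> RigidTransform:
    """Least-squares rigid fit mapping fixed landmarks onto moving landmarks.

    Solves ``argmin_T sum_i ||T(fixed_i) - moving_i||^2`` in closed form via
    SVD of the cross-covariance (Kabsch), with the reflection guard that
    forces a proper rotation (det R = +1). Correspondence is by order;
    mismatched label names only raise a warning. The returned transform's
    center is the fixed-point centroid.

    Raises
    ------
    PairingError
        If the two sets have different sizes.
    InsufficientLandmarksError
        If fewer than 3 pairs are supplied.
    DegenerateConfigurationError
        If the fixed points are collinear within tolerance (the rotation
        about the line is then unobservable).
    """
    fixed_pts = fixed_pts.to_lps()
    moving_pts = moving_pts.to_lps()
    if len(fixed_pts) != len(moving_pts):
        raise PairingError(
            f"cannot pair {len(fixed_pts)} fixed with {len(moving_pts)} moving landmarks"
        )
    if len(fixed_pts) < 3:
        raise InsufficientLandmarksError(
            f"rigid fit requires at least 3 landmark pairs, got {len(fixed_pts)}"
        )
    check_label_correspondence(fixed_pts, moving_pts)

    f = fixed_pts.points
    m = moving_pts.points
    f_centroid = f.mean(axis=0)
    m_centroid = m.mean(axis=0)
    fc = f - f_centroid
    mc = m - m_centroid

    # Collinear fixed points leave rotation about their common line free.
    sv = np.linalg.svd(fc, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1e-300):
        raise DegenerateConfigurationError(
            "landmarks are collinear within tolerance; rigid fit is not unique"
        )

    h = fc.T @ mc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T

    # With center at the fixed centroid, R(f_i - c) + c + t ~ m_i gives
    # t = m_centroid - f_centroid exactly.
    return RigidTransform.from_matrix_parts(
        rotation=r,
        offset=m_centroid - r @ f_centroid,
        center=f_centroid,
    )
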