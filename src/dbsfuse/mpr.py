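"""Oblique multiplanar reformation (MPR) along an electrode axis.

A directional electrode's segmented contacts are only interpretable in
views oriented by the electrode itself. Given two contact coordinates the
axis is formed, and slices are extracted either in a plane *containing* the
axis (long-axis view of the lead) or *orthogonal* to it (contact
cross-sections), then fused with the soft-tissue volume by window/level
mapping and alpha blending.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateAxisError, InvalidParameterError
from .transforms import RigidTransform
from .volume import Volume3D, sample_trilinear

__all__ = ["SlicePlane", "electrode_axis", "make_plane", "extract_slice", "fused_mpr"]

_Z = np.array([0.0, 0.0, 1.0])
_X = np.array([1.0, 0.0, 0.0])


@dataclass(frozen=True)
class SlicePlane:
    """An oriented, bounded sampling plane in physical LPS space.

    ``in_plane_u``/``in_plane_v`` and ``normal`` form a right-handed
    orthonormal triad; ``extent`` (mm) and ``spacing`` (mm/px) define the
    raster.
    """

    center: np.ndarray
    normal: np.ndarray
    in_plane_u: np.ndarray
    in_plane_v: np.ndarray
    extent: np.ndarray
    spacing: np.ndarray

    def __post_init__(self) -> None:
        for name in ("center", "normal", "in_plane_u", "in_plane_v"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float).reshape(3))
        for name in ("extent", "spacing"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float).reshape(2))
        triad = np.stack([self.in_plane_u, self.in_plane_v, self.normal])
        if not np.allclose(triad @ triad.T, np.eye(3), atol=1e-9):
            raise InvalidParameterError("plane triad is not orthonormal")
        if np.linalg.det(triad) < 0:
            raise InvalidParameterError("plane triad must be right-handed")
        if not (np.all(self.extent > 0) and np.all(self.spacing > 0)):
            raise InvalidParameterError("extent and spacing must be positive")

    @property
    def n_pixels(self) -> tuple[int, int]:
        n = np.floor(self.extent / self.spacing).astype(int) + 1
        return int(n[0]), int(n[1])

    def pixel_positions(self) -> np.ndarray:
        """Physical LPS positions (nu, nv, 3) of every pixel center (exact affine)."""
        nu, nv = self.n_pixels
        iu = np.arange(nu, dtype=float) * self.spacing[0] - self.extent[0] / 2.0
        iv = np.arange(nv, dtype=float) * self.spacing[1] - self.extent[1] / 2.0
        return (
            self.center[None, None, :]
            + iu[:, None, None] * self.in_plane_u[None, None, :]
            + iv[None, :, None] * self.in_plane_v[None, None, :]
        )

    def pixel_map(self) -> dict:
        """JSON-serializable pixel->mm affine description."""
        return {
            "origin_mm": list(self.center - (self.extent[0] / 2) * self.in_plane_u
                              - (self.extent[1] / 2) * self.in_plane_v),
            "u_axis": list(self.in_plane_u),
            "v_axis": list(self.in_plane_v),
            "normal": list(self.normal),
            "spacing_mm": list(self.spacing),
            "n_pixels": list(self.n_pixels),
            "frame": "LPS",
        }


def electrode_axis(p_distal, p_proximal) -> np.ndarray:
    """Unit vector from the distal to the proximal electrode contact."""
    delta = np.asarray(p_proximal, dtype=float) - np.asarray(p_distal, dtype=float)
    norm = float(np.linalg.norm(delta))
    if norm <= 1e-6:
        raise DegenerateAxisError("electrode contact points coincide; axis undefined")
    return delta / norm


def make_plane(axis, center, extent=(60.0, 60.0), spacing=(0.5, 0.5)) -> SlicePlane:
    """Right-handed orthonormal plane whose normal is ``axis``.

    The in-plane basis is ``u = normalize(axis x z)`` with an x-axis fallback
    when the axis is within ~2.5 degrees of z, then ``v = normal x u``; the
    tie-break is deterministic so repeated runs produce identical rasters.
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    ref = _X if abs(float(axis @ _Z)) > 0.999 else _Z
    u = np.cross(axis, ref)
    u = u / np.linalg.norm(u)
    v = np.cross(axis, u)
    return SlicePlane(
        center=center, normal=axis, in_plane_u=u, in_plane_v=v,
        extent=extent, spacing=spacing,
    )


def make_electrode_plane(
    p_distal, p_proximal, mode: str = "inplane",
    extent=(60.0, 60.0), spacing=(0.5, 0.5), center=None,
) -> SlicePlane:
    """Electrode-oriented plane: long-axis view or contact cross-section.

    ``inplane`` builds a plane *containing* the electrode axis (the axis
    becomes the in-plane v direction), centered on the axis midpoint;
    ``orthogonal`` builds the plane perpendicular to the axis through the
    distal contact (or ``center`` if given).
    """
    axis = electrode_axis(p_distal, p_proximal)
    midpoint = (np.asarray(p_distal, dtype=float) + np.asarray(p_proximal, dtype=float)) / 2.0
    if mode == "orthogonal":
        c = np.asarray(p_distal, dtype=float) if center is None else np.asarray(center, dtype=float)
        return make_plane(axis, c, extent, spacing)
    if mode == "inplane":
        # Normal perpendicular to the axis, chosen by the same z/x tie-break.
        helper = make_plane(axis, midpoint, extent, spacing)
        normal = helper.in_plane_u
        c = midpoint if center is None else np.asarray(center, dtype=float)
        return SlicePlane(
            center=c, normal=normal, in_plane_u=helper.in_plane_v, in_plane_v=axis,
            extent=extent, spacing=spacing,
        )
    raise InvalidParameterError(f"mode must be 'inplane' or 'orthogonal', got {mode!r}")


def extract_slice(vol: Volume3D, plane: SlicePlane, fill: float = 0.0) -> np.ndarray:
    """Trilinearly sample ``vol`` on the plane raster; outside voxels get ``fill``."""
    pts = plane.pixel_positions()
    values, _ = sample_trilinear(vol, pts.reshape(-1, 3), fill=fill)
    return values.reshape(pts.shape[:2])


def fused_mpr(
    fixed: Volume3D,
    moving: Volume3D,
    T: RigidTransform,
    plane: SlicePlane,
    wl_fixed: tuple[float, float],
    wl_moving: tuple[float, float],
    alpha: float = 0.5,
) -> np.ndarray:
    """Windowed, alpha-blended fused slice of the registered pair.

    The plane is defined in fixed space; moving pixels are sampled at the
    T-mapped positions, so the fusion is valid for any rigid alignment.
    ``wl_*`` are (window, level) pairs for each input.
    """
    pts = plane.pixel_positions().reshape(-1, 3)
    fvals, _ = sample_trilinear(fixed, pts)
    mvals, _ = sample_trilinear(moving, T.apply(pts))
    shape = plane.n_pixels

    def _wl(img: np.ndarray, wl: tuple[float, float]) -> np.ndarray:
        window, level = wl
        if window <= 0:
            raise InvalidParameterError(f"window must be > 0, got {window}")
        return np.clip((img - (level - window / 2.0)) / window, 0.0, 1.0)

    if not (0.0 <= alpha <= 1.0):
        raise InvalidParameterError(f"alpha must be in [0, 1], got {alpha}")
    fixed_slice = _wl(fvals.reshape(shape), wl_fixed)
    moving_slice = _wl(mvals.reshape(shape), wl_moving)
    return (1.0 - alpha) * fixed_slice + alpha * moving_slice
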