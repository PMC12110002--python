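"""Physical-space 3D image model: geometry, resampling, and display prep.

A :class:`Volume3D` couples a voxel array with the affine voxel-to-world map
used throughout clinical imaging: ``p = origin + direction @ (spacing * idx)``.
All physical coordinates in this package are millimetres in the LPS
(left-posterior-superior, DICOM/ITK) frame; NIfTI files, which store an RAS
world, are converted on read and write. Voxel centers sit at integer 0-based
indices, the standard convention for trilinear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import nibabel as nib
from scipy.ndimage import map_coordinates

from .errors import GeometryMismatchError, InvalidGeometryError, InvalidParameterError

__all__ = [
    "Volume3D",
    "index_to_physical",
    "physical_to_index",
    "resample_linear",
    "window_level",
    "alpha_blend",
    "read_nifti",
    "write_nifti",
    "ras_to_lps",
    "lps_to_ras",
]

# RAS and LPS differ by a sign flip of the first two axes.
_RAS_LPS_FLIP = np.diag([-1.0, -1.0, 1.0])


def ras_to_lps(points: np.ndarray) -> np.ndarray:
    """Convert physical points (..., 3) from RAS to LPS (negate x and y)."""
    points = np.asarray(points, dtype=float)
    return points * np.array([-1.0, -1.0, 1.0])


# The flip is an involution; the inverse map is the same operation.
lps_to_ras = ras_to_lps


@dataclass(frozen=True)
class Volume3D:
    """A 3D scalar image with physical-space metadata.

    Parameters
    ----------
    data
        3D intensity array (arbitrary units). Axis order is (i, j, k), the
        fastest-varying physical direction given by ``direction[:, 0]``.
    spacing
        Per-axis voxel size in mm; strictly positive.
    origin
        Physical LPS position (mm) of voxel (0, 0, 0).
    direction
        3x3 orthonormal matrix of direction cosines, determinant +1.
    """

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        origin = np.asarray(self.origin, dtype=float).reshape(3)
        direction = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if data.ndim != 3 or min(data.shape) < 1:
            raise InvalidGeometryError(
                f"data must be a 3D array with each axis >= 1, got shape {data.shape}"
            )
        if not np.all(spacing > 0):
            raise InvalidGeometryError(f"spacing must be positive, got {spacing}")
        if not np.allclose(direction.T @ direction, np.eye(3), atol=1e-9):
            raise InvalidGeometryError("direction matrix is not orthonormal")
        if np.linalg.det(direction) < 0:
            raise InvalidGeometryError("direction matrix must have determinant +1")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "direction", direction)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def same_grid(self, other: "Volume3D", atol: float = 1e-9) -> bool:
        """True if the two volumes share shape, spacing, origin and direction."""
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.direction, other.direction, atol=atol)
        )

    def physical_center(self) -> np.ndarray:
        """Physical centroid of the voxel grid (center of the FOV box), mm."""
        center_idx = (np.array(self.shape, dtype=float) - 1.0) / 2.0
        return index_to_physical(self, center_idx)

    def corner_points(self) -> np.ndarray:
        """Physical positions (8, 3) of the eight corner voxels."""
        n = np.array(self.shape, dtype=float) - 1.0
        corners = np.array(
            [[i * n[0], j * n[1], k * n[2]] for i in (0, 1) for j in (0, 1) for k in (0, 1)]
        )
        return index_to_physical(self, corners)


def index_to_physical(vol: Volume3D, idx: np.ndarray) -> np.ndarray:
    """Map continuous voxel indices (..., 3) to physical LPS points (mm).

    Indices need not lie inside the grid; the affine map extrapolates.
    """
    idx = np.asarray(idx, dtype=float)
    return (vol.direction @ (vol.spacing * idx)[..., None])[..., 0] + vol.origin


def physical_to_index(vol: Volume3D, p: np.ndarray) -> np.ndarray:
    """Map physical LPS points (..., 3) to continuous voxel indices.

    Exact inverse of :func:`index_to_physical` (direction is orthonormal, so
    the inverse rotation is the transpose).
    """
    p = np.asarray(p, dtype=float)
    return (vol.direction.T @ (p - vol.origin)[..., None])[..., 0] / vol.spacing


def sample_trilinear(
    vol: Volume3D, points: np.ndarray, fill: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Trilinearly sample ``vol`` at physical points (N, 3).

    Returns ``(values, inside)`` where ``inside`` flags points whose
    continuous index lies within the voxel-center bounding box
    ``[0, n-1]`` on every axis; values at outside points are ``fill``.
    """
    idx = physical_to_index(vol, points)
    # Snap sub-nanometre near-integer indices so grid-aligned sampling is
    # exact (identity resampling reproduces the source bit for bit).
    nearest = np.round(idx)
    idx = np.where(np.abs(idx - nearest) < 1e-9, nearest, idx)
    n = np.array(vol.shape, dtype=float)
    inside = np.all((idx >= 0.0) & (idx <= n - 1.0), axis=-1)
    values = map_coordinates(
        np.asarray(vol.data, dtype=float), idx.T, order=1, mode="constant", cval=fill
    )
    values = np.where(inside, values, fill)
    return values, inside


def resample_linear(
    src: Volume3D,
    reference: Volume3D,
    transform=None,
    fill: float = 0.0,
) -> Volume3D:
    """Resample ``src`` onto the grid of ``reference`` through a rigid map.

    Output voxel (i, j, k) holds the trilinear interpolation of ``src`` at
    ``T(index_to_physical(reference, (i, j, k)))``; ``T=None`` means identity.
    Points mapping outside the source voxel-center box receive ``fill``.
    """
    ref_idx = np.stack(
        np.meshgrid(*[np.arange(n, dtype=float) for n in reference.shape], indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)
    pts = index_to_physical(reference, ref_idx)
    if transform is not None:
        pts = transform.apply(pts)
    values, _ = sample_trilinear(src, pts, fill=fill)
    return Volume3D(
        data=values.reshape(reference.shape),
        spacing=reference.spacing.copy(),
        origin=reference.origin.copy(),
        direction=reference.direction.copy(),
    )


def window_level(vol: Volume3D, window: float, level: float) -> Volume3D:
    """Linear display mapping: center ``level``, width ``window``, clipped to [0, 1]."""
    if window <= 0:
        raise InvalidParameterError(f"window must be > 0, got {window}")
    lo = level - window / 2.0
    out = np.clip((np.asarray(vol.data, dtype=float) - lo) / window, 0.0, 1.0)
    return Volume3D(out, vol.spacing.copy(), vol.origin.copy(), vol.direction.copy())


def alpha_blend(a: Volume3D, b: Volume3D, alpha: float) -> Volume3D:
    """Convex combination ``(1 - alpha) * a + alpha * b`` on a shared grid."""
    if not (0.0 <= alpha <= 1.0):
        raise InvalidParameterError(f"alpha must be in [0, 1], got {alpha}")
    if not a.same_grid(b):
        raise GeometryMismatchError("alpha_blend requires volumes on the same grid")
    out = (1.0 - alpha) * np.asarray(a.data, dtype=float) + alpha * np.asarray(b.data, dtype=float)
    return Volume3D(out, a.spacing.copy(), a.origin.copy(), a.direction.copy())


# ---------------------------------------------------------------------------
# NIfTI I/O (nibabel). NIfTI world coordinates are RAS; internal frame is LPS,
# so the first two affine rows are negated in both directions. When both a
# qform and an sform are present the sform wins.
# ---------------------------------------------------------------------------


def read_nifti(path) -> Volume3D:
    """Load a NIfTI-1 volume into the internal LPS representation."""
    img = nib.load(str(path))
    affine_ras = img.get_sform() if img.header["sform_code"] > 0 else img.affine
    affine_lps = affine_ras.copy()
    affine_lps[:2, :] *= -1.0
    linear = affine_lps[:3, :3]
    spacing = np.linalg.norm(linear, axis=0)
    if np.any(spacing <= 0):
        raise InvalidGeometryError(f"non-positive voxel size in {path}")
    direction = linear / spacing
    # NIfTI-1 stores the affine in float32; restore exact orthonormality by
    # polar decomposition (nearest rotation), rejecting grossly sheared input.
    u, _, vt = np.linalg.svd(direction)
    nearest = u @ vt
    if np.max(np.abs(nearest - direction)) > 1e-3:
        raise InvalidGeometryError(f"direction matrix in {path} is not near-orthonormal")
    direction = nearest
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    return Volume3D(data=data, spacing=spacing, origin=affine_lps[:3, 3], direction=direction)


def write_nifti(vol: Volume3D, path) -> None:
    """Write a volume as NIfTI-1 (sform and qform both set, RAS world)."""
    affine_lps = np.eye(4)
    affine_lps[:3, :3] = vol.direction @ np.diag(vol.spacing)
    affine_lps[:3, 3] = vol.origin
    affine_ras = affine_lps.copy()
    affine_ras[:2, :] *= -1.0
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float64), affine_ras)
    img.set_sform(affine_ras, code=1)
    img.set_qform(affine_ras, code=1)
    nib.save(img, str(path))
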