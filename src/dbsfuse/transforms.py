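"""Versor-parameterized rigid 3D transforms.

A rigid transform is stored as a unit quaternion (versor, scalar-first
``(w, x, y, z)``), a translation vector and an explicit fixed rotation
center, all in LPS millimetres. The point map is

    q = R (p - center) + center + translation

and, by package-wide convention, maps fixed-space physical points into
moving-space physical points. Keeping the center explicit (typically the
fixed-image physical center) decouples the rotation parameters from large
translation offsets during optimization.

Euler-angle conversions use the ZYX intrinsic convention: ``angles =
(rx, ry, rz)`` compose as ``R = Rz(rz) @ Ry(ry) @ Rx(rx)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import LandmarkParseError

__all__ = ["RigidTransform", "identity_transform"]


def _as_unit_versor(versor: np.ndarray) -> np.ndarray:
    v = np.asarray(versor, dtype=float).reshape(4)
    norm = np.linalg.norm(v)
    if not np.isfinite(norm) or abs(norm - 1.0) > 1e-6:
        raise ValueError(f"versor must have unit norm, got |q| = {norm}")
    return v / norm


@dataclass(frozen=True)
class RigidTransform:
    """Rigid 3D map with versor rotation, translation and fixed center (mm)."""

    versor: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0, 0.0]))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        object.__setattr__(self, "versor", _as_unit_versor(self.versor))
        object.__setattr__(
            self, "translation", np.asarray(self.translation, dtype=float).reshape(3)
        )
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float).reshape(3))

    # -- representations ----------------------------------------------------

    @property
    def rotation_matrix(self) -> np.ndarray:
        w, x, y, z = self.versor
        return Rotation.from_quat([x, y, z, w]).as_matrix()

    @property
    def offset(self) -> np.ndarray:
        """Affine offset d such that the map is p -> R p + d."""
        return self.center + self.translation - self.rotation_matrix @ self.center

    def to_matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix of the point map (LPS mm)."""
        m = np.eye(4)
        m[:3, :3] = self.rotation_matrix
        m[:3, 3] = self.offset
        return m

    @classmethod
    def from_matrix_parts(
        cls, rotation: np.ndarray, offset: np.ndarray, center: np.ndarray | None = None
    ) -> "RigidTransform":
        """Build from affine parts (p -> R p + d), storing the given center."""
        center = np.zeros(3) if center is None else np.asarray(center, dtype=float)
        x, y, z, w = Rotation.from_matrix(rotation).as_quat()
        versor = np.array([w, x, y, z])
        if versor[0] < 0:  # canonical sign: non-negative scalar part
            versor = -versor
        translation = np.asarray(offset, dtype=float) + rotation @ center - center
        return cls(versor=versor, translation=translation, center=center)

    @classmethod
    def from_euler(
        cls,
        angles,
        translation=(0.0, 0.0, 0.0),
        center=(0.0, 0.0, 0.0),
    ) -> "RigidTransform":
        """Build from Euler angles (rx, ry, rz) rad, ZYX intrinsic order."""
        rx, ry, rz = np.asarray(angles, dtype=float)
        rot = Rotation.from_euler("ZYX", [rz, ry, rx])
        x, y, z, w = rot.as_quat()
        versor = np.array([w, x, y, z])
        if versor[0] < 0:
            versor = -versor
        return cls(versor=versor, translation=translation, center=center)

    def to_euler(self) -> np.ndarray:
        """Euler angles (rx, ry, rz) rad, inverse of :meth:`from_euler`."""
        w, x, y, z = self.versor
        rz, ry, rx = Rotation.from_quat([x, y, z, w]).as_euler("ZYX")
        return np.array([rx, ry, rz])

    # -- algebra ------------------------------------------------------------

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map fixed-space physical points (..., 3) into moving space."""
        p = np.asarray(points, dtype=float)
        rotated = (self.rotation_matrix @ (p - self.center)[..., None])[..., 0]
        return rotated + self.center + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return T with T(p) = self(other(p)); center taken from ``self``."""
        r_a, r_b = self.rotation_matrix, other.rotation_matrix
        return RigidTransform.from_matrix_parts(
            r_a @ r_b, r_a @ other.offset + self.offset, center=self.center
        )

    def invert(self) -> "RigidTransform":
        r = self.rotation_matrix
        return RigidTransform.from_matrix_parts(r.T, -r.T @ self.offset, center=self.center)

    # -- serialization ------------------------------------------------------

    def save(self, path) -> None:
        """Write a plain-text key/value transform file."""
        lines = [
            "format: dbsfuse-rigid-1",
            "frame: LPS",
            "convention: q = R (p - center) + center + translation; fixed -> moving",
            "versor_wxyz: " + " ".join(f"{v:.17g}" for v in self.versor),
            "translation_mm: " + " ".join(f"{v:.17g}" for v in self.translation),
            "center_mm: " + " ".join(f"{v:.17g}" for v in self.center),
        ]
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path) -> "RigidTransform":
        fields: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if ":" not in line:
                    raise LandmarkParseError(f"malformed transform line: {line!r}")
                key, _, value = line.partition(":")
                fields[key.strip()] = value.strip()
        try:
            versor = np.array([float(v) for v in fields["versor_wxyz"].split()])
            translation = np.array([float(v) for v in fields["translation_mm"].split()])
            center = np.array([float(v) for v in fields["center_mm"].split()])
        except (KeyError, ValueError) as exc:
            raise LandmarkParseError(f"invalid transform file {path}: {exc}") from exc
        return cls(versor=versor, translation=translation, center=center)


def identity_transform(center=(0.0, 0.0, 0.0)) -> RigidTransform:
    return RigidTransform(center=np.asarray(center, dtype=float))
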