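"""Synthetic multimodal phantom: ground-truth-linked volume pairs.

The generator renders one anatomical scene twice, emulating the data regime
of a postoperative electrode-verification study: a high-resolution
narrow-FOV "CT-like" volume (bone shell, semicircular-canal-like tori and
the electrode hyperintense, soft tissue flat) and a lower-resolution
full-FOV "MR-like" volume (soft-tissue contrast, hypointense nucleus,
hyperintense canals, no electrode — it is acquired before implantation).
The two grids are related by a known rigid transform that plays the role of
the unknown patient repositioning between sessions, so every downstream
stage can be scored against ground truth.

The intensity mappings of the two renderings are deliberately non-monotone
in one another (bone: bright CT / dark MR; soft tissue: flat CT / bright
MR), so correlation-style metrics cannot align the pair while
mutual-information metrics can — the property that motivates MI-based
registration of these modalities in the first place. Canal-like tori are
used because semicircular canals are the rare structure conspicuous in both
modalities, which is what makes them usable as cross-modality landmarks.

Default grids are desk-scale stand-ins that preserve the clinical 1:5
fine-to-coarse spacing ratio (128^3 at 0.4 mm vs 96^3 at 1.0 mm; the
clinical regime is 512x512x497 at 0.2 mm vs 192x192x160 at 1.0 mm, available
via ``full_size_spec``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .errors import PhantomSpecError
from .landmarks import LandmarkSet, write_fcsv
from .transforms import RigidTransform
from .volume import Volume3D, index_to_physical, write_nifti

__all__ = ["PhantomSpec", "PhantomPair", "generate_phantom_pair", "write_fixture_bundle",
           "full_size_spec"]

# Scene layout (LPS mm, scene == fixed frame). Everything the registration
# must "see" lies inside the narrow fine FOV (half-width ~25 mm).
_HEAD_SEMIAXES = np.array([40.0, 42.0, 38.0])
_SKULL_FRACTION = 0.88
_CANAL_CENTERS = (np.array([-18.0, -10.0, -6.0]), np.array([18.0, -10.0, -6.0]))
_CANAL_RING_RADIUS = 4.0
_CANAL_TUBE_RADIUS = 1.2
# Petrous-bone-like blocks: the canals are embedded in dense temporal bone,
# which is the dominant structure both modalities actually share in the
# narrow FOV (bright on CT, dark on T2).
_PETROUS_OFFSET = np.array([0.0, 1.0, -2.0])
_PETROUS_SEMIAXES = np.array([7.0, 8.0, 6.0])
# Third-ventricle-like midline CSF slab: conspicuous on T2, nearly invisible
# on CT (poor soft-tissue contrast).
_VENTRICLE_CENTER = np.array([0.0, 0.0, -2.0])
_VENTRICLE_SEMIAXES = np.array([1.5, 10.0, 8.0])
_NUCLEUS_CENTER = np.array([8.0, 2.0, -6.0])
_NUCLEUS_SEMIAXES = np.array([5.0, 3.0, 3.0])
_ELECTRODE_DISTAL = np.array([8.0, 2.0, -8.0])
_ELECTRODE_PROXIMAL = np.array([16.0, 8.0, 18.0])
_ELECTRODE_RADIUS = 0.65
_CONTACT_RADIUS = 1.0
_CONTACT_OFFSETS_MM = (1.5, 4.5, 7.5)
_EDGE_MM = 0.8  # smooth edge width; keeps the metric profile differentiable

# CT-like rendering: bone/canals/electrode hyperdense, soft tissue flat.
_CT = {"soft": 100.0, "skull": 1000.0, "petrous": 1000.0, "canal": 1500.0,
       "ventricle": 80.0, "electrode": 3000.0, "contact": 4000.0}
# MR-like (T2) rendering: fluid-filled canals and CSF bright, bone dark,
# nucleus hypointense, electrode absent preoperatively.
_MR = {"soft": 600.0, "skull": 100.0, "petrous": 100.0, "canal": 900.0,
       "ventricle": 1000.0, "nucleus": 250.0}


@dataclass(frozen=True)
class PhantomSpec:
    """Study-condition parameters for one synthetic subject."""

    fine_shape: tuple[int, int, int] = (128, 128, 128)
    fine_spacing: tuple[float, float, float] = (0.4, 0.4, 0.4)
    coarse_shape: tuple[int, int, int] = (96, 96, 96)
    coarse_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    max_rotation_deg: float = 5.0
    max_translation_mm: float = 5.0
    ct_noise_sd: float = 40.0
    mr_noise_sd: float = 25.0
    truncate_canal: bool = False
    seed: int = 0


def full_size_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """Clinical-scale grids (slow; intended for one-off demonstrations)."""
    return PhantomSpec(
        fine_shape=(512, 512, 497), fine_spacing=(0.2, 0.2, 0.2),
        coarse_shape=(192, 192, 160), coarse_spacing=(1.0, 1.0, 1.0),
        seed=seed, **overrides,
    )


@dataclass(frozen=True)
class PhantomPair:
    """One generated subject with every ground-truth linkage."""

    fixed: Volume3D        # MR-like, coarse full FOV, fixed frame
    moving: Volume3D       # CT-like, fine narrow FOV, moving frame
    init_fixed: LandmarkSet
    init_moving: LandmarkSet
    eval_fixed: LandmarkSet
    eval_moving: LandmarkSet
    truth: RigidTransform  # maps fixed-frame points to moving-frame points
    electrode: tuple[np.ndarray, np.ndarray]  # (distal, proximal), moving frame


def _ellipsoid_dist(p: np.ndarray, center: np.ndarray, semiaxes: np.ndarray) -> np.ndarray:
    """Approximate signed distance (mm) to an ellipsoid surface (<0 inside)."""
    q = (p - center) / semiaxes
    return (np.linalg.norm(q, axis=-1) - 1.0) * float(semiaxes.min())


def _torus_dist(p: np.ndarray, center: np.ndarray, ring_axis: int,
                ring_r: float, tube_r: float) -> np.ndarray:
    d = p - center
    axial = d[..., ring_axis]
    in_plane = np.sqrt(np.maximum(
        np.sum(d * d, axis=-1) - axial * axial, 0.0))
    return np.sqrt((in_plane - ring_r) ** 2 + axial * axial) - tube_r


def _capsule_dist(p: np.ndarray, a: np.ndarray, b: np.ndarray, radius: float) -> np.ndarray:
    ab = b - a
    t = np.clip(((p - a) @ ab) / float(ab @ ab), 0.0, 1.0)
    closest = a + t[..., None] * ab
    return np.linalg.norm(p - closest, axis=-1) - radius


def _mask(dist: np.ndarray) -> np.ndarray:
    """Compactly supported smooth inside-indicator from a signed distance.

    Cubic smoothstep over a band of +-_EDGE_MM around the surface; exactly 0
    (1) beyond it. Compact support matters: an infinite-tail profile would
    imprint a monotone distance-to-structure trace on every far voxel, which
    is invisible in intensity but dominates rank statistics between the two
    renderings.
    """
    t = np.clip(0.5 - dist / (2.0 * _EDGE_MM), 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _paint(base: np.ndarray, mask: np.ndarray, value: float) -> np.ndarray:
    return base * (1.0 - mask) + value * mask


def _canal_mask(p: np.ndarray, side: int, truncate: bool) -> np.ndarray:
    """Canal torus; optionally cut at a plane, as a narrow FOV would cut it."""
    center = _CANAL_CENTERS[side]
    m = _mask(_torus_dist(p, center, ring_axis=0,
                          ring_r=_CANAL_RING_RADIUS, tube_r=_CANAL_TUBE_RADIUS))
    if truncate:
        # keep only the inferior half of the ring (superior apex missing)
        m = m * _mask(p[..., 2] - center[2])
    return m


def _render_ct(p: np.ndarray, truncate_canal: bool) -> np.ndarray:
    """CT-like scene intensity at scene points (..., 3)."""
    head = _mask(_ellipsoid_dist(p, np.zeros(3), _HEAD_SEMIAXES))
    inner = _mask(_ellipsoid_dist(p, np.zeros(3), _HEAD_SEMIAXES * _SKULL_FRACTION))
    img = np.zeros(p.shape[:-1])
    img = _paint(img, inner, _CT["soft"])
    img = _paint(img, head - inner, _CT["skull"])
    img = _paint(img, _mask(_ellipsoid_dist(p, _VENTRICLE_CENTER, _VENTRICLE_SEMIAXES)),
                 _CT["ventricle"])
    for side in (0, 1):
        img = _paint(img, _mask(_ellipsoid_dist(
            p, _CANAL_CENTERS[side] + _PETROUS_OFFSET, _PETROUS_SEMIAXES)),
            _CT["petrous"])
    img = _paint(img, _canal_mask(p, 0, truncate_canal), _CT["canal"])
    img = _paint(img, _canal_mask(p, 1, False), _CT["canal"])
    img = _paint(img, _mask(_capsule_dist(p, _ELECTRODE_DISTAL, _ELECTRODE_PROXIMAL,
                                          _ELECTRODE_RADIUS)), _CT["electrode"])
    axis = _ELECTRODE_PROXIMAL - _ELECTRODE_DISTAL
    axis = axis / np.linalg.norm(axis)
    for off in _CONTACT_OFFSETS_MM:
        c = _ELECTRODE_DISTAL + off * axis
        img = _paint(img, _mask(np.linalg.norm(p - c, axis=-1) - _CONTACT_RADIUS),
                     _CT["contact"])
    return img


def _render_mr(p: np.ndarray) -> np.ndarray:
    """T2-like scene intensity at scene points (..., 3); no electrode (pre-op)."""
    head = _mask(_ellipsoid_dist(p, np.zeros(3), _HEAD_SEMIAXES))
    inner = _mask(_ellipsoid_dist(p, np.zeros(3), _HEAD_SEMIAXES * _SKULL_FRACTION))
    img = np.zeros(p.shape[:-1])
    img = _paint(img, inner, _MR["soft"])
    img = _paint(img, head - inner, _MR["skull"])
    img = _paint(img, _mask(_ellipsoid_dist(p, _VENTRICLE_CENTER, _VENTRICLE_SEMIAXES)),
                 _MR["ventricle"])
    img = _paint(img, _mask(_ellipsoid_dist(p, _NUCLEUS_CENTER, _NUCLEUS_SEMIAXES)),
                 _MR["nucleus"])
    for side in (0, 1):
        img = _paint(img, _mask(_ellipsoid_dist(
            p, _CANAL_CENTERS[side] + _PETROUS_OFFSET, _PETROUS_SEMIAXES)),
            _MR["petrous"])
    img = _paint(img, _canal_mask(p, 0, False), _MR["canal"])
    img = _paint(img, _canal_mask(p, 1, False), _MR["canal"])
    return img


def _scene_landmarks(truncate_canal: bool, rng: np.random.Generator):
    """Initialization (canal apices) and evaluation (other scene points).

    With a truncated canal the superior apex of that canal is invisible in
    the narrow-FOV volume; its moving-frame pick is displaced by ~1.5 mm to
    emulate the placement inaccuracy such an incomplete reconstruction
    causes.
    """
    l, r = _CANAL_CENTERS
    rr = _CANAL_RING_RADIUS
    init_pts = np.array([
        l + [0.0, 0.0, rr],    # left superior apex (truncation victim)
        l + [0.0, -rr, 0.0],   # left anterior apex
        r + [0.0, 0.0, rr],    # right superior apex
        r + [0.0, -rr, 0.0],   # right anterior apex
    ])
    init_labels = ("canal-L-sup", "canal-L-ant", "canal-R-sup", "canal-R-ant")
    eval_pts = np.array([
        _NUCLEUS_CENTER,
        _CANAL_CENTERS[1] + [0.0, rr, 0.0],   # right posterior apex
        np.array([-15.0, 5.0, 5.0]),          # contralateral soft-tissue point
    ])
    eval_labels = ("eval-nucleus", "eval-canal-R-post", "eval-soft-L")
    moving_error = np.zeros_like(init_pts)
    if truncate_canal:
        direction = rng.normal(size=3)
        moving_error[0] = 1.5 * direction / np.linalg.norm(direction)
    return init_pts, init_labels, eval_pts, eval_labels, moving_error


def _random_truth(spec: PhantomSpec, rng: np.random.Generator) -> RigidTransform:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(spec.max_rotation_deg) * rng.uniform()
    versor = np.concatenate([[np.cos(angle / 2.0)], np.sin(angle / 2.0) * axis])
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    translation = spec.max_translation_mm * rng.uniform() * direction
    return RigidTransform(versor=versor, translation=translation, center=np.zeros(3))


def _centered_grid(shape, spacing) -> tuple[np.ndarray, np.ndarray]:
    shape = np.asarray(shape, dtype=float)
    spacing = np.asarray(spacing, dtype=float)
    origin = -(shape - 1.0) * spacing / 2.0
    return origin, spacing


def generate_phantom_pair(spec: PhantomSpec = PhantomSpec()) -> PhantomPair:
    """Render one subject; deterministic for a given spec (seed included)."""
    rng = np.random.default_rng(spec.seed)
    truth = _random_truth(spec, rng)

    coarse_origin, coarse_spacing = _centered_grid(spec.coarse_shape, spec.coarse_spacing)
    fixed_grid = Volume3D(np.zeros(spec.coarse_shape), coarse_spacing, coarse_origin)

    # Fine grid centered on the scene center as seen in the moving frame.
    fine_origin0, fine_spacing = _centered_grid(spec.fine_shape, spec.fine_spacing)
    moving_center = truth.apply(np.zeros(3))
    fine_origin = fine_origin0 + moving_center
    moving_grid = Volume3D(np.zeros(spec.fine_shape), fine_spacing, fine_origin)

    # Narrow FOV must sit strictly inside the full FOV once mapped back.
    fine_corners_fixed = truth.invert().apply(moving_grid.corner_points())
    coarse_lo = coarse_origin
    coarse_hi = coarse_origin + (np.asarray(spec.coarse_shape) - 1) * coarse_spacing
    if not (np.all(fine_corners_fixed > coarse_lo) and np.all(fine_corners_fixed < coarse_hi)):
        raise PhantomSpecError(
            "fine (narrow) FOV is not strictly contained in the coarse FOV "
            "under the ground-truth transform"
        )

    def _grid_points(vol: Volume3D) -> np.ndarray:
        idx = np.stack(
            np.meshgrid(*[np.arange(n, dtype=float) for n in vol.shape], indexing="ij"),
            axis=-1,
        )
        return index_to_physical(vol, idx)

    mr = _render_mr(_grid_points(fixed_grid))
    scene_of_moving = truth.invert().apply(_grid_points(moving_grid))
    ct = _render_ct(scene_of_moving, spec.truncate_canal)

    if spec.mr_noise_sd > 0:
        mr = mr + rng.normal(0.0, spec.mr_noise_sd, size=mr.shape)
    if spec.ct_noise_sd > 0:
        ct = ct + rng.normal(0.0, spec.ct_noise_sd, size=ct.shape)

    fixed = Volume3D(mr, coarse_spacing, coarse_origin)
    moving = Volume3D(ct, fine_spacing, fine_origin)

    init_pts, init_labels, eval_pts, eval_labels, moving_error = _scene_landmarks(
        spec.truncate_canal, rng
    )
    init_fixed = LandmarkSet(init_labels, init_pts, "LPS")
    init_moving = LandmarkSet(init_labels, truth.apply(init_pts) + moving_error, "LPS")
    eval_fixed = LandmarkSet(eval_labels, eval_pts, "LPS")
    eval_moving = LandmarkSet(eval_labels, truth.apply(eval_pts), "LPS")

    electrode = (truth.apply(_ELECTRODE_DISTAL), truth.apply(_ELECTRODE_PROXIMAL))
    return PhantomPair(
        fixed=fixed, moving=moving,
        init_fixed=init_fixed, init_moving=init_moving,
        eval_fixed=eval_fixed, eval_moving=eval_moving,
        truth=truth, electrode=electrode,
    )


def write_fixture_bundle(spec: PhantomSpec, out_dir) -> dict:
    """Write volumes, landmark files, truth transform and a JSON manifest.

    Re-running with the same spec reproduces byte-identical arrays. Landmark
    files are written in Slicer .fcsv (RAS) form; the electrode coordinates
    and manifest are JSON.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pair = generate_phantom_pair(spec)

    paths = {
        "fixed_volume": "fixed_mr.nii.gz",
        "moving_volume": "moving_ct.nii.gz",
        "init_landmarks_fixed": "init_fixed.fcsv",
        "init_landmarks_moving": "init_moving.fcsv",
        "eval_landmarks_fixed": "eval_fixed.fcsv",
        "eval_landmarks_moving": "eval_moving.fcsv",
        "truth_transform": "truth_transform.txt",
        "electrode": "electrode.json",
    }
    write_nifti(pair.fixed, out / paths["fixed_volume"])
    write_nifti(pair.moving, out / paths["moving_volume"])
    write_fcsv(pair.init_fixed, out / paths["init_landmarks_fixed"])
    write_fcsv(pair.init_moving, out / paths["init_landmarks_moving"])
    write_fcsv(pair.eval_fixed, out / paths["eval_landmarks_fixed"])
    write_fcsv(pair.eval_moving, out / paths["eval_landmarks_moving"])
    pair.truth.save(out / paths["truth_transform"])
    with open(out / paths["electrode"], "w") as fh:
        json.dump(
            {
                "frame": "LPS",
                "space": "moving",
                "distal_mm": [float(v) for v in pair.electrode[0]],
                "proximal_mm": [float(v) for v in pair.electrode[1]],
            },
            fh, indent=2,
        )
    manifest = {"spec": asdict(spec), "seed": spec.seed, "files": paths}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
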