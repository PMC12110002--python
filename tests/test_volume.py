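import numpy as np
import pytest
from hypothesis import given, strategies as st

from dbsfuse.errors import GeometryMismatchError, InvalidGeometryError, InvalidParameterError
from dbsfuse.transforms import RigidTransform, identity_transform
from dbsfuse.volume import (
    Volume3D,
    alpha_blend,
    index_to_physical,
    physical_to_index,
    read_nifti,
    resample_linear,
    window_level,
    write_nifti,
)

from conftest import random_rigid


def _vol(shape=(4, 4, 4), spacing=(1, 1, 1), origin=(0, 0, 0), direction=None, data=None):
    if data is None:
        data = np.zeros(shape)
    return Volume3D(data, spacing, origin, np.eye(3) if direction is None else direction)


class TestGeometryMapping:
    @pytest.mark.parametrize(
        "spacing,origin,idx,expected",
        [
            ((1, 1, 1), (0, 0, 0), (0, 0, 0), (0, 0, 0)),
            ((1, 1, 1), (0, 0, 0), (2, 3, 4), (2, 3, 4)),
            ((0.2, 0.2, 0.2), (-5, -5, -5), (10, 0, 0), (-3, -5, -5)),
        ],
    )
    def test_index_to_physical_hand_cases(self, spacing, origin, idx, expected):
        vol = _vol(spacing=spacing, origin=origin)
        assert np.allclose(index_to_physical(vol, idx), expected, atol=1e-12)

    def test_physical_to_index_hand_case(self):
        vol = _vol(spacing=(2, 2, 2), origin=(1, 1, 1))
        assert np.allclose(physical_to_index(vol, (5, 1, 1)), (2, 0, 0), atol=1e-12)
        assert np.allclose(physical_to_index(vol, vol.origin), (0, 0, 0), atol=1e-12)

    def test_round_trip_random_geometries(self):
        """index -> physical -> index is exact for oblique direction matrices."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            direction = random_rigid(rng).rotation_matrix
            vol = _vol(
                spacing=rng.uniform(0.1, 3.0, 3),
                origin=rng.uniform(-50, 50, 3),
                direction=direction,
            )
            idx = rng.uniform(-10, 30, size=(20, 3))
            back = physical_to_index(vol, index_to_physical(vol, idx))
            assert np.max(np.abs(back - idx)) < 1e-9

    def test_invariants_enforced(self):
        with pytest.raises(InvalidGeometryError):
            _vol(spacing=(0, 1, 1))
        with pytest.raises(InvalidGeometryError):
            _vol(direction=np.diag([1.0, 1.0, -1.0]))  # reflection
        with pytest.raises(InvalidGeometryError):
            Volume3D(np.zeros((4, 4)), (1, 1, 1), (0, 0, 0), np.eye(3))


class TestResample:
    def test_identity_resample_is_bit_identical(self):
        rng = np.random.default_rng(0)
        src = _vol(data=rng.normal(size=(6, 5, 7)), spacing=(0.7, 1.1, 0.9), origin=(-2, 3, 1))
        out = resample_linear(src, src, identity_transform())
        assert np.array_equal(out.data, src.data)

    def test_translated_ramp_matches_closed_form(self):
        """Trilinear interpolation reproduces an affine field exactly inside."""
        n = 12
        idx = np.arange(n, dtype=float)
        x = idx[:, None, None] * np.ones((1, n, n))
        src = _vol(data=x, shape=(n, n, n))  # f(p) = p_x on an identity grid
        T = RigidTransform(translation=(2.0, 0.0, 0.0))
        out = resample_linear(src, src, T)
        interior = out.data[1:-3, 1:-1, 1:-1]
        expected = (x + 2.0)[1:-3, 1:-1, 1:-1]
        assert np.max(np.abs(interior - expected)) < 1e-12

    def test_affine_field_exact_under_random_rigid(self):
        """Any affine intensity field survives resampling through any rigid map."""
        rng = np.random.default_rng(7)
        n = 10
        coef = np.array([0.3, -0.7, 0.2])
        grid = np.stack(np.meshgrid(*[np.arange(n, dtype=float)] * 3, indexing="ij"), axis=-1)
        T = random_rigid(rng, max_angle_rad=0.4, max_translation_mm=1.5)
        # Source large enough that all mapped reference points stay interior.
        m = 40
        sgrid = np.stack(np.meshgrid(*[np.arange(m, dtype=float)] * 3, indexing="ij"), axis=-1)
        src = Volume3D(sgrid @ coef, (1, 1, 1), (-15, -15, -15), np.eye(3))
        ref = _vol(shape=(n, n, n))
        out = resample_linear(src, ref, T)
        mapped = T.apply(grid.reshape(-1, 3))
        expected = ((mapped - src.origin) @ coef).reshape(n, n, n)
        assert np.max(np.abs(out.data - expected)) < 1e-9

    def test_out_of_bounds_gets_fill(self):
        src = _vol(data=np.ones((4, 4, 4)))
        T = RigidTransform(translation=(100.0, 0.0, 0.0))
        out = resample_linear(src, src, T, fill=-7.0)
        assert np.all(out.data == -7.0)


class TestWindowLevel:
    def test_linear_map_and_clipping(self):
        vol = _vol(data=np.array([[[0.0, 25.0, 50.0, 75.0, 100.0, 200.0]]]))
        out = window_level(vol, window=100, level=50)
        assert np.allclose(out.data[0, 0], [0.0, 0.25, 0.5, 0.75, 1.0, 1.0])

    def test_invalid_window(self):
        with pytest.raises(InvalidParameterError):
            window_level(_vol(), window=0, level=50)

    @given(st.integers(0, 2**32 - 1))
    def test_range_and_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.normal(0, 100, size=(4, 4, 4))
        out = window_level(_vol(data=data), window=rng.uniform(1, 200), level=rng.normal(0, 50))
        assert np.all(out.data >= 0) and np.all(out.data <= 1)
        order = np.argsort(data.ravel())
        assert np.all(np.diff(out.data.ravel()[order]) >= 0)


class TestAlphaBlend:
    def test_endpoints_and_midpoint(self):
        a = _vol(data=np.full((3, 3, 3), 0.2))
        b = _vol(data=np.full((3, 3, 3), 0.6))
        assert np.array_equal(alpha_blend(a, b, 0.0).data, a.data)
        assert np.array_equal(alpha_blend(a, b, 1.0).data, b.data)
        assert np.allclose(alpha_blend(a, b, 0.5).data, 0.4)

    def test_swap_identity(self):
        rng = np.random.default_rng(3)
        a = _vol(data=rng.uniform(size=(4, 4, 4)))
        b = _vol(data=rng.uniform(size=(4, 4, 4)))
        total = alpha_blend(a, b, 0.3).data + alpha_blend(b, a, 0.3).data
        assert np.allclose(total, a.data + b.data, atol=1e-12)

    def test_grid_mismatch(self):
        with pytest.raises(GeometryMismatchError):
            alpha_blend(_vol(), _vol(origin=(1, 0, 0)), 0.5)


class TestNiftiIO:
    def test_round_trip_geometry_and_data(self, tmp_path):
        rng = np.random.default_rng(1)
        direction = random_rigid(rng).rotation_matrix
        vol = Volume3D(rng.normal(size=(5, 6, 7)), (0.5, 0.8, 1.2), (3, -4, 9), direction)
        path = tmp_path / "vol.nii.gz"
        write_nifti(vol, path)
        back = read_nifti(path)
        # geometry survives at NIfTI-1 float32 header precision
        assert np.allclose(back.data, vol.data, atol=1e-12)
        assert np.allclose(back.spacing, vol.spacing, atol=1e-5)
        assert np.allclose(back.origin, vol.origin, atol=1e-4)
        assert np.allclose(back.direction, vol.direction, atol=1e-6)

    def test_lps_convention_against_itk(self, tmp_path):
        """SimpleITK reads NIfTI into LPS natively; it must agree with ours."""
        sitk = pytest.importorskip("SimpleITK")
        vol = Volume3D(np.arange(24, dtype=float).reshape(2, 3, 4), (1, 2, 3), (5, -6, 7))
        path = tmp_path / "v.nii.gz"
        write_nifti(vol, path)
        img = sitk.ReadImage(str(path))
        assert np.allclose(img.GetOrigin(), vol.origin, atol=1e-6)
        assert np.allclose(img.GetSpacing(), vol.spacing, atol=1e-9)
        assert np.allclose(np.array(img.GetDirection()).reshape(3, 3), vol.direction, atol=1e-9)
        # sitk arrays are indexed (z, y, x)
        assert np.allclose(sitk.GetArrayFromImage(img).transpose(2, 1, 0), vol.data)
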