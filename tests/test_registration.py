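import numpy as np
import pytest

from dbsfuse.errors import RegistrationInitError
from dbsfuse.registration import (
    FixedSamples,
    RegistrationParams,
    mattes_mi,
    metric_gradient,
    mi_from_histogram,
    register,
    sample_fixed_points,
)
from dbsfuse.transforms import RigidTransform, identity_transform
from dbsfuse.volume import Volume3D, index_to_physical


def _identity_vol(data):
    return Volume3D(np.asarray(data, dtype=float), (1, 1, 1), (0, 0, 0), np.eye(3))


def _full_samples(vol):
    return sample_fixed_points(vol, 1.0, seed=0)


def _histogram_mi_oracle(f, m, n_bins):
    """Brute-force joint-histogram MI, independent of the Parzen machinery."""
    joint, _, _ = np.histogram2d(
        f, m, bins=n_bins, range=[[f.min(), f.max()], [m.min(), m.max()]]
    )
    p = joint / joint.sum()
    pf, pm = p.sum(axis=1), p.sum(axis=0)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / np.outer(pf, pm)[nz])))


class TestSampling:
    def test_full_fraction_hits_every_voxel_once(self):
        vol = _identity_vol(np.arange(27).reshape(3, 3, 3))
        s = sample_fixed_points(vol, 1.0, seed=1)
        assert len(s) == 27
        assert sorted(s.intensities.tolist()) == list(range(27))

    def test_sample_count_arithmetic(self):
        vol = _identity_vol(np.zeros((20, 20, 25)))
        assert len(sample_fixed_points(vol, 0.01, seed=0)) == 100

    def test_seed_reproducibility(self):
        vol = _identity_vol(np.random.default_rng(0).normal(size=(10, 10, 10)))
        a = sample_fixed_points(vol, 0.1, seed=5)
        b = sample_fixed_points(vol, 0.1, seed=5)
        c = sample_fixed_points(vol, 0.1, seed=6)
        assert np.array_equal(a.points, b.points)
        assert not np.array_equal(a.points, c.points)

    def test_region_mask_restricts_draw(self):
        vol = _identity_vol(np.zeros((6, 6, 6)))
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[:2] = True
        s = sample_fixed_points(vol, 1.0, seed=0, region_mask=mask)
        assert len(s) == mask.sum()
        assert np.all(s.points[:, 0] <= 1.0)


class TestMattesMI:
    def test_box_mode_matches_histogram_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            fixed = _identity_vol(rng.normal(size=(8, 8, 8)))
            moving = _identity_vol(0.3 * fixed.data + rng.normal(size=(8, 8, 8)))
            s = _full_samples(fixed)
            val = mattes_mi(s, moving, identity_transform(), n_bins=16, moving_window="box")
            oracle = _histogram_mi_oracle(s.intensities, moving.data.reshape(-1)[
                np.ravel_multi_index(tuple(np.round(
                    (s.points - moving.origin).T).astype(int)), moving.shape)
            ], 16)
            assert abs(-val - oracle) < 1e-12

    def test_self_mi_equals_binned_entropy(self):
        rng = np.random.default_rng(3)
        vol = _identity_vol(rng.normal(size=(8, 8, 8)))
        s = _full_samples(vol)
        val = -mattes_mi(s, vol, identity_transform(), n_bins=12, moving_window="box")
        counts, _ = np.histogram(vol.data, bins=12, range=(vol.data.min(), vol.data.max()))
        p = counts / counts.sum()
        entropy = -np.sum(p[p > 0] * np.log(p[p > 0]))
        assert abs(val - entropy) < 1e-9

    def test_independent_noise_has_null_mi(self):
        """Jackknife-debiased MI of permuted noise is within 3 SE of zero."""
        rng = np.random.default_rng(4)
        n = 32768
        f = rng.normal(size=n)
        m = rng.permutation(f)
        blocks = 16
        mi_full = _histogram_mi_oracle(f, m, 8)
        deleted = []
        for b in range(blocks):
            keep = np.ones(n, dtype=bool)
            keep[b::blocks] = False
            deleted.append(_histogram_mi_oracle(f[keep], m[keep], 8))
        deleted = np.array(deleted)
        mi_jack = blocks * mi_full - (blocks - 1) * deleted.mean()
        se = np.sqrt((blocks - 1) / blocks * np.sum((deleted - deleted.mean()) ** 2))
        assert abs(mi_jack) < 3 * se

    def test_constant_channel_returns_zero_with_warning(self):
        fixed = _identity_vol(np.ones((4, 4, 4)))
        moving = _identity_vol(np.random.default_rng(0).normal(size=(4, 4, 4)))
        with pytest.warns(UserWarning, match="constant"):
            assert mattes_mi(_full_samples(fixed), moving, identity_transform()) == 0.0

    def test_insufficient_overlap_raises(self):
        fixed = _identity_vol(np.random.default_rng(0).normal(size=(4, 4, 4)))
        far = RigidTransform(translation=(1000, 0, 0))
        from dbsfuse.errors import InsufficientOverlapError

        with pytest.raises(InsufficientOverlapError):
            mattes_mi(_full_samples(fixed), fixed, far)

    def test_cubic_parzen_weights_are_normalized(self):
        """Cubic-window histogram mass equals the box-window sample count."""
        rng = np.random.default_rng(5)
        from dbsfuse.registration import joint_histogram

        f = rng.normal(size=500)
        m = rng.normal(size=500)
        h = joint_histogram(f, m, 32, moving_window="cubic")
        assert abs(h.sum() - 500) < 1e-9


def _smooth_pair(n=24, offset_mm=0.0):
    """Correlated smooth multimodal pair on identity grids."""
    idx = np.stack(np.meshgrid(*[np.arange(n, dtype=float)] * 3, indexing="ij"), axis=-1)
    c = (n - 1) / 2.0
    r2 = np.sum((idx - c) ** 2, axis=-1)
    fixed = _identity_vol(np.exp(-r2 / (2 * 25.0)))
    moving_data = 1.0 / (1.0 + r2 / 30.0)  # non-linear intensity relation
    moving = Volume3D(moving_data, (1, 1, 1), (offset_mm, 0, 0), np.eye(3))
    return fixed, moving


class TestMetricGradient:
    def test_matches_external_central_difference(self):
        fixed, moving = _smooth_pair(offset_mm=1.3)
        s = _full_samples(fixed)
        T = identity_transform(center=(11.5, 11.5, 11.5))
        h = 0.25
        g = metric_gradient(s, moving, T, n_bins=16, step_sizes=(1e-3, h))
        shifted = lambda dx: RigidTransform(center=T.center, translation=(dx, 0, 0))
        expected_tx = (
            mattes_mi(s, moving, shifted(h), 16) - mattes_mi(s, moving, shifted(-h), 16)
        ) / (2 * h)
        assert g[3] == pytest.approx(expected_tx, abs=1e-15)

    def test_translation_gradient_points_toward_alignment(self):
        fixed, moving = _smooth_pair(offset_mm=2.0)
        s = _full_samples(fixed)
        g = metric_gradient(s, moving, identity_transform(center=(11.5,) * 3), n_bins=16)
        # Metric (negative MI) decreases toward +x, so the descent direction
        # -g must have a positive x-translation component.
        assert -g[3] > 0

    def test_stationarity_at_alignment(self):
        """Gradient at the optimum is far below the gradient off-optimum."""
        fixed, moving = _smooth_pair(offset_mm=0.0)
        s = _full_samples(fixed)
        T = identity_transform(center=(11.5,) * 3)
        g_opt = metric_gradient(s, moving, T, n_bins=16)
        g_off = metric_gradient(
            s, Volume3D(moving.data, moving.spacing, (2.0, 0, 0), np.eye(3)), T, n_bins=16
        )
        assert np.linalg.norm(g_opt) < 0.1 * np.linalg.norm(g_off)


class TestRegister:
    def test_already_aligned_stays_put(self):
        rng = np.random.default_rng(6)
        vol = _identity_vol(rng.normal(size=(16, 16, 16)))
        params = RegistrationParams(sampling_fraction=0.5, max_iterations=5, seed=0)
        res = register(vol, vol, identity_transform(center=(7.5,) * 3), params)
        corners = vol.corner_points()
        disp = np.linalg.norm(res.transform.apply(corners) - corners, axis=1).max()
        assert disp < 0.1

    def test_loop_control_contracts(self, small_pair):
        pair = small_pair
        t0 = RigidTransform(versor=pair.truth.versor, translation=pair.truth.translation,
                            center=pair.truth.center)
        inf_conv = RegistrationParams(convergence_min=np.inf, convergence_window=10,
                                      max_iterations=30, seed=0)
        res = register(pair.fixed, pair.moving, t0, inf_conv)
        assert res.converged and res.iterations_run == 10
        never = RegistrationParams(convergence_min=0.0, max_iterations=12, seed=0)
        res2 = register(pair.fixed, pair.moving, t0, never)
        assert res2.iterations_run == 12 and not res2.converged
        assert len(res2.metric_trace) == res2.iterations_run

    def test_never_worse_than_start(self, small_pair):
        pair = small_pair
        res = register(pair.fixed, pair.moving, pair.truth,
                       RegistrationParams(max_iterations=8, seed=1))
        assert res.final_metric <= res.metric_at_init

    def test_bitwise_determinism(self, small_pair):
        pair = small_pair
        params = RegistrationParams(max_iterations=6, seed=9)
        a = register(pair.fixed, pair.moving, pair.truth, params)
        b = register(pair.fixed, pair.moving, pair.truth, params)
        assert a.metric_trace == b.metric_trace
        assert np.array_equal(a.transform.versor, b.transform.versor)
        assert np.array_equal(a.transform.translation, b.transform.translation)

    def test_insufficient_overlap_at_start(self, small_pair):
        pair = small_pair
        bad = RigidTransform(translation=(500.0, 0, 0))
        with pytest.raises(RegistrationInitError):
            register(pair.fixed, pair.moving, bad, RegistrationParams(seed=0))

    def test_refinement_improves_tre(self, small_pair):
        """A perturbed start is pulled back toward truth (held-out landmarks)."""
        from dbsfuse.evaluation import pre_post_report

        pair = small_pair
        t0 = RigidTransform(
            versor=pair.truth.versor,
            translation=pair.truth.translation + np.array([1.0, -0.7, 0.5]),
            center=pair.truth.center,
        )
        res = register(pair.fixed, pair.moving, t0, RegistrationParams(seed=2))
        pre, post = pre_post_report(t0, res.transform, pair.eval_fixed, pair.eval_moving)
        assert post.mean_mm < pre.mean_mm
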