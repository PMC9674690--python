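"""Phasor transform, reference curve, projection plane and cloud geometry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from t1phasor import (
    PhantomSpec,
    build_projection_plane,
    build_reference_curve,
    dft_phasor,
    ir_to_decay,
    mono_exponential_phasor,
    phasor_cloud,
    project,
    simulate_phantom,
)
from t1phasor.errors import (
    DegeneratePlaneError,
    DegenerateVoxelError,
    DimensionError,
)
from t1phasor.phasor import dft_phasor_many, mono_exponential_decay

from conftest import ANCHORS, naive_phasor


class TestDftPhasor:
    def test_delta_decay_is_zero_lifetime_limit(self):
        pv = dft_phasor([1, 0, 0, 0, 0, 0, 0, 0])
        assert np.allclose(pv.g, 1.0) and np.allclose(pv.s, 0.0)

    def test_constant_decay_is_infinite_lifetime_limit(self):
        pv = dft_phasor([3.0] * 8)
        assert np.allclose(pv.g, 0.0, atol=1e-15)
        assert np.allclose(pv.s, 0.0, atol=1e-15)
        assert pv.total == pytest.approx(24.0)

    def test_exponential_decay_matches_trig_oracle(self, molli_times):
        v = np.exp(-molli_times / 1.5)
        pv = dft_phasor(v)
        g, s = naive_phasor(v)
        assert np.max(np.abs(pv.g - g)) < 1e-12
        assert np.max(np.abs(pv.s - s)) < 1e-12
        assert pv.s[0] > 0  # +sin convention puts decays in the upper half

    def test_oracle_equivalence_random_decays(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            m = rng.integers(4, 16)
            v = rng.uniform(0.05, 1.0, size=m)
            pv = dft_phasor(v)
            g, s = naive_phasor(v)
            assert np.max(np.abs(np.concatenate([pv.g - g, pv.s - s]))) < 1e-12

    def test_degenerate_total_raises(self):
        with pytest.raises(DegenerateVoxelError):
            dft_phasor([0.0, 0.0, 0.0, 0.0])
        with pytest.raises(DegenerateVoxelError):
            dft_phasor([1.0, -1.0, -1.0, 0.5])

    def test_linearity_weighted_mixture(self, molli_times):
        d1 = 3.0 * np.exp(-molli_times / 1.5)
        d2 = 0.5 * np.exp(-molli_times / 2.0)
        p1, p2, pm = dft_phasor(d1), dft_phasor(d2), dft_phasor(d1 + d2)
        w = p1.total / (p1.total + p2.total)
        assert np.allclose(pm.vector, w * p1.vector + (1 - w) * p2.vector, atol=1e-14)

    def test_vectorized_matches_scalar_and_flags_degenerates(self, molli_times):
        rng = np.random.default_rng(0)
        arr = rng.uniform(0.1, 1.0, size=(5, molli_times.size))
        arr[2] = 0.0
        coords, totals = dft_phasor_many(arr)
        assert np.all(np.isnan(coords[2])) and totals[2] == 0.0
        for i in (0, 1, 3, 4):
            assert np.allclose(coords[i], dft_phasor(arr[i]).vector, atol=1e-15)


class TestMonoExponentialPhasor:
    @pytest.mark.parametrize("mode", ["decay", "inversion_recovery"])
    def test_zero_lifetime_limit(self, molli_times, mode):
        pv = mono_exponential_phasor(1e-9, molli_times, mode)
        assert np.allclose(pv.g, 1.0, atol=1e-6)
        assert np.allclose(pv.s, 0.0, atol=1e-6)

    def test_infinite_lifetime_limit_decay_mode(self, molli_times):
        pv = mono_exponential_phasor(1e9, molli_times, "decay")
        assert np.allclose(pv.vector, 0.0, atol=1e-6)

    def test_ir_mode_matches_converted_recovery(self, molli_times):
        pv = mono_exponential_phasor(1.5, molli_times, "inversion_recovery")
        s = 1 - 2 * np.exp(-molli_times / 1.5)
        ref = dft_phasor(s[-1] - s)
        # the reference path evaluates a rescaled (underflow-safe) decay that
        # is exactly proportional; phasors agree to float round-off
        assert np.allclose(pv.vector, ref.vector, rtol=0, atol=5e-14)

    def test_nonpositive_lifetime_rejected(self, molli_times):
        with pytest.raises(ValueError):
            mono_exponential_phasor(-1.0, molli_times, "decay")

    def test_extreme_lifetimes_do_not_underflow(self, molli_times):
        d = mono_exponential_decay(1e-9, molli_times, "inversion_recovery")
        assert d[0] == 1.0 and np.all(np.isfinite(d))


class TestReferenceCurve:
    def test_limit_endpoints_project_to_calibration_points(self, molli_times, ir_plane):
        grid = np.array([1e-9, 0.5, 1.5, 5.0, 1e9])
        curve = build_reference_curve(molli_times, grid, mode="decay", plane=ir_plane)
        assert np.allclose(curve.projected[0], [1.0, 0.0], atol=1e-6)
        assert np.allclose(curve.projected[-1], [0.0, 0.0], atol=1e-6)

    def test_points_equal_mono_exponential_phasor(self, molli_times, ir_plane):
        grid = np.logspace(-1, 1, 7)
        curve = build_reference_curve(
            molli_times, grid, mode="inversion_recovery", plane=ir_plane
        )
        for i, tau in enumerate(grid):
            expected = mono_exponential_phasor(tau, molli_times, "inversion_recovery")
            assert np.allclose(curve.vectors[i], expected.vector, atol=0)

    def test_injective_over_measured_range(self, molli_times, ir_plane):
        grid = np.linspace(0.5, 5.0, 200)
        curve = build_reference_curve(
            molli_times, grid, mode="inversion_recovery", plane=ir_plane
        )
        arc = np.linalg.norm(np.diff(curve.projected, axis=0), axis=1)
        assert np.all(arc > 0)

    def test_empty_grid_rejected(self, molli_times):
        with pytest.raises(ValueError):
            build_reference_curve(molli_times, np.array([]), mode="decay")


class TestProjectionPlane:
    def test_basis_orthonormal_and_anchors_upper_half(self, molli_times, ir_plane):
        p = ir_plane
        assert abs(p.basis_u1 @ p.basis_u1 - 1) < 1e-12
        assert abs(p.basis_u2 @ p.basis_u2 - 1) < 1e-12
        assert abs(p.basis_u1 @ p.basis_u2) < 1e-12
        for a in p.anchor_lifetimes:
            pv = mono_exponential_phasor(a, molli_times, p.mode)
            assert project(pv, p)[1] >= 0

    def test_duplicate_anchor_degenerate(self, molli_times):
        with pytest.raises(DegeneratePlaneError):
            build_projection_plane(molli_times, (1.5, 1.5, 2.0))

    def test_anchors_lie_exactly_in_plane(self, molli_times, ir_plane):
        vecs = [
            mono_exponential_phasor(a, molli_times, "inversion_recovery").vector
            for a in ir_plane.anchor_lifetimes
        ]
        raw = ir_plane.raw_coords(np.array(vecs))
        for i in range(3):
            for j in range(i + 1, 3):
                d_full = np.linalg.norm(vecs[i] - vecs[j])
                d_plane = np.linalg.norm(raw[i] - raw[j])
                assert abs(d_full - d_plane) < 1e-10

    def test_calibration_is_exact_at_the_lifetime_limits(self, ir_plane):
        n = ir_plane.n_harmonics
        zero_life = np.concatenate([np.ones(n), np.zeros(n)])
        assert np.allclose(project(zero_life, ir_plane), [1.0, 0.0], atol=1e-14)
        assert np.allclose(project(np.zeros(2 * n), ir_plane), [0.0, 0.0], atol=1e-14)

    def test_harmonic_mismatch_rejected(self, ir_plane):
        with pytest.raises(DimensionError):
            project(np.zeros(6), ir_plane)


class TestProjectGeometry:
    def test_two_component_mixture_on_chord(self, molli_times, ir_plane):
        d1 = mono_exponential_decay(1.5, molli_times, "inversion_recovery")
        d2 = mono_exponential_decay(2.0, molli_times, "inversion_recovery")
        p1 = project(dft_phasor(d1), ir_plane)
        p2 = project(dft_phasor(d2), ir_plane)
        for a, b in [(0.3, 0.7), (2.0, 1.0), (0.05, 0.95)]:
            pm = project(dft_phasor(a * d1 + b * d2), ir_plane)
            w = a * d1.sum() / (a * d1.sum() + b * d2.sum())
            assert np.allclose(pm, w * p1 + (1 - w) * p2, atol=1e-10)

    def test_three_component_mixtures_fill_triangle(self, molli_times, ir_plane):
        taus = (1.2, 1.6, 2.2)
        decays = [mono_exponential_decay(t, molli_times, "inversion_recovery") for t in taus]
        pure = np.array([project(dft_phasor(d), ir_plane) for d in decays])
        rng = np.random.default_rng(3)
        for _ in range(100):
            w = rng.dirichlet([1, 1, 1])
            mix = sum(wi * d for wi, d in zip(w, decays))
            pm = project(dft_phasor(mix), ir_plane)
            # barycentric membership in the pure-projection triangle
            mat = np.column_stack([pure[1] - pure[0], pure[2] - pure[0]])
            lam = np.linalg.solve(mat, pm - pure[0])
            assert lam[0] >= -1e-9 and lam[1] >= -1e-9 and lam.sum() <= 1 + 1e-9

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        a=st.floats(0.05, 5.0),
        b=st.floats(0.05, 5.0),
        t1=st.floats(0.3, 4.0),
        t2=st.floats(0.3, 4.0),
    )
    def test_exact_convexity_property(self, a, b, t1, t2):
        times = np.array([0.129, 0.209, 1.344, 1.394, 2.494, 2.551, 3.644, 4.807])
        plane = _PLANE_CACHE.setdefault(
            "p", build_projection_plane(times, ANCHORS, mode="inversion_recovery")
        )
        d1 = mono_exponential_decay(t1, times, "inversion_recovery")
        d2 = mono_exponential_decay(t2, times, "inversion_recovery")
        pm = project(dft_phasor(a * d1 + b * d2), plane)
        w = a * d1.sum() / (a * d1.sum() + b * d2.sum())
        p1 = project(dft_phasor(d1), plane)
        p2 = project(dft_phasor(d2), plane)
        assert np.allclose(pm, w * p1 + (1 - w) * p2, atol=1e-10)


_PLANE_CACHE: dict = {}


class TestPhasorCloud:
    def test_pure_region_points_coincide(self, phantom_noiseless, ir_plane):
        fractions, _, converted = phantom_noiseless
        roi = fractions.f_myo == 1.0
        cloud = phasor_cloud(converted, roi, ir_plane)
        assert len(cloud) == roi.sum()
        assert np.ptp(cloud.axis1) < 1e-9 and np.ptp(cloud.axis2) < 1e-9

    def test_single_voxel_roi(self, phantom_noiseless, ir_plane):
        fractions, _, converted = phantom_noiseless
        r, c = np.argwhere(fractions.f_blood == 1.0)[0]
        roi = np.zeros(converted.grid_shape, dtype=bool)
        roi[r, c] = True
        cloud = phasor_cloud(converted, roi, ir_plane)
        expected = project(dft_phasor(converted.data[r, c]), ir_plane)
        assert len(cloud) == 1
        assert np.allclose([cloud.axis1[0], cloud.axis2[0]], expected)

    def test_full_phantom_on_pure_component_chord(self, phantom_noiseless, ir_plane, molli_times):
        fractions, _, converted = phantom_noiseless
        cloud = phasor_cloud(converted, fractions.support, ir_plane)
        p_myo = project(
            mono_exponential_phasor(1.5, molli_times, "inversion_recovery"), ir_plane
        )
        p_blood = project(
            mono_exponential_phasor(2.0, molli_times, "inversion_recovery"), ir_plane
        )
        u = p_myo - p_blood
        u = u / np.linalg.norm(u)
        rel = cloud.points - p_blood
        perp = rel - np.outer(rel @ u, u)
        assert np.abs(perp).max() < 1e-9

    def test_empty_roi_rejected(self, phantom_noiseless, ir_plane):
        fractions, _, converted = phantom_noiseless
        with pytest.raises(ValueError):
            phasor_cloud(converted, np.zeros(converted.grid_shape, bool), ir_plane)

    def test_unconverted_stack_rejected(self, phantom_noiseless, ir_plane):
        fractions, raw, _ = phantom_noiseless
        with pytest.raises(DimensionError):
            phasor_cloud(raw, fractions.support, ir_plane)

    def test_degenerate_voxels_reported_not_dropped_silently(self, molli_times, ir_plane):
        from t1phasor import ContrastStack

        data = np.zeros((2, 2, molli_times.size))
        data[0, 0] = np.exp(-molli_times / 1.5)
        stack = ContrastStack(data=data, times=molli_times, converted=True)
        cloud = phasor_cloud(stack, np.ones((2, 2), bool), ir_plane)
        assert len(cloud) == 1
        assert set(cloud.degenerate_ids) == {1, 2, 3}


class TestReferenceGeometryProperties:
    def test_mono_exponential_lies_on_interpolated_locus(self, molli_times, ir_plane):
        grid = np.logspace(np.log10(0.3), np.log10(8.0), 400)
        curve = build_reference_curve(
            molli_times, grid, mode="inversion_recovery", plane=ir_plane
        )
        from t1phasor.analysis import _signed_polyline_distance

        for tau in (0.9, 1.6, 3.3):
            p = project(
                mono_exponential_phasor(tau, molli_times, "inversion_recovery"), ir_plane
            )
            arc = np.linalg.norm(np.diff(curve.projected, axis=0), axis=1).max()
            d = _signed_polyline_distance(p[None, :], curve.projected)
            assert abs(d[0]) < arc  # within the grid-resolution bound

    def test_gaussian_decays_fall_above_mono_exponential_locus(self):
        times = np.linspace(0.0, 4.0, 16)
        taus_grid = np.logspace(-2, 2, 2000)
        locus = np.array(
            [
                (dft_phasor(np.exp(-times / t)).g[0], dft_phasor(np.exp(-times / t)).s[0])
                for t in taus_grid
            ]
        )
        for tau in (0.8, 1.5, 2.5):
            pv = dft_phasor(np.exp(-((times / tau) ** 2)))
            i = np.argmin(np.abs(locus[:, 0] - pv.g[0]))
            assert pv.s[0] > locus[i, 1]
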