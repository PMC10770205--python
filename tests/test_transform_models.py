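"""Transform family: fitting, residuals, warping, nested-model assessment."""

import numpy as np
import pytest
from scipy.optimize import minimize

from dsareg.transform_models import (
    TYPE_ORDER,
    CorrespondenceSet,
    DegeneracyError,
    Transform2D,
    TransformType,
    apply_transform,
    assess_transform_types,
    fit_transform,
    warp_image,
)

ALL_TYPES = list(TYPE_ORDER)


def random_transform(ttype, rng):
    """Random well-conditioned ground-truth transform of the given type."""
    if ttype is TransformType.TRANSLATION:
        return Transform2D.from_similarity_params(
            translation=rng.uniform(-50, 50, 2), ttype=ttype)
    if ttype is TransformType.RIGID:
        return Transform2D.from_similarity_params(
            rotation_deg=rng.uniform(-180, 180), translation=rng.uniform(-50, 50, 2),
            ttype=ttype)
    if ttype is TransformType.SIMILARITY:
        return Transform2D.from_similarity_params(
            scale=rng.uniform(0.5, 2), rotation_deg=rng.uniform(-180, 180),
            translation=rng.uniform(-50, 50, 2))
    m = np.eye(3)
    m[:2, :2] = np.eye(2) + rng.uniform(-0.3, 0.3, (2, 2))
    m[:2, 2] = rng.uniform(-50, 50, 2)
    if ttype is TransformType.PROJECTIVE:
        m[2, :2] = rng.uniform(-1e-4, 1e-4, 2)
    return Transform2D(ttype, m)


def noiseless_instance(ttype, seed, n=6):
    rng = np.random.default_rng(seed)
    moving = rng.uniform(0, 512, (n, 2))
    t = random_transform(ttype, rng)
    return CorrespondenceSet(moving, apply_transform(t, moving)), t


class TestFitTransform:
    @pytest.mark.parametrize("ttype", ALL_TYPES)
    def test_identity_when_fixed_equals_moving(self, ttype):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 100, (6, 2))
        fit = fit_transform(CorrespondenceSet(pts, pts), ttype)
        assert np.allclose(fit.transform.matrix, np.eye(3), atol=1e-8)
        assert fit.mean_residual < 1e-8

    def test_similarity_recovers_scale2_rot90_translation(self):
        moving = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        truth = Transform2D.from_similarity_params(scale=2, rotation_deg=90,
                                                   translation=(5, 5))
        fixed = apply_transform(truth, moving)
        fit = fit_transform(CorrespondenceSet(moving, fixed), TransformType.SIMILARITY)
        assert np.allclose(fit.transform.matrix, truth.matrix, atol=1e-9)
        assert fit.mean_residual < 1e-9

    @pytest.mark.parametrize("ttype", ALL_TYPES)
    def test_exact_recovery_from_noiseless_points(self, ttype):
        for seed in range(20):
            corr, truth = noiseless_instance(ttype, seed)
            fit = fit_transform(corr, ttype)
            assert fit.mean_residual < 1e-6
            assert np.abs(fit.transform.matrix - truth.matrix).max() < 1e-6

    def test_similarity_matches_generic_nonlinear_minimizer(self):
        """Closed-form Procrustes agrees with an independent 4-parameter
        numerical minimization of the same sum-of-squares objective."""
        rng = np.random.default_rng(5)
        moving = rng.uniform(0, 512, (6, 2))
        truth = random_transform(TransformType.SIMILARITY, rng)
        fixed = apply_transform(truth, moving) + rng.normal(0, 2, (6, 2))

        def sse(params):
            s, th, tx, ty = params
            c, si = np.cos(th), np.sin(th)
            pred = moving @ (s * np.array([[c, si], [-si, c]])) + [tx, ty]
            return ((pred - fixed) ** 2).sum()

        best = min(
            (minimize(sse, [s0, th0, 0, 0], method="Nelder-Mead",
                      options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000})
             for s0 in (0.5, 1.0, 2.0) for th0 in (-2.0, 0.0, 2.0)),
            key=lambda r: r.fun,
        )
        fit = fit_transform(CorrespondenceSet(moving, fixed), TransformType.SIMILARITY)
        assert (fit.residuals ** 2).sum() == pytest.approx(best.fun, abs=1e-6)

    def test_insufficient_points_raise(self):
        one = CorrespondenceSet([[0, 0]], [[1, 1]])
        with pytest.raises(ValueError):
            fit_transform(one, TransformType.RIGID)
        with pytest.raises(ValueError):
            fit_transform(CorrespondenceSet([[0, 0], [1, 1]], [[0, 0], [1, 1]]),
                          TransformType.AFFINE)

    @pytest.mark.parametrize("ttype", [TransformType.AFFINE, TransformType.PROJECTIVE])
    def test_collinear_points_are_degenerate(self, ttype):
        moving = np.column_stack([np.arange(6.0), 2 * np.arange(6.0)])
        with pytest.raises(DegeneracyError):
            fit_transform(CorrespondenceSet(moving, moving + 1), ttype)

    def test_reflection_never_returned_for_similarity(self):
        """Mirrored correspondences either fit with a proper rotation (det +1)
        or are rejected as degenerate — a reflection is never returned."""
        rng = np.random.default_rng(4)
        moving = rng.uniform(0, 100, (6, 2))
        fixed = moving * [-1, 1] + rng.normal(0, 2, (6, 2))
        for ttype in (TransformType.RIGID, TransformType.SIMILARITY):
            try:
                fit = fit_transform(CorrespondenceSet(moving, fixed), ttype)
            except DegeneracyError:
                continue
            assert np.linalg.det(fit.transform.matrix[:2, :2]) > 0

    def test_order_invariance_and_translation_equivariance(self):
        rng = np.random.default_rng(11)
        corr, _ = noiseless_instance(TransformType.SIMILARITY, 3, n=8)
        fixed = corr.fixed + rng.normal(0, 1, corr.fixed.shape)
        corr = CorrespondenceSet(corr.moving, fixed)
        perm = rng.permutation(8)
        f1 = fit_transform(corr, TransformType.SIMILARITY)
        f2 = fit_transform(CorrespondenceSet(corr.moving[perm], corr.fixed[perm]),
                           TransformType.SIMILARITY)
        assert np.allclose(f1.transform.matrix, f2.transform.matrix, atol=1e-9)

        off = np.array([17.0, -4.0])
        f3 = fit_transform(CorrespondenceSet(corr.moving + off, corr.fixed + off),
                           TransformType.SIMILARITY)
        assert np.allclose(f1.transform.matrix[:2, :2], f3.transform.matrix[:2, :2],
                           atol=1e-9)


class TestApplyTransform:
    def test_identity_and_pure_translation(self):
        pts = np.array([[1.0, 1.0], [3.5, -2.0]])
        assert np.allclose(apply_transform(Transform2D.identity(), pts), pts)
        t = Transform2D.from_similarity_params(translation=(5, -3),
                                               ttype=TransformType.TRANSLATION)
        assert np.allclose(apply_transform(t, [[1, 1]]), [[6, -2]])

    def test_composition_associativity_on_random_points(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = random_transform(TransformType.PROJECTIVE, rng)
            b = random_transform(TransformType.AFFINE, rng)
            pts = rng.uniform(0, 512, (5, 2))
            lhs = apply_transform(a, apply_transform(b, pts))
            rhs = apply_transform(a.compose(b), pts)
            assert np.allclose(lhs, rhs, atol=1e-9)


class TestWarpImage:
    @pytest.fixture()
    def smooth_image(self):
        yy, xx = np.mgrid[0:64, 0:64]
        return 0.5 + 0.5 * np.sin(xx / 9.0) * np.cos(yy / 7.0)

    def test_identity_leaves_image_unchanged(self, smooth_image):
        out = warp_image(Transform2D.identity(), smooth_image)
        assert np.abs(out - smooth_image).max() < 1e-7

    def test_integer_translation_shifts_columns(self, smooth_image):
        t = Transform2D.from_similarity_params(translation=(10, 0))
        out = warp_image(t, smooth_image)
        assert np.allclose(out[:, 10:], smooth_image[:, :-10], atol=1e-9)
        assert np.allclose(out[:, :10], 1.0)  # background fill

    def test_roundtrip_interior_error_is_small(self, smooth_image):
        t = Transform2D.from_similarity_params(scale=1.05, rotation_deg=8,
                                               translation=(3, -2), center=(31.5, 31.5))
        back = warp_image(t.inverse(), warp_image(t, smooth_image))
        interior = np.abs(back - smooth_image)[8:-8, 8:-8]
        assert interior.mean() < 0.01


class TestAssessTransformTypes:
    def test_sets_below_min_points_are_excluded(self):
        corr, _ = noiseless_instance(TransformType.SIMILARITY, 0, n=5)
        table, summary = assess_transform_types({"p1": corr}, min_points=6)
        assert table.empty and summary.empty

    def test_noiseless_similarity_sets_nested_exactness(self):
        corr, truth = noiseless_instance(TransformType.SIMILARITY, 1, n=8)
        table, _ = assess_transform_types({"p": corr})
        by_type = table.set_index("ttype")["mean_residual"]
        for t in ("similarity", "affine", "projective"):
            assert by_type[t] < 1e-6
        # rotation present -> translation alone cannot align
        assert by_type["translation"] > 1.0

    def test_rms_residual_nonincreasing_with_dof(self):
        """Nesting: each family contains the previous, so the minimized
        (sum-of-squares) residual can only shrink as dof grows."""
        rng = np.random.default_rng(0)
        for s in range(30):
            corr, _ = noiseless_instance(TransformType.SIMILARITY, 100 + s, n=8)
            noisy = CorrespondenceSet(corr.moving,
                                      corr.fixed + rng.normal(0, 2, corr.fixed.shape))
            rms = [fit_transform(noisy, t).rms_residual for t in TYPE_ORDER]
            assert np.all(np.diff(rms) <= 1e-6)


class TestSerialization:
    def test_json_roundtrip(self):
        t = Transform2D.from_similarity_params(scale=1.3, rotation_deg=20,
                                               translation=(4, 5))
        back = Transform2D.from_json(t.to_json())
        assert back.ttype is t.ttype
        assert np.allclose(back.matrix, t.matrix)
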