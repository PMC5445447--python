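"""Point-distribution model, grey-profile model and iterative fitting."""

import numpy as np
import pytest

from mousetrack import asm
from mousetrack import catalog as cat
from mousetrack._geometry import apply_similarity

from tests.conftest import render_frame_from_polys


def two_mode_model(n=100, s=200, sig1=8.0, sig2=5.0, seed=3, f_v=0.98):
    """Shapes sampled from a known 2-mode linear model, plus the generator
    modes for recovery checks."""
    rng = np.random.default_rng(seed)
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    base = np.stack([35 * np.sin(ang), -55 * np.cos(ang)], axis=1)
    m1 = np.stack([12 * np.sin(2 * ang), np.zeros(n)], axis=1).reshape(-1)
    m1 /= np.linalg.norm(m1)
    m2 = np.stack([np.zeros(n), 10 * np.sin(3 * ang)], axis=1).reshape(-1)
    m2 /= np.linalg.norm(m2)
    shapes = []
    coeffs = []
    for _ in range(s):
        c1, c2 = rng.normal(0, sig1), rng.normal(0, sig2)
        pts = (base.reshape(-1) + c1 * m1 + c2 * m2).reshape(-1, 2)
        shapes.append(cat.align_vertical(pts, 0, n // 2).reshape(-1))
        coeffs.append((c1, c2))
    model = asm.build_shape_model(np.stack(shapes), f_v=f_v, m=3.0)
    model.landmark_indices = {"nose": 0, "tail_base": n // 2}
    return model, np.array([m1, m2]).T, np.array(coeffs), np.stack(shapes)


class TestBuildShapeModel:
    def test_identical_shapes_give_flat_model(self):
        shape = np.random.default_rng(0).uniform(0, 10, 40)
        model = asm.build_shape_model(np.tile(shape, (5, 1)))
        assert np.allclose(model.mean, shape)
        assert model.eigvals[0] == pytest.approx(0.0, abs=1e-18)
        assert model.t == 1                       # policy floor

    def test_mode_count_prefix_rule(self):
        assert asm.mode_count(np.array([4.0, 3.0, 2.0, 1.0]), 0.5) == 2
        assert asm.mode_count(np.array([4.0, 3.0, 2.0, 1.0]), 0.4) == 1
        assert asm.mode_count(np.array([4.0, 3.0, 2.0, 1.0]), 1.0) == 4
        # brute-force scan over all prefixes agrees
        rng = np.random.default_rng(1)
        for _ in range(20):
            lam = np.sort(rng.uniform(0, 10, 6))[::-1]
            f_v = rng.uniform(0.1, 1.0)
            t = asm.mode_count(lam, f_v)
            total = lam.sum()
            prefix = np.cumsum(lam)
            brute = next(i + 1 for i in range(6)
                         if prefix[i] >= f_v * total - 1e-12)
            assert t == brute

    def test_generative_recovery_two_modes(self):
        model, true_modes, coeffs, _ = two_mode_model()
        assert model.t == 2
        # principal angles between learned and true 2-D subspaces < 5 deg
        P = model.eigvecs[:, :2]
        Q, _ = np.linalg.qr(true_modes)
        s = np.linalg.svd(Q.T @ P, compute_uv=False)
        angles = np.degrees(np.arccos(np.clip(s, -1, 1)))
        assert angles.max() < 5.0
        # per-mode eigenvalue-to-generator-variance ratios within 10%
        assert abs(model.eigvals[0] / 8.0 ** 2 - 1.0) < 0.1
        assert abs(model.eigvals[1] / 5.0 ** 2 - 1.0) < 0.1

    def test_orthonormal_eigenvectors(self):
        model, *_ = two_mode_model(s=50)
        P = model.eigvecs
        assert np.abs(P.T @ P - np.eye(P.shape[1])).max() < 1e-8

    def test_too_few_shapes_rejected(self):
        with pytest.raises(ValueError):
            asm.build_shape_model(np.zeros((2, 10)))


class TestProjectReconstruct:
    def test_mean_projects_to_zero(self):
        model, *_ = two_mode_model(s=50)
        assert np.allclose(asm.project(model.mean, model), 0.0, atol=1e-9)

    def test_single_mode_coefficient_recovered(self):
        model, *_ = two_mode_model(s=50)
        b0 = 2 * np.sqrt(model.eigvals[0])
        x = model.mean + model.eigvecs[:, 0] * b0
        b = asm.project(x, model)
        assert b[0] == pytest.approx(b0, rel=1e-9)
        assert np.allclose(b[1:], 0.0, atol=1e-6 * b0)

    def test_full_rank_round_trip(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 3, (100, 32))          # s > 2n: full-rank covariance
        model = asm.build_shape_model(X, f_v=1.0)
        x = rng.normal(0, 3, 32)
        back = asm.reconstruct(asm.project(x, model, t=32), model).reshape(-1)
        assert np.linalg.norm(back - x) < 1e-9

    def test_dimension_mismatch_rejected(self):
        model, *_ = two_mode_model(s=10)
        with pytest.raises(ValueError):
            asm.project(np.zeros(10), model)


class TestClamp:
    def test_out_of_box_clipped(self):
        model, *_ = two_mode_model(s=50)
        b = np.array([5.0, -5.0]) * np.sqrt(model.eigvals[:2])
        c = asm.clamp(b, model)
        assert np.allclose(np.abs(c), 3.0 * np.sqrt(model.eigvals[:2]))

    def test_inside_box_unchanged_and_idempotent(self):
        model, *_ = two_mode_model(s=50)
        rng = np.random.default_rng(3)
        for _ in range(10):
            b = rng.normal(0, 2, 2) * np.sqrt(model.eigvals[:2])
            c = asm.clamp(b, model)
            assert np.allclose(asm.clamp(c, model), c)
            if np.all(np.abs(b) <= 3 * np.sqrt(model.eigvals[:2])):
                assert np.allclose(c, b)


class TestProfileModel:
    def test_identical_step_edges_give_tight_stats(self):
        step = np.zeros(11)
        step[5:] = 1.0
        profiles = np.tile(np.diff(step) / np.abs(np.diff(step)).sum(),
                           (10, 4, 1))
        mean, icov = asm.build_profile_model(profiles, k=5)
        assert np.allclose(mean, profiles[0])

    def test_flat_profiles_normalized_to_zero(self):
        img = np.full((50, 50), 77.0)
        contour = np.stack([10 + 20 * np.cos(np.linspace(0, 2 * np.pi, 12,
                                                         endpoint=False)),
                            25 + 15 * np.sin(np.linspace(0, 2 * np.pi, 12,
                                                         endpoint=False))],
                           axis=1)
        prof = asm.sample_profiles(img, contour, k=5)
        assert np.allclose(prof, 0.0)
        assert np.all(np.isfinite(prof))

    def test_noise_variance_propagates_to_diagonal(self):
        # i.i.d. pixel noise through first differences and normalization:
        # Monte-Carlo against the sampled covariance diagonal
        rng = np.random.default_rng(4)
        sigma = 1.0
        raw = rng.normal(0, sigma, (500, 3, 11))
        deriv = np.diff(raw, axis=2)
        denom = np.abs(deriv).sum(axis=2, keepdims=True)
        profiles = deriv / denom
        mean, icov = asm.build_profile_model(profiles, k=5, shrinkage=0.0)
        emp_cov_diag = np.var(profiles[:, 0, :], axis=0)
        S = np.linalg.inv(icov[0])
        assert np.allclose(np.diag(S), emp_cov_diag, rtol=0.2)

    def test_mahalanobis_diagonal_case(self):
        rng = np.random.default_rng(5)
        d = 8
        var = rng.uniform(0.5, 2.0, d)
        mean = rng.normal(0, 1, d)
        icov = np.diag(1.0 / var)
        g = rng.normal(0, 1, d)
        expected = np.sum((g - mean) ** 2 / var)
        assert asm.profile_quality(g, mean, icov) == pytest.approx(expected)
        assert asm.profile_quality(mean, mean, icov) == 0.0


@pytest.fixture(scope="module")
def rendered_two_mode():
    """2-mode model with self-consistent profile statistics from renders."""
    model, *_ = two_mode_model()
    rng = np.random.default_rng(5)
    profs = []
    for _ in range(40):
        b = asm.clamp(rng.uniform(-2, 2, model.t)
                      * np.sqrt(model.eigvals[:model.t]), model)
        inst = asm.ShapeInstance(1.0, rng.uniform(0, 360),
                                 np.array([240.0, 240.0]), b)
        pts = inst.realize(model)
        frame = render_frame_from_polys([pts], noise=3.0, rng=rng)
        profs.append(asm.sample_profiles(frame, pts, 5))
    asm.attach_profile_model(model, np.stack(profs), 5)
    return model


class TestFit:
    def test_fixed_point_when_rendered_from_init(self, rendered_two_mode):
        model = rendered_two_mode
        b = np.zeros(model.t)
        b[0] = 1.2 * np.sqrt(model.eigvals[0])
        init = asm.ShapeInstance(1.0, 40.0, np.array([240.0, 240.0]), b)
        target = init.realize(model)
        frame = render_frame_from_polys([target])
        fitted = asm.fit(model, frame, init, n_max=20)
        rms = np.sqrt(np.mean(np.sum((fitted.realize(model) - target) ** 2,
                                     axis=1)))
        assert rms < 0.3

    def test_three_px_offset_recovered(self, rendered_two_mode):
        model = rendered_two_mode
        b = np.zeros(model.t)
        b[0] = 1.2 * np.sqrt(model.eigvals[0])
        truth_inst = asm.ShapeInstance(1.0, 33.0, np.array([240.0, 240.0]), b)
        target = truth_inst.realize(model)
        frame = render_frame_from_polys([target], noise=3.0,
                                        rng=np.random.default_rng(7))
        for shift in [(3, 0), (0, 3), (-3, 0), (0, -3)]:
            init = asm.ShapeInstance(1.0, 33.0,
                                     np.array([240.0 + shift[0],
                                               240.0 + shift[1]]), b.copy())
            fitted = asm.fit(model, frame, init, n_max=60, search_l=7)
            rms = np.sqrt(np.mean(np.sum(
                (fitted.realize(model) - target) ** 2, axis=1)))
            assert rms < 0.5, f"shift {shift}: rms {rms:.3f}"

    def test_clamp_invariant_after_every_fit(self, rendered_two_mode):
        model = rendered_two_mode
        rng = np.random.default_rng(8)
        b = np.zeros(model.t)
        b[0] = np.sqrt(model.eigvals[0])
        init = asm.ShapeInstance(1.0, 10.0, np.array([240.0, 240.0]), b)
        frame = render_frame_from_polys([init.realize(model)], noise=3.0,
                                        rng=rng)
        inst = init
        lim = model.m * np.sqrt(model.eigvals[:model.t])
        for _ in range(15):
            inst = asm.fit_step(model, frame, inst)
            assert np.all(np.abs(inst.b) <= lim + 1e-12)

    def test_all_frozen_keeps_shape(self, rendered_two_mode):
        model = rendered_two_mode
        b = np.zeros(model.t)
        b[0] = 0.8 * np.sqrt(model.eigvals[0])
        init = asm.ShapeInstance(1.0, 70.0, np.array([240.0, 240.0]), b)
        frame = render_frame_from_polys([init.realize(model)])
        frozen = np.ones(model.n_points, dtype=bool)
        out = asm.fit_step(model, frame, init, frozen=frozen)
        assert np.allclose(out.realize(model), init.realize(model), atol=0.2)

    def test_missing_profile_stats_rejected(self):
        model, *_ = two_mode_model(s=10)
        init = asm.ShapeInstance(1.0, 0.0, np.zeros(2), np.zeros(model.t))
        with pytest.raises(ValueError):
            asm.fit_step(model, np.zeros((50, 50)), init)


class TestPersistence:
    def test_save_load_round_trip(self, rendered_two_mode, tmp_path):
        model = rendered_two_mode
        path = tmp_path / "model.npz"
        asm.save_model(path, model)
        back = asm.load_model(path)
        assert np.allclose(back.mean, model.mean)
        assert np.allclose(back.eigvecs, model.eigvecs)
        assert back.t == model.t
        assert np.allclose(back.profile_mean, model.profile_mean)
        assert back.landmark_indices == model.landmark_indices
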