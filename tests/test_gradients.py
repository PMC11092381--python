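import numpy as np
import pytest
import scipy.stats

from hemigrad.gradients import (
    GradientConfig,
    build_templates,
    diffusion_map_embed,
    embed_block,
    normalized_angle_affinity,
    procrustes_align,
    sparsify_profiles,
    variance_explained,
)


def dense_markov_oracle(A, alpha, n_components):
    """Brute-force right-eigendecomposition of P = D'^-1 W' (the oracle)."""
    d = A.sum(axis=1)
    W = A / np.outer(d**alpha, d**alpha)
    P = W / W.sum(axis=1, keepdims=True)
    evals, evecs = np.linalg.eig(P)
    order = np.argsort(-evals.real)
    lam = evals.real[order][1 : n_components + 1]
    vecs = evecs.real[:, order][:, 1 : n_components + 1]
    return vecs * (lam / (1 - lam)), lam


def random_affinity(rng, n):
    A = rng.random((n, n))
    A = (A + A.T) / 2
    np.fill_diagonal(A, 1.0)
    return A


class TestSparsify:
    def test_top_one_by_signed_value(self):
        col = np.array([5, 4, 3, 2, 1, 0, -1, -2, -3, -4], dtype=float)
        M = np.tile(col[:, None], (1, 3))
        out = sparsify_profiles(M, GradientConfig(density=0.1))
        expected = np.zeros_like(M)
        expected[0] = 5.0
        np.testing.assert_array_equal(out, expected)

    def test_full_density_is_identity(self, rng):
        M = rng.standard_normal((15, 15))
        out = sparsify_profiles(M, GradientConfig(density=1.0))
        np.testing.assert_array_equal(out, M)

    def test_matches_sort_oracle(self, rng):
        M = rng.standard_normal((20, 20))
        out = sparsify_profiles(M, GradientConfig(density=0.1))
        assert ((out != 0).sum(axis=0) == 2).all()
        for j in range(20):
            keep = np.sort(np.argsort(-M[:, j], kind="stable")[:2])
            expected = np.zeros(20)
            expected[keep] = M[keep, j]
            np.testing.assert_array_equal(out[:, j], expected)

    def test_ties_keep_lower_index(self):
        M = np.array([[1.0, 0.0], [1.0, 0.0], [0.5, 1.0], [0.2, 1.0]])
        out = sparsify_profiles(M, GradientConfig(density=0.25))
        assert out[0, 0] == 1.0 and out[1, 0] == 0.0
        assert out[2, 1] == 1.0 and out[3, 1] == 0.0

    def test_row_axis_variant(self, rng):
        M = rng.standard_normal((10, 10))
        out = sparsify_profiles(M, GradientConfig(density=0.2, threshold_axis="row"))
        assert ((out != 0).sum(axis=1) == 2).all()

    def test_zero_survivors_rejected(self):
        with pytest.raises(ValueError, match="density"):
            sparsify_profiles(np.ones((5, 5)), GradientConfig(density=0.05))


class TestAffinity:
    def test_identical_orthogonal_opposite_profiles(self):
        P = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 2.0], [-3.0, 0.0]])
        A = normalized_angle_affinity(P)
        assert A[0, 1] == pytest.approx(1.0)
        assert A[0, 2] == pytest.approx(0.5)
        assert A[0, 3] == pytest.approx(0.0)

    def test_bounds_symmetry_unit_diagonal(self, rng):
        P = rng.standard_normal((12, 30))
        A = normalized_angle_affinity(P)
        assert A.min() >= 0.0 and A.max() <= 1.0
        np.testing.assert_array_equal(np.diag(A), np.ones(12))
        np.testing.assert_array_equal(A, A.T)

    def test_zero_profile_named(self):
        P = np.zeros((3, 4))
        P[1] = 1.0
        P[2] = 2.0
        with pytest.raises(ValueError, match=r"\[0\]"):
            normalized_angle_affinity(P)


class TestDiffusionMap:
    def test_two_communities_give_piecewise_constant_component(self):
        n = 16
        A = np.full((n, n), 1e-6)
        A[:8, :8] = 1.0
        A[8:, 8:] = 1.0
        emb = diffusion_map_embed(A, GradientConfig(n_components=3))
        g1 = emb.scores[:, 0]
        within = g1[:8].var() + g1[8:].var()
        between = (g1[:8].mean() - g1[8:].mean()) ** 2
        assert within < 1e-6 * between

    def test_rank_one_affinity_gives_null_embedding(self):
        A = np.ones((10, 10))
        emb = diffusion_map_embed(A, GradientConfig(n_components=3))
        assert np.abs(emb.lambdas).max() < 1e-10
        assert np.abs(emb.scores).max() < 1e-8

    def test_matches_dense_markov_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 21))
            A = random_affinity(rng, n)
            cfg = GradientConfig(n_components=4)
            emb = diffusion_map_embed(A, cfg)
            oracle, lam = dense_markov_oracle(A, cfg.alpha, 4)
            np.testing.assert_allclose(emb.lambdas, lam, atol=1e-10)
            for k in range(4):
                r = scipy.stats.pearsonr(emb.scores[:, k], oracle[:, k])[0]
                assert abs(r) > 1 - 1e-9

    def test_lambda_scaling_preserves_component_order(self, rng):
        A = random_affinity(rng, 15)
        emb = diffusion_map_embed(A, GradientConfig(n_components=5))
        mags = np.abs(emb.lambdas / (1 - emb.lambdas))
        assert (np.diff(mags) <= 1e-12).all()

    def test_diffusion_time_scaling(self, rng):
        A = random_affinity(rng, 12)
        e0 = diffusion_map_embed(A, GradientConfig(n_components=3))
        e2 = diffusion_map_embed(A, GradientConfig(n_components=3, diffusion_time=2.0))
        ratio0 = e0.scores[:, 0] / (e0.lambdas[0] / (1 - e0.lambdas[0]))
        ratio2 = e2.scores[:, 0] / (e2.lambdas[0] ** 2)
        np.testing.assert_allclose(ratio0, ratio2, atol=1e-10)

    def test_asymmetric_affinity_rejected(self):
        A = np.random.default_rng(0).random((5, 5))
        with pytest.raises(ValueError, match="symmetric"):
            diffusion_map_embed(A, GradientConfig(n_components=2))


class TestVarianceExplained:
    def test_simple_fractions(self):
        np.testing.assert_allclose(
            variance_explained([2.0, 1.0, 1.0]), [0.5, 0.25, 0.25]
        )
        np.testing.assert_allclose(variance_explained([1.0]), [1.0])

    def test_matches_manual_normalization(self, rng):
        lam = rng.random(8)
        np.testing.assert_allclose(variance_explained(lam), lam / lam.sum())

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            variance_explained([0.0, 0.0])


class TestProcrustes:
    def test_identity_when_source_equals_template(self, rng):
        T = rng.standard_normal((30, 5))
        np.testing.assert_allclose(procrustes_align(T, T), T, atol=1e-10)

    def test_sign_flips_are_absorbed(self, rng):
        T = rng.standard_normal((30, 5))
        S = T * np.array([-1, 1, -1, 1, -1])
        np.testing.assert_allclose(procrustes_align(S, T), T, atol=1e-8)

    def test_random_rotation_recovered(self, rng):
        T = rng.standard_normal((40, 6))
        Q, _ = np.linalg.qr(rng.standard_normal((6, 6)))
        np.testing.assert_allclose(procrustes_align(T @ Q, T), T, atol=1e-8)

    def test_alignment_is_isometric(self, rng):
        S = rng.standard_normal((25, 4))
        T = rng.standard_normal((25, 4))
        A = procrustes_align(S, T)
        dS = np.linalg.norm(S[:, None] - S[None, :], axis=2)
        dA = np.linalg.norm(A[:, None] - A[None, :], axis=2)
        np.testing.assert_allclose(dS, dA, atol=1e-8)

    def test_rank_deficient_crossproduct_rejected(self):
        S = np.zeros((10, 3))
        S[:, 0] = np.arange(10)
        with pytest.raises(ValueError, match="fewer"):
            procrustes_align(S, S)


class TestPipelineLevel:
    def test_embedding_sign_flip_invariant_after_alignment(self, rng):
        A = random_affinity(rng, 30)
        cfg = GradientConfig(n_components=5)
        emb = diffusion_map_embed(A, cfg)
        T = rng.standard_normal((30, 5))
        base = procrustes_align(emb.scores, T)
        flipped = emb.scores * np.array([1, -1, 1, -1, 1])
        np.testing.assert_allclose(procrustes_align(flipped, T), base, atol=1e-8)

    def test_single_subject_mirror_template(self, small_cohort):
        from hemigrad.connectome import compute_fc, partition_fc
        from hemigrad.connectome import HemiBlocks

        sub = small_cohort.subjects[0]
        fc = compute_fc(sub.timeseries)
        b = partition_fc(fc, small_cohort.parcellation)
        mirrored = HemiBlocks(LL=b.LL, RR=b.LL, LR=b.LR, RL=b.LR.T)
        cfg = GradientConfig()
        tmpl = build_templates([mirrored], cfg)
        direct = embed_block(b.LL, cfg)
        np.testing.assert_allclose(tmpl.intra, direct.scores, atol=1e-10)

    def test_hc_only_template_changes_little(self, small_cohort):
        from hemigrad.connectome import compute_fc, partition_fc
        from hemigrad.gradients import align_subject

        cfg = GradientConfig()
        blocks = [
            partition_fc(compute_fc(s.timeseries), small_cohort.parcellation)
            for s in small_cohort.subjects
        ]
        groups = [s.group for s in small_cohort.subjects]
        t_all = build_templates(blocks, cfg, "all_subjects", groups)
        t_hc = build_templates(blocks, cfg, "hc_only", groups)
        a_all = align_subject(blocks[0], t_all, cfg)
        a_hc = align_subject(blocks[0], t_hc, cfg)
        for k in range(3):
            r = scipy.stats.pearsonr(a_all["LL"][:, k], a_hc["LL"][:, k])[0]
            # independent templates carry a global sign indeterminacy
            assert abs(r) > 0.99
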