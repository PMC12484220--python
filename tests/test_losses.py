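"""Closed forms, loop oracles, clamp behavior, and gradient checks for losses."""

import numpy as np
import pytest

import scsoftclust as sc
from scsoftclust.autodiff import Tensor
from scsoftclust.losses import (
    LossWeights,
    contrastive_loss,
    cosine_similarity,
    dec_target_kl,
    reconstruction_loss,
    soft_clustering_loss,
    student_t_q,
    total_loss,
)


def _random_stochastic(rng, n, k):
    m = rng.uniform(0.05, 1.0, size=(n, k))
    return m / m.sum(axis=1, keepdims=True)


class TestReconstruction:
    def test_perfect_reconstruction_is_zero(self, rng):
        x1, x2 = rng.normal(size=(4, 3)), rng.normal(size=(4, 2))
        assert float(reconstruction_loss(x1, x2, Tensor(x1), Tensor(x2)).data) == 0.0

    def test_all_ones_closed_form(self):
        x1, x2 = np.zeros((3, 4)), np.zeros((3, 2))
        loss = reconstruction_loss(x1, x2, Tensor(np.ones((3, 4))), Tensor(np.ones((3, 2))))
        assert float(loss.data) == 3 * 4 + 3 * 2

    def test_matches_double_loop(self, rng):
        x1, x2 = rng.normal(size=(3, 2)), rng.normal(size=(3, 2))
        r1, r2 = rng.normal(size=(3, 2)), rng.normal(size=(3, 2))
        expected = sum(
            (x[i, j] - r[i, j]) ** 2
            for x, r in ((x1, r1), (x2, r2))
            for i in range(3)
            for j in range(2)
        )
        got = float(reconstruction_loss(x1, x2, Tensor(r1), Tensor(r2)).data)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="shapes"):
            reconstruction_loss(np.ones((3, 2)), np.ones((3, 2)),
                                Tensor(np.ones((3, 3))), Tensor(np.ones((3, 2))))


class TestCosine:
    def test_identical_orthogonal_scaled(self):
        v = np.array([1.0, 2.0, 3.0])
        assert cosine_similarity(v, v) == pytest.approx(1.0)
        assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)
        assert cosine_similarity(v, 3 * v) == pytest.approx(1.0)

    def test_zero_vector_floored(self):
        assert np.isfinite(cosine_similarity(np.zeros(3), np.ones(3)))


def _contrastive_loop_oracle(h_hat, h1, h2, s, T, denominator="as_printed"):
    """Independent scalar re-implementation with explicit loops."""
    def unit(v):
        return v / max(np.linalg.norm(v), 1e-12)

    n = h_hat.shape[0]
    total = 0.0
    for i in range(n):
        for hm in (h1, h2):
            pos = np.exp(unit(h_hat[i]) @ unit(hm[i]) / T)
            den = sum(
                np.exp((1 - s[i, j]) * (unit(h_hat[i]) @ unit(hm[j])) / T)
                for j in range(n)
            )
            if denominator == "as_printed":
                den -= np.exp(1 / T)
            else:
                den -= np.exp((1 - s[i, i]) * (unit(h_hat[i]) @ unit(hm[i])) / T)
            total += np.log(pos / max(den, 1e-8))
    return -total / (2 * n)


class TestContrastive:
    @pytest.mark.parametrize("denominator", ["as_printed", "drop_self"])
    def test_matches_loop_oracle(self, rng, denominator):
        n, d = 6, 5
        h_hat, h1, h2 = (rng.normal(size=(n, d)) for _ in range(3))
        s = _random_stochastic(rng, n, n)
        loss, _ = contrastive_loss(Tensor(h_hat), Tensor(h1), Tensor(h2),
                                   Tensor(s), 0.5, denominator)
        expected = _contrastive_loop_oracle(h_hat, h1, h2, s, 0.5, denominator)
        assert float(loss.data) == pytest.approx(expected, rel=1e-10)

    def test_single_aligned_cell_takes_clamp_branch(self):
        """n=1 with h1 = h2 = h_hat: denominator is 1 - e^{1/T} < 0, clamped."""
        h = Tensor(np.array([[1.0, 0.0]]))
        s = Tensor(np.array([[1.0]]))
        loss, clamped = contrastive_loss(h, h, h, s, temperature=0.5)
        assert clamped == 2  # both modalities
        assert np.isfinite(float(loss.data))

    def test_scale_invariance(self, rng):
        n, d = 5, 4
        h_hat, h1, h2 = (rng.normal(size=(n, d)) for _ in range(3))
        s = _random_stochastic(rng, n, n)
        a, _ = contrastive_loss(Tensor(h_hat), Tensor(h1), Tensor(h2), Tensor(s), 0.5)
        b, _ = contrastive_loss(Tensor(3.7 * h_hat), Tensor(3.7 * h1),
                                Tensor(3.7 * h2), Tensor(s), 0.5)
        assert float(a.data) == pytest.approx(float(b.data), abs=1e-6)

    def test_temperature_enters_only_via_self_term_when_sims_vanish(self, rng):
        """With all-orthogonal embeddings (D = 0), the loss depends on T only
        through the subtracted e^{1/T}: loss = log(n - e^{1/T} clamped)."""
        n = 4
        basis = np.eye(2 * n)
        h_hat = Tensor(basis[:n])      # spans first n coordinates
        h1 = Tensor(basis[n:])         # orthogonal complement: every D_ij = 0
        h2 = Tensor(basis[n:])
        s = Tensor(np.full((n, n), 1 / n))
        for T in (0.5, 1.0):
            loss, _ = contrastive_loss(h_hat, h1, h2, s, T)
            expected = np.log(max(n - np.exp(1 / T), 1e-8))
            assert float(loss.data) == pytest.approx(expected, rel=1e-10)

    def test_non_stochastic_s_rejected(self, rng):
        h = Tensor(rng.normal(size=(3, 2)))
        with pytest.raises(ValueError, match="row-stochastic"):
            contrastive_loss(h, h, h, Tensor(np.ones((3, 3))), 0.5)


class TestSoftClusteringLoss:
    def test_gamma_equals_q_gives_zero(self, rng):
        g = _random_stochastic(rng, 5, 3)
        assert float(soft_clustering_loss(g, Tensor(g)).data) == pytest.approx(0.0, abs=1e-12)

    def test_one_hot_vs_uniform_is_log2(self):
        g = np.array([[1.0, 0.0]])
        q = Tensor(np.array([[0.5, 0.5]]))
        assert float(soft_clustering_loss(g, q).data) == pytest.approx(np.log(2))

    def test_matches_double_loop(self, rng):
        g = _random_stochastic(rng, 5, 3)
        q = _random_stochastic(rng, 5, 3)
        expected = sum(
            g[i, j] * np.log(g[i, j] / q[i, j]) for i in range(5) for j in range(3)
        )
        got = float(soft_clustering_loss(g, Tensor(q)).data)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_nonnegative_on_random_instances(self, rng):
        for _ in range(200):
            n, k = int(rng.integers(2, 8)), int(rng.integers(2, 5))
            g = _random_stochastic(rng, n, k)
            q = _random_stochastic(rng, n, k)
            assert float(soft_clustering_loss(g, Tensor(q)).data) >= -1e-12

    def test_non_stochastic_rejected(self, rng):
        with pytest.raises(ValueError, match="row-stochastic"):
            soft_clustering_loss(np.ones((3, 2)), Tensor(_random_stochastic(rng, 3, 2)))

    def test_gamma_receives_no_gradient(self, rng):
        h = Tensor(rng.normal(size=(4, 3)), requires_grad=True)
        centers = Tensor(rng.normal(size=(2, 3)), requires_grad=True)
        q = student_t_q(h, centers)
        g = _random_stochastic(rng, 4, 2)
        soft_clustering_loss(g, q).backward()
        assert h.grad is not None and centers.grad is not None


def test_dec_target_kl_nonnegative_and_zero_at_fixed_point(rng):
    q = _random_stochastic(rng, 6, 3)
    val = float(dec_target_kl(Tensor(q)).data)
    assert val >= -1e-12
    uniform_fp = np.full((4, 2), 0.5)  # p == q when q is its own target
    assert float(dec_target_kl(Tensor(uniform_fp)).data) == pytest.approx(0.0, abs=1e-12)


class TestTotalLoss:
    def test_arithmetic(self):
        w = LossWeights(alpha=0.1, beta=1.0, temperature=0.5)
        assert total_loss(1.0, 2.0, 3.0, w) == pytest.approx(4.2)

    def test_ablation_identity(self):
        w = LossWeights(alpha=0.0, beta=0.0, temperature=0.5)
        assert total_loss(7.5, 100.0, 100.0, w) == 7.5

    def test_sweep_grid_gives_sixteen_distinct_totals(self):
        grid = [0.01, 0.1, 1.0, 10.0]
        totals = {
            total_loss(1.0, 2.0, 3.0, LossWeights(alpha=a, beta=b, temperature=0.5))
            for a in grid
            for b in grid
        }
        assert len(totals) == 16

    def test_invalid_temperature(self):
        with pytest.raises(ValueError):
            LossWeights(temperature=0.0)


class TestGradientChecks:
    """Autodiff gradients of each loss match central finite differences."""

    @staticmethod
    def _check(build, x0, rel_tol=1e-3):
        t = Tensor(x0, requires_grad=True)
        build(t).backward()
        g = t.grad.copy()
        num = np.zeros_like(x0)
        eps = 1e-6
        for idx in np.ndindex(*x0.shape):
            xp, xm = x0.copy(), x0.copy()
            xp[idx] += eps
            xm[idx] -= eps
            num[idx] = (
                float(build(Tensor(xp, requires_grad=True)).data)
                - float(build(Tensor(xm, requires_grad=True)).data)
            ) / (2 * eps)
        scale = max(np.abs(num).max(), 1e-8)
        assert np.abs(g - num).max() / scale < rel_tol

    def test_reconstruction_gradient(self, rng):
        x1, x2 = rng.normal(size=(4, 3)), rng.normal(size=(4, 2))
        r2 = rng.normal(size=(4, 2))
        self._check(
            lambda t: reconstruction_loss(x1, x2, t, Tensor(r2)),
            rng.normal(size=(4, 3)),
        )

    def test_contrastive_gradient(self, rng):
        n, d = 5, 4
        h1, h2 = rng.normal(size=(n, d)), rng.normal(size=(n, d))
        s = _random_stochastic(rng, n, n)
        self._check(
            lambda t: contrastive_loss(t, Tensor(h1), Tensor(h2), Tensor(s), 0.5)[0],
            rng.normal(size=(n, d)),
        )

    def test_soft_loss_gradient_through_student_t(self, rng):
        centers = rng.normal(size=(3, 4))
        g = _random_stochastic(rng, 5, 3)
        self._check(
            lambda t: soft_clustering_loss(g, student_t_q(t, Tensor(centers))),
            rng.normal(size=(5, 4)),
        )
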