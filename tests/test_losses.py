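"""Loss components against hand evaluations and brute-force oracles."""

import numpy as np
import pytest

from hms.losses import (BridgeLossWeights, FocalConfig, bridge_composite,
                        co_activation_penalty, coral_loss, focal_bce,
                        kl_align_loss, mmd_loss, nt_xent,
                        pairwise_alignment_losses, prototype_loss)
from hms.nn import Tensor

PLAIN = FocalConfig(alpha=1.0, gamma=0.0, label_smoothing=0.0)


class TestFocalBCE:
    def test_reduces_to_mean_bce(self, rng):
        logits = rng.normal(scale=3, size=(1000, 4))
        y = rng.integers(0, 2, size=(1000, 4)).astype(float)
        p = 1 / (1 + np.exp(-logits))
        bce = -(y * np.log(p) + (1 - y) * np.log(1 - p)).mean()
        assert focal_bce(logits, y, PLAIN).item() == pytest.approx(bce, abs=1e-10)

    def test_hand_values(self):
        # p=0.9, y=1, gamma 0 -> -ln 0.9
        logit = np.log(0.9 / 0.1)
        assert focal_bce([[logit]], [[1.0]], PLAIN).item() == \
            pytest.approx(-np.log(0.9), abs=1e-9)
        # logit 0 (p=0.5), y=1, gamma 2 -> 0.25 * ln 2
        cfg = FocalConfig(alpha=1.0, gamma=2.0, label_smoothing=0.0)
        assert focal_bce([[0.0]], [[1.0]], cfg).item() == \
            pytest.approx(0.25 * np.log(2), abs=1e-12)

    def test_perfect_fit_limit(self):
        logits = np.array([[40.0, -40.0]])
        y = np.array([[1.0, 0.0]])
        assert focal_bce(logits, y, PLAIN).item() < 1e-12

    def test_saturated_logits_keep_finite_gradients(self):
        t = Tensor(np.array([[-60.0, 60.0]]), requires_grad=True)
        loss = focal_bce(t, np.array([[1.0, 0.0]]),
                         FocalConfig(alpha=1.0, gamma=2.0, label_smoothing=0.0))
        loss.backward()
        assert np.all(np.isfinite(t.grad))
        assert t.grad[0, 0] < 0  # positive label still pulls the logit up

    def test_label_smoothing_mixture(self):
        cfg = FocalConfig(alpha=1.0, gamma=0.0, label_smoothing=0.1)
        logit, y = 1.3, 1.0
        p = 1 / (1 + np.exp(-logit))
        ys = y * 0.9 + 0.05
        expect = -(ys * np.log(p) + (1 - ys) * np.log(1 - p))
        assert focal_bce([[logit]], [[y]], cfg).item() == \
            pytest.approx(expect, abs=1e-10)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            FocalConfig(gamma=-1.0)
        with pytest.raises(ValueError):
            focal_bce(np.zeros((2, 3)), np.zeros((2, 4)))


class TestCoActivation:
    def test_values_and_bounds(self):
        assert co_activation_penalty([0.0, 0.0], [0.5, 1.0]).item() == 0.0
        assert co_activation_penalty([1.0, 0.5], [1.0, 0.2]).item() == \
            pytest.approx(0.55)
        assert co_activation_penalty([1.0, 1.0], [1.0, 1.0]).item() == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            co_activation_penalty([0.1], [0.1, 0.2])


class TestNTXent:
    def test_hand_value(self):
        u = np.array([1.0, 0, 0, 0])
        negs = np.array([[0, 1.0, 0, 0], [0, 0, 1.0, 0]])
        assert nt_xent(u, u, negs, tau=1.0).item() == \
            pytest.approx(np.log(1 + 2 / np.e), abs=1e-12)

    def test_separation_limit(self):
        u = np.array([1.0, 0.0])
        negs = np.array([[-1.0, 0.0]])
        assert nt_xent(u, u, negs, tau=1e-3).item() < 1e-12

    def test_matches_softmax_ce_oracle(self, rng):
        q = rng.normal(size=(8, 16))
        q /= np.linalg.norm(q, axis=1, keepdims=True)
        k = rng.normal(size=(8, 16))
        k /= np.linalg.norm(k, axis=1, keepdims=True)
        queue = rng.normal(size=(16, 16))
        queue /= np.linalg.norm(queue, axis=1, keepdims=True)
        tau = 0.2
        # independent oracle: softmax cross-entropy with positive at index 0
        losses = []
        for i in range(8):
            logits = np.concatenate([[q[i] @ k[i]], q[i] @ queue.T]) / tau
            logits -= logits.max()
            losses.append(-(logits[0] - np.log(np.exp(logits).sum())))
        assert nt_xent(q, k, queue, tau).item() == \
            pytest.approx(np.mean(losses), abs=1e-6)

    def test_temperature_must_be_positive(self):
        with pytest.raises(ValueError):
            nt_xent(np.ones(2), np.ones(2), np.ones((1, 2)), tau=0.0)


class TestPairwiseAlignment:
    def test_identity_and_hand_values(self):
        mse, cos = pairwise_alignment_losses(np.array([1.0, 2.0]),
                                             np.array([1.0, 2.0]))
        assert mse.item() == 0.0 and cos.item() == pytest.approx(0.0, abs=1e-9)
        mse, cos = pairwise_alignment_losses(np.array([1.0, 0.0]),
                                             np.array([0.0, 1.0]))
        assert mse.item() == pytest.approx(1.0)
        assert cos.item() == pytest.approx(1.0, abs=1e-9)

    def test_antiparallel_attains_bound(self):
        _, cos = pairwise_alignment_losses(np.array([0.0, 1.0]),
                                           np.array([0.0, -1.0]))
        assert cos.item() == pytest.approx(2.0, abs=1e-9)


class TestKL:
    def test_zero_on_equal(self, rng):
        U = rng.normal(size=(5, 7))
        assert kl_align_loss(U, U).item() == pytest.approx(0.0, abs=1e-12)

    def test_hand_value(self):
        u = np.array([0.0, 0.0])
        v = np.array([np.log(3.0), 0.0])
        expect = 0.5 * np.log(0.5 / 0.75) + 0.5 * np.log(0.5 / 0.25)
        assert kl_align_loss(u, v).item() == pytest.approx(expect, abs=1e-12)

    def test_nonnegative(self, rng):
        U = rng.normal(size=(100, 6))
        V = rng.normal(size=(100, 6))
        assert kl_align_loss(U, V).item() >= 0.0


class TestMMD:
    def test_zero_on_identical(self, rng):
        X = rng.normal(size=(6, 3))
        assert abs(mmd_loss(X, X).item()) < 1e-10

    def test_hand_value_fixed_sigma(self):
        X = np.array([[0.0]])
        Y = np.array([[1.0]])
        assert mmd_loss(X, Y, sigma=1.0).item() == \
            pytest.approx(2 - 2 * np.exp(-0.5), abs=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        X = rng.normal(size=(5, 3))
        Y = rng.normal(size=(5, 3))
        sigma = 0.7

        def k(a, b):
            return np.exp(-np.sum((a - b) ** 2) / (2 * sigma**2))

        def mean_k(A, B):
            return np.mean([[k(a, b) for b in B] for a in A])

        oracle = mean_k(X, X) + mean_k(Y, Y) - 2 * mean_k(X, Y)
        assert mmd_loss(X, Y, sigma=sigma).item() == \
            pytest.approx(oracle, abs=1e-10)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            mmd_loss(np.zeros((0, 2)), np.ones((3, 2)))


class TestCORAL:
    def test_zero_on_identical(self, rng):
        X = rng.normal(size=(6, 4))
        assert coral_loss(X, X).item() == pytest.approx(0.0, abs=1e-12)

    def test_hand_value_1d(self):
        X = np.array([[2**-0.5], [-(2**-0.5)]])   # var 1 (n-1 denominator)
        Y = np.array([[0.0], [0.0]])              # var 0
        assert coral_loss(X, Y).item() == pytest.approx(0.25, abs=1e-12)

    def test_matches_covariance_oracle(self, rng):
        X = rng.normal(size=(9, 4))
        Y = rng.normal(size=(7, 4))
        cx = np.cov(X, rowvar=False)
        cy = np.cov(Y, rowvar=False)
        oracle = ((cx - cy) ** 2).sum() / (4 * 16)
        assert coral_loss(X, Y).item() == pytest.approx(oracle, abs=1e-10)

    def test_needs_two_rows(self):
        with pytest.raises(ValueError):
            coral_loss(np.ones((1, 2)), np.ones((3, 2)))


class TestPrototype:
    def test_zero_at_prototypes(self):
        protos = {0: np.array([1.0, 0.0]), 1: np.array([0.0, 1.0])}
        E = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert prototype_loss(E, [0, 1], protos).item() == 0.0

    def test_hand_value(self):
        assert prototype_loss(np.array([[1.0, 0.0]]), [0],
                              {0: np.zeros(2)}).item() == pytest.approx(1.0)

    def test_convex_along_interpolation(self, rng):
        protos = {0: rng.normal(size=4), 1: rng.normal(size=4)}
        labels = rng.integers(0, 2, size=10)
        E = rng.normal(size=(10, 4))
        P = np.stack([protos[int(l)] for l in labels])
        values = [prototype_loss(E + t * (P - E), labels, protos).item()
                  for t in np.linspace(0, 1, 6)]
        assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))

    def test_missing_prototype(self):
        with pytest.raises(KeyError):
            prototype_loss(np.ones((1, 2)), [3], {0: np.zeros(2)})


class TestComposite:
    def test_zero_components(self):
        comps = {k: 0.0 for k in BridgeLossWeights.COMPONENTS}
        assert bridge_composite(comps, BridgeLossWeights()).item() == 0.0

    def test_default_weights_and_linearity(self):
        w = BridgeLossWeights()
        assert w.infonce == 1.0 and w.mse == 10.0
        comps = {k: 0.0 for k in BridgeLossWeights.COMPONENTS}
        comps["mse"] = 0.1
        assert bridge_composite(comps, w).item() == pytest.approx(1.0)

    def test_drop_zeroes_exactly_one(self):
        w = BridgeLossWeights().drop("proto")
        assert w.proto == 0.0
        assert w.mse == 10.0 and w.infonce == 1.0 and w.kl == 0.5
        with pytest.raises(KeyError):
            BridgeLossWeights().drop("nope")

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            BridgeLossWeights(mse=-1.0)


def test_all_losses_zero_on_perfect_alignment_and_differentiable(rng):
    """Shared invariants: >= 0 everywhere, 0 at perfect alignment, finite
    gradients under the epsilon guards."""
    U = rng.normal(size=(6, 5))
    losses = {
        "mse+cos": lambda A, B: sum(pairwise_alignment_losses(A, B)),
        "kl": kl_align_loss,
        "mmd": mmd_loss,
        "coral": coral_loss,
    }
    for name, fn in losses.items():
        assert fn(Tensor(U), Tensor(U)).item() == pytest.approx(0.0, abs=1e-9)
        A = Tensor(rng.normal(size=(6, 5)), requires_grad=True)
        val = fn(A, Tensor(U))
        assert val.item() >= -1e-12
        val.backward()
        assert np.all(np.isfinite(A.grad))
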