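"""Dynamic-margin sub-center ArcFace: margins, cosines, logits, loss."""

import numpy as np
import pytest

from hemafuse import (LossConfig, SubcenterArcFace, compute_margins,
                      margin_logits, subcenter_cosines)
from hemafuse.autodiff import Tensor

from oracles import naive_margin_loss, naive_subcenter_cosines, softmax_cross_entropy


class TestMarginSchedule:
    def test_rarest_class_gets_upper_bound(self):
        table = compute_margins([1], a=0.5, b=0.05)
        assert table.margins[0] == pytest.approx(0.5)

    def test_abundant_classes_approach_lower_bound(self):
        table = compute_margins([10**8])
        assert table.margins[0] == pytest.approx(0.05, abs=1e-3)

    def test_thousand_sample_class_matches_direct_evaluation(self):
        table = compute_margins([1000])
        assert table.margins[0] == pytest.approx(0.45 / np.sqrt(1000) + 0.05,
                                                 rel=1e-12)

    def test_margins_non_increasing_in_count(self):
        counts = np.array([1, 3, 10, 50, 400, 5000])
        m = compute_margins(counts).margins
        assert np.all(np.diff(m) <= 0)
        assert np.all((m >= 0.05) & (m <= 0.5))

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            compute_margins([10, 0, 5])

    def test_bounds_must_be_ordered(self):
        with pytest.raises(ValueError):
            compute_margins([5], a=0.05, b=0.5)


class TestSubcenterCosines:
    def test_aligned_unit_vectors_give_cosine_one(self):
        w = np.zeros((2, 1, 3))
        w[0, 0, 0] = 1.0
        w[1, 0, 1] = 1.0
        cos = subcenter_cosines(np.array([1.0, 0, 0]), w)
        assert cos[0] == pytest.approx(1.0, abs=1e-6)
        assert cos[1] == pytest.approx(0.0, abs=1e-12)

    def test_max_rule_picks_best_subcenter(self):
        # sub-centers at cosines 0.2, 0.9, -0.5 to x (constructed in 2-D)
        angles = np.arccos([0.2, 0.9, -0.5])
        w = np.stack([[np.cos(a), np.sin(a)] for a in angles])[None]
        cos = subcenter_cosines(np.array([1.0, 0.0]), w)
        assert cos[0] == pytest.approx(0.9, abs=1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(size=5)
            w = rng.normal(size=(4, 3, 5))
            assert np.allclose(subcenter_cosines(x, w),
                               naive_subcenter_cosines(x, w), atol=1e-12)

    def test_cosines_invariant_to_embedding_scale(self, rng):
        x = rng.normal(size=6)
        w = rng.normal(size=(3, 2, 6))
        assert np.allclose(subcenter_cosines(x, w),
                           subcenter_cosines(7.3 * x, w))

    def test_zero_embedding_rejected(self):
        with pytest.raises(ValueError):
            subcenter_cosines(np.zeros(4), np.ones((2, 1, 4)))


class TestMarginLogits:
    def test_zero_margin_is_plain_scaling(self, rng):
        cos = rng.uniform(-0.9, 0.9, size=5)
        out = margin_logits(cos, target=2, m=0.0, s=64.0)
        assert np.allclose(out, 64.0 * cos)

    def test_aligned_target_with_half_margin(self):
        cos = np.array([1.0, 0.0])
        out = margin_logits(cos, target=0, m=0.5, s=64.0)
        assert out[0] == pytest.approx(64 * np.cos(0.5), rel=1e-9)  # ~56.158
        assert out[1] == 0.0

    def test_margin_strictly_decreases_target_logit(self, rng):
        for _ in range(20):
            theta = rng.uniform(0.05, np.pi - 0.6)
            cos = np.array([np.cos(theta), 0.1])
            with_m = margin_logits(cos, 0, m=0.5, s=64.0)
            without = margin_logits(cos, 0, m=0.0, s=64.0)
            assert with_m[0] < without[0]
            assert with_m[1] == without[1]


class TestLoss:
    def _head(self, rng, n=4, k=3, d=8):
        return SubcenterArcFace(n, k, d, rng)

    def test_closed_form_two_class_case(self, rng):
        head = SubcenterArcFace(2, 1, 2, rng)
        head.subcenters.data = np.array([[[1.0, 0.0]], [[0.0, 1.0]]])
        emb = Tensor(np.array([[1.0, 0.0]]))
        loss = head.loss(emb, [0], np.zeros(2), s=1.0)
        assert loss.item() == pytest.approx(-np.log(np.e / (np.e + 1)),
                                            abs=1e-5)

    def test_zero_margin_single_center_equals_cross_entropy(self, rng):
        head = self._head(rng, k=1)
        for _ in range(10):
            emb = rng.normal(size=(6, 8))
            labels = rng.integers(0, 4, size=6)
            loss = head.loss(Tensor(emb), labels, np.zeros(4), s=64.0)
            cos = np.stack([subcenter_cosines(e, head.subcenters.data)
                            for e in emb])
            assert loss.item() == pytest.approx(
                softmax_cross_entropy(64.0 * cos, labels), rel=1e-9)

    def test_matches_naive_transcription(self, rng):
        """Dual-route check against explicit arccos/exponential arithmetic."""
        for _ in range(100):
            n = int(rng.integers(2, 6))
            k = int(rng.integers(1, 4))
            d = int(rng.integers(2, 9))
            b = int(rng.integers(1, 17))
            head = SubcenterArcFace(n, k, d, rng)
            emb = rng.normal(size=(b, d))
            labels = rng.integers(0, n, size=b)
            margins = rng.uniform(0.0, 0.5, size=n)
            ours = head.loss(Tensor(emb), labels, margins, s=64.0).item()
            ref = naive_margin_loss(emb, labels, head.subcenters.data,
                                    margins, 64.0)
            assert ours == pytest.approx(ref, rel=1e-6)

    def test_margin_never_reduces_the_loss(self, rng):
        head = self._head(rng)
        for _ in range(20):
            emb = rng.normal(size=(5, 8))
            labels = rng.integers(0, 4, size=5)
            with_m = head.loss(Tensor(emb), labels,
                               np.full(4, 0.3), s=64.0).item()
            without = head.loss(Tensor(emb), labels, np.zeros(4), s=64.0).item()
            assert with_m >= without - 1e-10

    def test_gradient_matches_finite_differences(self, rng):
        head = self._head(rng, n=3, k=2, d=5)
        emb0 = rng.normal(size=(2, 5))
        labels = np.array([0, 2])
        margins = np.array([0.2, 0.3, 0.1])
        emb = Tensor(emb0, requires_grad=True)
        head.loss(emb, labels, margins, s=8.0).backward()
        eps = 1e-6
        num = np.zeros_like(emb0)
        for i in range(2):
            for j in range(5):
                for sign in (1, -1):
                    pert = emb0.copy()
                    pert[i, j] += sign * eps
                    val = head.loss(Tensor(pert), labels, margins, s=8.0).item()
                    num[i, j] += sign * val / (2 * eps)
        assert np.allclose(emb.grad, num, atol=1e-5)

    def test_out_of_range_label_rejected(self, rng):
        head = self._head(rng)
        with pytest.raises(IndexError):
            head.loss(Tensor(rng.normal(size=(1, 8))), [7], np.zeros(4))

    def test_loss_config_validation(self):
        with pytest.raises(ValueError):
            LossConfig(s=-1)
        with pytest.raises(ValueError):
            LossConfig(sub_centers=0)
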