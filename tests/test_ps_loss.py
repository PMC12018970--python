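"""The alignment + cross-entropy objective and its learnable combination."""

import numpy as np
import pytest

from poultrans import autodiff as ad
from poultrans import ps_loss as pl
from poultrans.autodiff import Linear, Tensor
from poultrans.fixtures import generate_alignment_batch


class TestMapImageFeatures:
    def test_zero_params_map_to_zero(self, rng):
        mapper = Linear(8, 4, rng)
        mapper.weight.data[:] = 0.0
        mapper.bias.data[:] = 0.0
        out = pl.map_image_features(Tensor(rng.normal(size=(3, 8))), mapper)
        np.testing.assert_array_equal(out.data, np.zeros((3, 4)))

    def test_default_output_dimension_is_1198(self):
        cfg = pl.PSLossConfig()
        aligner = pl.ImageTextAligner(cfg, text_dim=16)
        out = pl.map_image_features(Tensor(np.zeros((2, 2048))), aligner.mapper)
        assert out.shape == (2, 1198)

    def test_matches_explicit_matrix_multiply_oracle(self, rng):
        mapper = Linear(5, 3, rng)
        x = rng.normal(size=(4, 5))
        got = pl.map_image_features(Tensor(x), mapper).data
        expected = np.zeros((4, 3))
        for i in range(4):
            for j in range(3):
                expected[i, j] = sum(x[i, k] * mapper.weight.data[k, j] for k in range(5)) + mapper.bias.data[j]
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_dim_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="dim"):
            pl.map_image_features(Tensor(np.zeros((2, 7))), Linear(5, 3, rng))


class TestSimilarityMatrix:
    def test_scaled_copies_give_unit_diagonal(self, rng):
        i = rng.normal(size=(3, 6))
        t = 2.5 * i
        s = pl.similarity_matrix(Tensor(i), Tensor(t)).data
        np.testing.assert_allclose(np.diag(s), 1.0)

    def test_orthogonal_pair_scores_zero(self):
        s = pl.similarity_matrix(Tensor(np.array([[1.0, 0.0]])), Tensor(np.array([[0.0, 1.0]]))).data
        assert s[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_dot_norm_loop_oracle(self, rng):
        i = rng.normal(size=(3, 4))
        t = rng.normal(size=(3, 4))
        s = pl.similarity_matrix(Tensor(i), Tensor(t)).data
        for a in range(3):
            for b in range(3):
                expected = i[a] @ t[b] / (np.linalg.norm(i[a]) * np.linalg.norm(t[b]))
                assert s[a, b] == pytest.approx(expected, abs=1e-9)

    def test_entries_bounded_by_one(self, rng):
        s = pl.similarity_matrix(Tensor(rng.normal(size=(5, 8))), Tensor(rng.normal(size=(5, 8)))).data
        assert np.all(np.abs(s) <= 1 + 1e-9)


class TestImageMappingLoss:
    def test_identity_similarity_gives_zero(self):
        assert pl.image_mapping_loss(Tensor(np.eye(2)), margin=0.2).item() == pytest.approx(0.0)

    def test_single_element_matrix(self):
        assert pl.image_mapping_loss(Tensor(np.array([[0.5]]))).item() == pytest.approx(0.5)

    def test_enumerated_two_by_two_case(self):
        s = np.array([[0.9, 0.5], [0.3, 0.8]])
        # row 0: (1-0.9) + max(0, 0.5-0.2) = 0.4 ; row 1: (1-0.8) + max(0, 0.3-0.2) = 0.3
        assert pl.image_mapping_loss(Tensor(s), margin=0.2).item() == pytest.approx(0.35)

    def test_nonnegative_when_similarities_at_most_one(self, rng):
        s = np.clip(rng.normal(size=(4, 4)), -1, 1)
        assert pl.image_mapping_loss(Tensor(s)).item() >= 0

    def test_monotone_in_entries(self):
        base = np.array([[0.9, 0.5], [0.3, 0.8]])
        l0 = pl.image_mapping_loss(Tensor(base)).item()
        up_off = base.copy()
        up_off[0, 1] += 0.05  # off-diagonal above margin -> loss strictly increases
        assert pl.image_mapping_loss(Tensor(up_off)).item() > l0
        up_diag = base.copy()
        up_diag[0, 0] += 0.05  # diagonal up -> loss strictly decreases
        assert pl.image_mapping_loss(Tensor(up_diag)).item() < l0

    def test_off_diagonals_below_margin_incur_no_hinge(self):
        s = np.array([[1.0, 0.19], [0.15, 1.0]])
        assert pl.image_mapping_loss(Tensor(s), margin=0.2).item() == pytest.approx(0.0)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            pl.image_mapping_loss(Tensor(np.zeros((2, 3))))


class TestTextCrossEntropy:
    def test_perfect_prediction_gives_zero(self):
        logits = np.full((1, 2, 4), -50.0)
        logits[0, 0, 1] = 50.0
        logits[0, 1, 2] = 50.0
        loss = pl.text_cross_entropy(Tensor(logits), np.array([[1, 2]]), np.ones((1, 2)))
        assert loss.item() == pytest.approx(0.0, abs=1e-9)

    def test_known_probability_closed_form(self):
        # construct logits whose softmax puts exactly e^-2 on the target
        p_true = np.exp(-2.0)
        other = (1 - p_true) / 2
        logits = np.log(np.array([[[p_true, other, other]]]))
        loss = pl.text_cross_entropy(Tensor(logits), np.array([[0]]), np.ones((1, 1)))
        assert loss.item() == pytest.approx(2.0, abs=1e-9)

    def test_matches_masked_loop_oracle(self, rng):
        logits = rng.normal(size=(2, 3, 5))
        targets = rng.integers(0, 5, size=(2, 3))
        mask = np.array([[1, 1, 0], [1, 0, 0]], dtype=float)
        got = pl.text_cross_entropy(Tensor(logits), targets, mask).item()
        total, n = 0.0, 0
        for b in range(2):
            for t in range(3):
                if mask[b, t]:
                    p = np.exp(logits[b, t]) / np.exp(logits[b, t]).sum()
                    total += -np.log(p[targets[b, t]])
                    n += 1
        assert got == pytest.approx(total / n, abs=1e-9)

    def test_all_pad_rejected(self):
        with pytest.raises(ValueError):
            pl.text_cross_entropy(Tensor(np.zeros((1, 2, 3))), np.zeros((1, 2), dtype=int), np.zeros((1, 2)))


class TestPoolTextFeatures:
    def test_single_token_returns_its_embedding(self, rng):
        emb = rng.normal(size=(1, 3, 4))
        mask = np.array([[1, 0, 0]], dtype=float)
        np.testing.assert_allclose(pl.pool_text_features(Tensor(emb), mask).data[0], emb[0, 0])

    def test_duplicate_tokens_average_to_themselves(self, rng):
        row = rng.normal(size=4)
        emb = np.stack([row, row])[None]
        out = pl.pool_text_features(Tensor(emb), np.ones((1, 2)))
        np.testing.assert_allclose(out.data[0], row)

    def test_matches_loop_oracle(self, rng):
        emb = rng.normal(size=(2, 4, 3))
        mask = np.array([[1, 1, 0, 0], [1, 1, 1, 0]], dtype=float)
        got = pl.pool_text_features(Tensor(emb), mask).data
        for b in range(2):
            rows = [emb[b, t] for t in range(4) if mask[b, t]]
            np.testing.assert_allclose(got[b], np.mean(rows, axis=0), atol=1e-12)


class TestCombinedLoss:
    def test_half_half_weighting(self):
        w = pl.LossWeights("fixed", (0.5, 0.5))
        out = pl.combined_loss(Tensor(np.array(0.4)), Tensor(np.array(1.0)), w)
        assert out.item() == pytest.approx(0.7)

    def test_degenerate_fixed_ratio_limit(self):
        w = pl.LossWeights("fixed", (1.0, 1e-12))
        out = pl.combined_loss(Tensor(np.array(0.4)), Tensor(np.array(1.0)), w)
        assert out.item() == pytest.approx(0.4, abs=1e-9)

    def test_learnable_weights_start_at_half_and_stay_normalized(self):
        w = pl.LossWeights("learnable")
        assert w.lambdas == pytest.approx((0.5, 0.5))
        w.logits.data = np.array([2.0, -1.0])
        li, lt = w.lambdas
        assert 0 < li < 1 and 0 < lt < 1 and li + lt == pytest.approx(1.0)

    def test_weight_gradient_matches_finite_difference(self):
        w = pl.LossWeights("learnable")
        li, lt = Tensor(np.array(0.8)), Tensor(np.array(0.3))
        pl.combined_loss(li, lt, w).backward()
        got = w.logits.grad.copy()
        eps = 1e-6
        for k in range(2):
            orig = w.logits.data[k]
            w.logits.data[k] = orig + eps
            up = pl.combined_loss(li, lt, w).item()
            w.logits.data[k] = orig - eps
            down = pl.combined_loss(li, lt, w).item()
            w.logits.data[k] = orig
            assert got[k] == pytest.approx((up - down) / (2 * eps), abs=1e-6)


class TestAlignerTraining:
    def test_ideal_fixture_drives_loss_below_threshold(self):
        """On noise-free aligned features, 100 Adam steps on the mapping layer
        push the alignment loss under 0.01."""
        img, txt, _ = generate_alignment_batch(8, 32, 16, noise_sd=0.0, seed=5)
        cfg = pl.PSLossConfig(image_dim=32, map_dim=16)
        aligner = pl.ImageTextAligner(cfg, text_dim=16, rng=np.random.default_rng(2))
        # text side enters pre-pooled; identity projection isolates the mapping layer
        aligner.text_proj.weight.data = np.eye(16)
        aligner.text_proj.bias.data[:] = 0.0
        opt = ad.Adam([{"params": [aligner.mapper.weight, aligner.mapper.bias], "lr": 0.05}])
        for _ in range(100):
            opt.zero_grad()
            loss = aligner.alignment_loss(Tensor(img), Tensor(txt))
            loss.backward()
            opt.step()
        assert loss.item() < 0.01

    def test_lambda_weights_remain_valid_across_200_steps(self):
        img, txt, _ = generate_alignment_batch(6, 16, 16, noise_sd=0.1, seed=3)
        aligner = pl.ImageTextAligner(pl.PSLossConfig(image_dim=16, map_dim=8), text_dim=16)
        opt = ad.Adam([{"params": aligner.parameters(), "lr": 0.01}])
        for _ in range(200):
            opt.zero_grad()
            l_img = aligner.alignment_loss(Tensor(img), Tensor(txt))
            total = aligner.total_loss(l_img, Tensor(np.array(1.3)))
            total.backward()
            opt.step()
            li, lt = aligner.weights.lambdas
            assert 0 < li < 1 and 0 < lt < 1
            assert li + lt == pytest.approx(1.0)

    def test_seeded_subsampling_keeps_matched_pairs(self, rng):
        cfg = pl.PSLossConfig(image_dim=16, map_dim=8, sample_fraction=0.5)
        aligner = pl.ImageTextAligner(cfg, text_dim=16)
        img, txt, _ = generate_alignment_batch(8, 16, 16, seed=0)
        a = aligner.alignment_loss(Tensor(img), Tensor(txt), np.random.default_rng(4)).item()
        b = aligner.alignment_loss(Tensor(img), Tensor(txt), np.random.default_rng(4)).item()
        assert a == pytest.approx(b)
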