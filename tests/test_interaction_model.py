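import numpy as np
import pytest

from dtakit.encoding import (
    DRUG_VOCAB,
    PROTEIN_VOCAB,
    EncoderOutput,
    TokenSequence,
    tokenize_drug,
    tokenize_protein,
)
from dtakit.errors import ConfigError, DomainError, ShapeError
from dtakit.interaction_model import (
    CrossAttentionRegressor,
    ModelConfig,
    build_additive_mask,
    masked_mha,
    masked_mean_pool,
    mse_loss,
    project,
)
from dtakit.nn import Linear, MaskedMultiHeadAttention, NEG_INF, Tensor


def brute_force_attention(q, k, v, key_mask, block):
    """Loop-based reference attention (explicit heads and positions)."""
    H, dk, d = block.n_heads, block.d_k, block.d_model
    Wq, bq = block.Wq.W.data, block.Wq.b.data
    Wk, bk = block.Wk.W.data, block.Wk.b.data
    Wv, bv = block.Wv.W.data, block.Wv.b.data
    Wo, bo = block.Wo.W.data, block.Wo.b.data
    Q = q @ Wq + bq
    K = k @ Wk + bk
    V = v @ Wv + bv
    Lq, Lk = q.shape[0], k.shape[0]
    heads = []
    for h in range(H):
        sl = slice(h * dk, (h + 1) * dk)
        out_h = np.zeros((Lq, dk))
        for i in range(Lq):
            logits = np.empty(Lk)
            for j in range(Lk):
                logits[j] = Q[i, sl] @ K[j, sl] / np.sqrt(dk)
                if key_mask[j] == 0:
                    logits[j] = -np.inf
            w = np.exp(logits - np.max(logits[key_mask > 0]))
            w[key_mask == 0] = 0.0
            w /= w.sum()
            for j in range(Lk):
                out_h[i] += w[j] * V[j, sl]
        heads.append(out_h)
    return np.concatenate(heads, axis=1) @ Wo + bo


class TestProjection:
    def test_identity_projection_preserves_hidden(self, rng):
        h = rng.normal(size=(1, 4, 3))
        layer = Linear(3, 3, rng, "p")
        layer.W.data = np.eye(3)
        layer.b.data = np.zeros(3)
        z, mask = project(EncoderOutput(Tensor(h), np.ones((1, 4))), layer)
        assert np.allclose(z.data, h)

    def test_bias_only_projection(self, rng):
        layer = Linear(3, 3, rng, "p")
        layer.W.data = np.zeros((3, 3))
        layer.b.data = np.ones(3)
        z, _ = project(EncoderOutput(Tensor(np.zeros((1, 2, 3))), np.ones((1, 2))), layer)
        assert np.allclose(z.data, 1.0)

    def test_width_mismatch_is_shape_error(self, rng):
        layer = Linear(4, 5, rng, "p")
        with pytest.raises(ShapeError):
            project(EncoderOutput(Tensor(np.zeros((1, 2, 3))), np.ones((1, 2))), layer)


class TestAdditiveMask:
    def test_masked_key_column_is_negative_infinity_surrogate(self):
        m = build_additive_mask(np.array([1.0, 1.0, 0.0]), L_q=2)
        assert m.shape == (2, 3)
        assert np.all(m[:, :2] == 0.0)
        assert np.all(m[:, 2] == -NEG_INF)

    def test_all_valid_mask_is_zero_matrix(self):
        assert np.all(build_additive_mask(np.ones(4), L_q=3) == 0.0)

    def test_no_valid_keys_rejected(self):
        with pytest.raises(ValueError):
            build_additive_mask(np.zeros(2), L_q=1)


class TestMaskedMHA:
    def test_equal_logits_average_the_two_valid_values(self, rng):
        block = MaskedMultiHeadAttention(2, 1, rng, "attn")
        for lin in (block.Wq, block.Wk, block.Wv, block.Wo):
            lin.W.data = np.eye(2)
            lin.b.data = np.zeros(2)
        q = np.zeros((1, 2))  # zero queries -> all logits equal
        k = rng.normal(size=(3, 2))
        v = np.array([[1.0, 5.0], [3.0, 7.0], [100.0, 100.0]])
        mask = build_additive_mask(np.array([1.0, 1.0, 0.0]), L_q=1)
        out = masked_mha(q, k, v, mask, block)
        assert np.allclose(out.data, [[2.0, 6.0]])

    def test_perturbing_masked_value_leaves_output_bit_identical(self, rng):
        block = MaskedMultiHeadAttention(4, 2, rng, "attn")
        q = rng.normal(size=(2, 4))
        k = rng.normal(size=(3, 4))
        v = rng.normal(size=(3, 4))
        mask = build_additive_mask(np.array([1.0, 0.0, 1.0]), L_q=2)
        out1 = masked_mha(q, k, v, mask, block).data
        v2 = v.copy()
        v2[1] = 1e6
        k2 = k.copy()
        k2[1] = -1e6
        out2 = masked_mha(q, k2, v2, mask, block).data
        assert np.array_equal(out1, out2)

    def test_attention_weights_sum_to_one_over_valid_keys(self, rng):
        block = MaskedMultiHeadAttention(4, 2, rng, "attn")
        block.capture_weights = True
        key_mask = np.array([[1.0, 1.0, 0.0, 1.0]])
        block(Tensor(rng.normal(size=(1, 2, 4))),
              Tensor(rng.normal(size=(1, 4, 4))),
              Tensor(rng.normal(size=(1, 4, 4))), key_mask)
        w = block.last_weights
        assert np.allclose(w.sum(axis=-1), 1.0, atol=1e-6)
        assert np.all(w[..., 2] == 0.0)

    @pytest.mark.parametrize("trial", range(3))
    def test_matches_brute_force_on_random_instances(self, rng, trial):
        block = MaskedMultiHeadAttention(4, 2, rng, "attn")
        q = rng.normal(size=(4, 4))
        k = rng.normal(size=(4, 4))
        v = rng.normal(size=(4, 4))
        key_mask = np.array([1.0, 1.0, 1.0, 0.0]) if trial else np.ones(4)
        mask = build_additive_mask(key_mask, L_q=4)
        ours = masked_mha(q, k, v, mask, block).data
        ref = brute_force_attention(q, k, v, key_mask, block)
        assert np.allclose(ours, ref, atol=1e-5)


class TestInteractionModes:
    @staticmethod
    def _model(mode):
        m = CrossAttentionRegressor(
            ModelConfig(d_model=8, n_heads=2, head_widths=(8,), dropout=0.0,
                        interaction_mode=mode, seed=3)
        )
        m.eval()
        return m

    def test_mode_none_pools_projected_latents_directly(self, rng):
        model = self._model("none")
        z_d = Tensor(rng.normal(size=(1, 3, 8)))
        z_p = Tensor(rng.normal(size=(1, 5, 8)))
        out_d, out_p = model.cross_attend(z_d, z_p, np.ones((1, 3)), np.ones((1, 5)))
        assert out_d is z_d and out_p is z_p

    def test_mode_d_to_p_leaves_protein_side_untouched(self, rng):
        model = self._model("d_to_p")
        z_d = Tensor(rng.normal(size=(1, 3, 8)))
        z_p = Tensor(rng.normal(size=(1, 5, 8)))
        out_d, out_p = model.cross_attend(z_d, z_p, np.ones((1, 3)), np.ones((1, 5)))
        assert out_p is z_p
        assert not np.array_equal(out_d.data, z_d.data)

    def test_unknown_mode_is_config_error(self):
        with pytest.raises(ConfigError):
            ModelConfig(interaction_mode="sideways")


class TestPooling:
    def test_hand_computed_masked_mean(self):
        z = Tensor(np.array([[[1.0, 1.0], [3.0, 3.0], [9.0, 9.0]]]))
        out = masked_mean_pool(z, np.array([[1.0, 1.0, 0.0]]))
        assert np.allclose(out.data, [[2.0, 2.0]])

    def test_all_valid_equals_row_mean(self, rng):
        z = rng.normal(size=(1, 4, 3))
        out = masked_mean_pool(Tensor(z), np.ones((1, 4)))
        assert np.allclose(out.data, z.mean(axis=1))

    def test_appending_padded_rows_changes_nothing(self, rng):
        z = rng.normal(size=(1, 3, 4))
        pooled = masked_mean_pool(Tensor(z), np.ones((1, 3))).data
        z_padded = np.concatenate([z, rng.normal(size=(1, 100, 4))], axis=1)
        mask = np.concatenate([np.ones((1, 3)), np.zeros((1, 100))], axis=1)
        pooled_padded = masked_mean_pool(Tensor(z_padded), mask).data
        assert np.allclose(pooled, pooled_padded)

    def test_all_masked_rejected(self):
        with pytest.raises(ValueError):
            masked_mean_pool(Tensor(np.zeros((1, 2, 2))), np.zeros((1, 2)))


class TestEndToEnd:
    def test_constant_head_predicts_its_bias(self, tiny_model):
        model = tiny_model
        saved = model.head.out.b.data.copy()
        savedW = model.head.out.W.data.copy()
        try:
            model.head.out.W.data[:] = 0.0
            model.head.out.b.data[:] = 4.25
            assert model.predict_pair("CCO", "MKLV") == pytest.approx(4.25)
            assert model.predict_pair("c1ccccc1", "ACDEFGHIKLMNP") == pytest.approx(4.25)
        finally:
            model.head.out.b.data = saved
            model.head.out.W.data = savedW

    def test_padding_invariance_is_exact(self, tiny_model):
        drug = tokenize_drug("CC(=O)Nc1ccccc1").padded(64, DRUG_VOCAB.pad_id)
        protein = tokenize_protein("MKLVHGWYDEACDEF").padded(
            128, PROTEIN_VOCAB.pad_id
        )
        base = tiny_model.predict_tokens([drug], [protein])[0]
        # corrupt the masked positions with arbitrary content ids
        d_pad = TokenSequence(drug.ids.copy(), drug.mask.copy(), "drug")
        p_pad = TokenSequence(protein.ids.copy(), protein.mask.copy(), "protein")
        d_pad.ids[int(drug.mask.sum()):] = DRUG_VOCAB.index["C"]
        p_pad.ids[int(protein.mask.sum()):] = PROTEIN_VOCAB.index["W"]
        corrupted = tiny_model.predict_tokens([d_pad], [p_pad])[0]
        assert corrupted == base

    def test_batch_equivalence(self, tiny_model):
        drugs = [tokenize_drug(s) for s in ("CCO", "c1ccccc1CC(=O)N", "C(F)(F)C")]
        prots = [tokenize_protein(s) for s in ("MKLV", "ACDEFGHIKLMNPQRSTVWY", "WWHH")]
        batch = tiny_model.predict_tokens(drugs, prots)
        singles = [
            tiny_model.predict_tokens([d], [p])[0] for d, p in zip(drugs, prots)
        ]
        assert np.allclose(batch, singles, atol=1e-5)

    def test_mode_none_equals_pooled_projection_pipeline(self):
        cfg = dict(d_model=8, n_heads=2, head_widths=(8,), dropout=0.0, seed=5)
        none_model = CrossAttentionRegressor(
            ModelConfig(interaction_mode="none", **cfg)
        )
        none_model.eval()
        drug = tokenize_drug("CCO")
        protein = tokenize_protein("MKLVH")
        got = none_model.predict_tokens([drug], [protein])[0]
        # manual pipeline: encode -> project -> pool -> concat -> head
        from dtakit.nn import concat

        enc_d = none_model.drug_encoder(drug.ids[None], drug.mask[None])
        enc_p = none_model.protein_encoder(protein.ids[None], protein.mask[None])
        z_d, m_d = project(enc_d, none_model.proj_drug)
        z_p, m_p = project(enc_p, none_model.proj_protein)
        r = concat([masked_mean_pool(z_d, m_d), masked_mean_pool(z_p, m_p)], axis=-1)
        manual = none_model.head(r).data.ravel()[0]
        assert got == pytest.approx(manual, abs=1e-12)


class TestMSELoss:
    def test_zero_when_equal(self):
        assert float(mse_loss([1.0, 2.0], Tensor(np.array([1.0, 2.0]))).data) == 0.0

    def test_unit_residuals(self):
        assert float(mse_loss([0.0, 0.0], Tensor(np.array([1.0, 1.0]))).data) == 1.0

    def test_single_pair_squared(self):
        assert float(mse_loss([2.0], Tensor(np.array([5.0]))).data) == 9.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(DomainError):
            mse_loss([1.0, 2.0], Tensor(np.array([1.0])))
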