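import numpy as np
import pytest

from _oracles import loop_enhanced_attention, loop_multihead
from slimfuse import model as M
from slimfuse.features import FeatureMatrix


def _ea_params(D, seed, variant="matmul", zero=False):
    p = M.EnhancedAttentionParams.init(D, seed, variant)
    if zero:
        for name in ("WQ", "WK", "WV", "WO"):
            getattr(p, name)[:] = 0.0
    return p


def _layernorm_rows(X):
    mu = X.mean(axis=1, keepdims=True)
    inv = 1.0 / np.sqrt(X.var(axis=1, keepdims=True) + 1e-5)
    return (X - mu) * inv


# ---------------------------------------------------------------------------
# enhanced attention
# ---------------------------------------------------------------------------


class TestEnhancedAttention:
    @pytest.mark.parametrize("variant", ["matmul", "elementwise"])
    def test_zero_weights_collapse_to_layernorm(self, variant):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5, 6))
        p = _ea_params(6, 1, variant, zero=True)
        Y = M.enhanced_attention_forward(X, p)
        assert np.array_equal(Y, _layernorm_rows(X))

    def test_single_position_closed_form(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(1, 4))
        p = _ea_params(4, 3, "matmul")
        Y = M.enhanced_attention_forward(x, p)
        expected = _layernorm_rows(x + x @ p.WV @ p.WO)
        assert np.allclose(Y, expected, atol=1e-12)

    @pytest.mark.parametrize("variant", ["matmul", "elementwise"])
    @pytest.mark.parametrize("seed", range(12))
    def test_matches_loop_oracle(self, variant, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(3, 7))
        D = int(rng.integers(4, 9))
        X = rng.normal(size=(L, D))
        p = _ea_params(D, seed + 100, variant)
        Y = M.enhanced_attention_forward(X, p)
        ref = loop_enhanced_attention(
            X, p.WQ, p.WK, p.WV, p.WO, p.ln_gain, p.ln_bias, variant
        )
        assert np.abs(Y - ref).max() < 1e-5
        assert Y.shape == X.shape  # input/output dims strictly consistent

    def test_output_rows_normalized_before_gain(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(6, 8))
        Y = M.enhanced_attention_forward(X, _ea_params(8, 5))
        # default gain=1, bias=0: rows are mean 0, variance 1
        assert np.abs(Y.mean(axis=1)).max() < 1e-4
        assert np.abs(Y.var(axis=1) - 1).max() < 1e-3

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            M.enhanced_attention_forward(np.zeros((3, 5)), _ea_params(4, 0))


# ---------------------------------------------------------------------------
# fusion
# ---------------------------------------------------------------------------


def _fm(seq_id, source, values, prefix):
    return FeatureMatrix(
        seq_id, source, values,
        [f"{prefix}{j}" for j in range(values.shape[1])],
    )


class TestFuseConcat:
    def test_default_widths_give_256(self):
        rng = np.random.default_rng(0)
        fused = M.fuse_concat(
            _fm("a", "seqfea", rng.normal(size=(4, 128)), "pc"),
            _fm("a", "pssm", rng.normal(size=(4, 20)), "ps"),
            _fm("a", "phy", rng.normal(size=(4, 108)), "ph"),
        )
        assert fused.width == 256 and fused.source == "fused"

    def test_row_alignment_and_channel_prefixes(self):
        rng = np.random.default_rng(1)
        blocks = [rng.normal(size=(5, w)) for w in (3, 2, 4)]
        fused = M.fuse_concat(
            _fm("a", "seqfea", blocks[0], "pc"),
            _fm("a", "pssm", blocks[1], "ps"),
            _fm("a", "phy", blocks[2], "ph"),
        )
        perm = np.array([4, 2, 0, 1, 3])
        fused_p = M.fuse_concat(
            _fm("a", "seqfea", blocks[0][perm], "pc"),
            _fm("a", "pssm", blocks[1][perm], "ps"),
            _fm("a", "phy", blocks[2][perm], "ph"),
        )
        assert np.array_equal(fused.values[perm], fused_p.values)
        assert fused.channel_names[0].startswith("seqfea:")
        assert fused.channel_names[3].startswith("pssm:")
        assert fused.channel_names[5].startswith("phy:")

    def test_length_mismatch_names_block(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError, match="'phy'"):
            M.fuse_concat(
                _fm("a", "seqfea", rng.normal(size=(4, 3)), "pc"),
                _fm("a", "pssm", rng.normal(size=(4, 2)), "ps"),
                _fm("a", "phy", rng.normal(size=(5, 2)), "ph"),
            )


class TestMultihead:
    def test_matches_loop_oracle(self):
        for seed in range(8):
            rng = np.random.default_rng(seed)
            L = int(rng.integers(3, 7))
            p = M.FusionParams.init(8, heads=4, seed=seed)
            X = rng.normal(size=(L, 8))
            Y = M.multihead_forward(X, p)
            ref = loop_multihead(X, p.WQ, p.WK, p.WV, p.WO, p.ln_gain, p.ln_bias, 4)
            assert np.abs(Y - ref).max() < 1e-5

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        p = M.FusionParams.init(12, heads=4, seed=1)
        X = rng.normal(size=(6, 12))
        perm = rng.permutation(6)
        Y = M.multihead_forward(X, p)
        Yp = M.multihead_forward(X[perm], p)
        assert np.allclose(Y[perm], Yp, atol=1e-10)

    def test_masked_position_content_is_ignored(self):
        rng = np.random.default_rng(4)
        p = M.FusionParams.init(8, heads=2, seed=2)
        X = rng.normal(size=(5, 8))
        mask = np.array([True, True, False, True, True])
        Y1 = M.multihead_forward(X, p, mask)
        X2 = X.copy()
        X2[2] = rng.normal(size=8) * 50
        Y2 = M.multihead_forward(X2, p, mask)
        unmasked = mask.nonzero()[0]
        assert np.allclose(Y1[unmasked], Y2[unmasked], atol=1e-10)

    def test_default_heads_and_mask_errors(self):
        assert M.FusionParams.init(256, 4, 0).heads == 4
        p = M.FusionParams.init(8, 2, 0)
        with pytest.raises(ValueError, match="mask"):
            M.multihead_forward(np.zeros((3, 8)), p, mask=np.ones(4, bool))
        with pytest.raises(ValueError, match="divisible"):
            M.FusionParams.init(10, 4, 0)


# ---------------------------------------------------------------------------
# MLP head
# ---------------------------------------------------------------------------


class TestMLP:
    def test_probabilities_normalize(self):
        rng = np.random.default_rng(0)
        p = M.MLPParams.init(6, 4, 2, seed=1)
        P = M.mlp_forward(rng.normal(size=(10, 6)), p)
        assert np.abs(P.sum(axis=1) - 1).max() < 1e-6
        assert (P >= 0).all()

    def test_zero_weights_give_half_half(self):
        p = M.MLPParams(np.zeros((6, 4)), np.zeros(4), np.zeros((4, 2)), np.zeros(2))
        P = M.mlp_forward(np.ones(6), p)
        assert np.allclose(P, [0.5, 0.5])

    def test_hand_computed_toy(self):
        # 2-d input, 1 hidden unit, pencil-and-paper forward pass
        p = M.MLPParams(
            W1=np.array([[1.0], [2.0]]), b1=np.array([0.5]),
            W2=np.array([[1.0, -1.0]]), b2=np.array([0.0, 0.25]),
        )
        x = np.array([1.0, -1.0])
        a1 = 1.0 - 2.0 + 0.5  # -0.5
        from math import erf, exp, sqrt

        h = 0.5 * a1 * (1 + erf(a1 / sqrt(2)))
        z = np.array([h, -h + 0.25])
        e = np.exp(z - z.max())
        expected = e / e.sum()
        assert np.allclose(M.mlp_forward(x, p), expected, atol=1e-6)

    def test_shape_mismatch(self):
        p = M.MLPParams.init(6, 4, 2, seed=0)
        with pytest.raises(ValueError):
            M.mlp_forward(np.zeros(5), p)

    def test_dropout_only_when_active(self):
        rng = np.random.default_rng(5)
        p = M.MLPParams.init(6, 32, 2, seed=2)
        x = rng.normal(size=(4, 6))
        assert np.array_equal(M.mlp_forward(x, p), M.mlp_forward(x, p))
        drop = M.mlp_forward(
            x, p, dropout_active=True, dropout=0.5, rng=np.random.default_rng(0)
        )
        assert not np.allclose(drop, M.mlp_forward(x, p))


# ---------------------------------------------------------------------------
# gradients
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("variant", ["matmul", "elementwise"])
def test_full_model_gradients_match_finite_differences(variant):
    rng = np.random.default_rng(0)
    bundle = M.init_bundle(
        seqfea_dim=5, phy_dim=4, pssm_dim=3, heads=2, hidden=6,
        variant=variant, config=M.TrainConfig(seed=3),
    )
    L = 7
    feats = M.SequenceFeatures(
        seq_id="t",
        blocks={
            "seqfea": rng.normal(size=(L, 5)),
            "pssm": rng.normal(size=(L, 3)),
            "phy": rng.normal(size=(L, 4)),
        },
        labels=rng.integers(0, 2, L),
        loss_idx=np.array([0, 2, 3, 6]),
    )

    def loss_of():
        Z, caches = M._forward_seq(bundle, feats)
        loss, dZ = M._loss_and_grad_logits(Z, feats.labels, feats.loss_idx)
        return loss / len(feats.loss_idx), dZ, caches

    params = bundle.parameters()
    _, dZ, caches = loss_of()
    grads = M._backward_seq(bundle, feats, dZ / len(feats.loss_idx), caches)
    eps = 1e-6
    for name, arr in params.items():
        idxs = [tuple(rng.integers(0, s) for s in arr.shape) for _ in range(3)]
        for ix in idxs:
            orig = arr[ix]
            arr[ix] = orig + eps
            lp, _, _ = loss_of()
            arr[ix] = orig - eps
            lm, _, _ = loss_of()
            arr[ix] = orig
            fd = (lp - lm) / (2 * eps)
            rel = abs(fd - grads[name][ix]) / max(1e-8, abs(fd) + abs(grads[name][ix]))
            assert rel < 1e-4, f"gradient mismatch in {name}[{ix}]"


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------


def _separable_dataset(n_seqs=6, L=30, seed=0):
    """Tiny sequences whose first seqfea channel encodes the label."""
    rng = np.random.default_rng(seed)
    seqs = []
    for i in range(n_seqs):
        labels = (rng.random(L) < 0.3).astype(int)
        seqfea = rng.normal(size=(L, 4)) * 0.1
        seqfea[:, 0] = labels * 2.0 - 1.0
        seqs.append(
            M.SequenceFeatures(
                seq_id=f"s{i}",
                blocks={
                    "seqfea": seqfea,
                    "pssm": rng.normal(size=(L, 2)) * 0.1,
                    "phy": rng.normal(size=(L, 2)) * 0.1,
                },
                labels=labels,
                loss_idx=np.arange(L),
            )
        )
    return seqs


def _tiny_bundle(seed=0, epochs=10):
    return M.init_bundle(
        seqfea_dim=4, phy_dim=2, pssm_dim=2, heads=2, hidden=8,
        config=M.TrainConfig(epochs=epochs, seed=seed, batch_sequences=3),
    )


class TestTraining:
    def test_zero_epochs_leaves_parameters_untouched(self):
        bundle = _tiny_bundle(epochs=0)
        before = {k: v.copy() for k, v in bundle.parameters().items()}
        trained, history = M.train(bundle, _separable_dataset(), None)
        assert history == []
        for k, v in trained.parameters().items():
            assert np.array_equal(v, before[k])

    def test_learns_separable_features(self):
        from slimfuse.evaluation import ScoreSet, roc_auc

        seqs = _separable_dataset()
        bundle = _tiny_bundle(epochs=50)
        trained, history = M.train(bundle, seqs, None)
        scores = np.concatenate([M.predict(trained, f) for f in seqs])
        labels = np.concatenate([f.labels for f in seqs])
        _, auc = roc_auc(ScoreSet(scores, labels))
        assert auc >= 0.99
        assert history[-1]["train_loss"] < history[0]["train_loss"]

    def test_seeded_runs_identical(self):
        seqs = _separable_dataset()
        h1 = M.train(_tiny_bundle(seed=5, epochs=5), seqs, seqs[:2])[1]
        h2 = M.train(_tiny_bundle(seed=5, epochs=5), seqs, seqs[:2])[1]
        assert h1 == h2  # bitwise identical loss/AUC histories

    def test_empty_loss_set_errors(self):
        seqs = _separable_dataset()
        for f in seqs:
            f.loss_idx = np.array([], dtype=np.int64)
        with pytest.raises(ValueError, match="loss residues"):
            M.train(_tiny_bundle(epochs=1), seqs, None)


class TestPredict:
    def test_deterministic_and_valid(self):
        seqs = _separable_dataset()
        bundle = _tiny_bundle(epochs=3)
        trained, _ = M.train(bundle, seqs, None)
        p1 = M.predict(trained, seqs[0])
        p2 = M.predict(trained, seqs[0])
        assert np.array_equal(p1, p2)
        assert ((p1 >= 0) & (p1 <= 1)).all()

    def test_missing_block_errors(self):
        bundle = _tiny_bundle()
        feats = M.SequenceFeatures("x", {"seqfea": np.zeros((3, 4))})
        with pytest.raises(ValueError, match="lack blocks"):
            M.predict(bundle, feats)

    def test_wrong_width_errors(self):
        bundle = _tiny_bundle()
        feats = M.SequenceFeatures(
            "x",
            {
                "seqfea": np.zeros((3, 4)),
                "pssm": np.zeros((3, 2)),
                "phy": np.zeros((3, 5)),
            },
        )
        with pytest.raises(ValueError, match="'phy'"):
            M.predict(bundle, feats)


def test_bundle_save_load_round_trip(tmp_path):
    bundle = _tiny_bundle(seed=9)
    bundle.save(tmp_path / "m")
    loaded = M.ModelBundle.load(tmp_path / "m")
    for k, v in bundle.parameters().items():
        assert np.array_equal(v, loaded.parameters()[k])
    assert loaded.blocks == bundle.blocks
    assert loaded.fusion.heads == bundle.fusion.heads
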