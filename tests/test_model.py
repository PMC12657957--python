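"""Model-core checks: the attention equations against a dense oracle, the
two-head construction, the evaluation formulas against brute-force
implementations, and the loss gradient against finite differences."""

import math

import numpy as np
import pytest
from scipy import stats

from ribodwell.autodiff import Tensor, no_grad
from ribodwell.model import (
    DwellModel,
    ModelConfig,
    maape,
    mse,
    pcc,
    relative_encoding,
    sample_loss,
    scc,
)

NAN = float("nan")


# ---------------------------------------------------------------------------
# embeddings


def test_zeroed_embeddings_give_zero_input(tiny_model64):
    m = DwellModel(ModelConfig(d_model=16, n_heads=2, dtype="float64"))
    m.params["codon_emb"].data[:] = 0
    m.params["cond_emb"].data[:] = 0
    x = m.embed(np.array([[1, 2, 3]]), np.array([0]))
    assert np.all(x.data == 0)


def test_condition_changes_input_by_constant_vector(tiny_model64):
    m = tiny_model64
    tokens = np.array([[5, 9, 33]])
    a = m.embed(tokens, np.array([1])).data
    b = m.embed(tokens, np.array([3])).data
    diff = b - a
    # the same condition-embedding difference at every position
    np.testing.assert_allclose(diff, np.broadcast_to(diff[:, :1, :], diff.shape), atol=1e-12)


def test_permuting_codons_permutes_embeddings(tiny_model64):
    tokens = np.array([[3, 17, 60, 22]])
    perm = [2, 0, 3, 1]
    a = tiny_model64.embed(tokens, np.array([2])).data
    b = tiny_model64.embed(tokens[:, perm], np.array([2])).data
    np.testing.assert_array_equal(a[:, perm, :], b)


# ---------------------------------------------------------------------------
# relative attention vs. dense oracle


def dense_attention_oracle(xn, Wq, Wke, Wv, Wkr, u, v):
    """Loop evaluation of e_ij/alpha_ij/h_i for a single head, with the same
    1/sqrt(d_head) scaling applied to the query side."""
    n, D = xn.shape
    dist = np.arange(-(n - 1), n)
    inv_freq = 1.0 / (10000.0 ** (np.arange(0, D, 2) / D))
    R = np.zeros((2 * n - 1, D))
    R[:, 0::2] = np.sin(dist[:, None] * inv_freq)
    R[:, 1::2] = np.cos(dist[:, None] * inv_freq)
    scale = 1.0 / math.sqrt(D)
    e = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            r = R[i - j + n - 1] @ Wkr
            e[i, j] = scale * (
                (xn[i] @ Wq + u) @ (xn[j] @ Wke) + (xn[i] @ Wq + v) @ r
            )
    alpha = np.exp(e - e.max(axis=1, keepdims=True))
    alpha /= alpha.sum(axis=1, keepdims=True)
    h = alpha @ (xn @ Wv)
    return alpha, h


def test_one_layer_one_head_matches_dense_oracle(rng):
    cfg = ModelConfig(d_model=8, n_layers=1, n_heads=1, d_ff=16, dtype="float64", seed=3)
    m = DwellModel(cfg)
    xn = rng.normal(size=(1, 3, 8))
    with no_grad():
        ctx, alpha = m._attend(Tensor(xn), 0, None)
    P = {k: v.data for k, v in m.params.items()}
    alpha_o, h_o = dense_attention_oracle(
        xn[0],
        P["layer0.Wq"],
        P["layer0.Wke"],
        P["layer0.Wv"],
        P["layer0.Wkr"],
        P["layer0.u"][0],
        P["layer0.v"][0],
    )
    np.testing.assert_allclose(alpha[0, 0], alpha_o, atol=1e-12)
    np.testing.assert_allclose(ctx.data[0], h_o, atol=1e-12)


def test_attention_rows_normalize(tiny_model64, rng):
    xn = rng.normal(size=(2, 12, 16))
    with no_grad():
        _, alpha = tiny_model64._attend(Tensor(xn), 0, None)
    np.testing.assert_allclose(alpha.sum(axis=-1), 1.0, atol=1e-6)


def test_single_position_attention_is_identity_weighted(rng):
    cfg = ModelConfig(d_model=8, n_layers=1, n_heads=1, d_ff=16, dtype="float64", seed=1)
    m = DwellModel(cfg)
    xn = rng.normal(size=(1, 1, 8))
    with no_grad():
        ctx, alpha = m._attend(Tensor(xn), 0, None)
    assert alpha[0, 0, 0, 0] == pytest.approx(1.0)
    np.testing.assert_allclose(ctx.data[0, 0], xn[0, 0] @ m.params["layer0.Wv"].data, atol=1e-12)


def test_zero_length_sequence_rejected(tiny_model64):
    with pytest.raises(ValueError):
        tiny_model64.forward(np.zeros((1, 0), dtype=int), np.array([0]))


# ---------------------------------------------------------------------------
# heads and prediction


def test_dc_identity_bit_exact(tiny_model64, rng):
    from ribodwell.core_io import CODONS, CodonSequence

    seq = CodonSequence("g", tuple(CODONS[i] for i in rng.integers(0, 61, 15)))
    p = tiny_model64.predict(seq, "LEU_ILE")
    np.testing.assert_array_equal(p.y_dc, p.y_ctrl + p.y_delta)


def test_zero_readout_weights_give_zero_outputs(rng):
    m = DwellModel(ModelConfig(d_model=16, n_heads=2, dtype="float64"))
    for k in ("head_ctrl_w", "head_ctrl_b", "head_delta_w", "head_delta_b"):
        m.params[k].data[:] = 0
    yc, yd = m.fast_forward(rng.integers(0, 64, (1, 6)), np.array([2]))
    assert np.all(yc == 0) and np.all(yd == 0)


def test_fast_forward_matches_tape_forward(tiny_model64, rng):
    tokens = rng.integers(0, 64, (3, 11))
    conds = np.array([0, 2, 5])
    mask = np.ones((3, 11), bool)
    mask[1, 8:] = False
    with no_grad():
        yc, yd = tiny_model64.forward(tokens, conds, mask)
    fc, fd = tiny_model64.fast_forward(tokens, conds, mask)
    np.testing.assert_allclose(yc.data, fc, atol=1e-12)
    np.testing.assert_allclose(yd.data, fd, atol=1e-12)


def test_birnn_backbone_contract(rng):
    m = DwellModel(ModelConfig(d_model=12, n_layers=1, backbone="birnn", dtype="float64"))
    tokens = rng.integers(0, 64, (2, 7))
    yc, yd = m.forward(tokens, np.array([0, 3]))
    assert yc.shape == (2, 7) and yd.shape == (2, 7)
    loss = sample_loss(rng.random(7), rng.random(7), rng.random(7), yc[0], yd[0])
    loss.backward()
    assert m.params["layer0.fwd_Wx"].grad is not None


# ---------------------------------------------------------------------------
# metrics


class TestMetrics:
    def test_pcc_perfect_and_inverted(self):
        y = [1.0, 2.0, 3.0]
        assert pcc(y, y) == pytest.approx(1.0)
        assert pcc(y, [-v for v in y]) == pytest.approx(-1.0)

    def test_pcc_against_textbook_oracle(self):
        y, yh = np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 4.0])
        expected = np.corrcoef(y, yh)[0, 1]
        assert pcc(y, yh) == pytest.approx(expected, abs=1e-12)

    def test_pcc_degenerate_returns_nan(self):
        assert np.isnan(pcc([1.0, 1.0], [1.0, 2.0]))
        assert np.isnan(pcc([1.0], [1.0]))

    def test_pcc_pairwise_missing_exclusion(self):
        y = [1.0, NAN, 3.0, 4.0]
        yh = [1.0, 2.0, NAN, 4.0]
        assert pcc(y, yh) == pytest.approx(pcc([1.0, 4.0], [1.0, 4.0]))

    def test_maape_examples(self):
        assert maape([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert maape([1.0, 1.0], [2.0, 2.0]) == pytest.approx(100 * np.arctan(1.0))

    def test_maape_bounded(self, rng):
        y, yh = rng.random(100), rng.random(100) * 100
        assert 0 <= maape(y, yh) <= 100 * np.pi / 2

    def test_mse_and_scc_identical_vectors(self):
        y = [3.0, 1.0, 2.0]
        assert mse(y, y) == 0.0
        assert scc(y, y) == pytest.approx(1.0)

    def test_scc_rank_invariance(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert scc(y, np.exp(y)) == pytest.approx(1.0)

    def test_scc_against_scipy_oracle_with_ties(self, rng):
        y = np.array([1.0, 2.0, 2.0, 3.0, 0.5])
        yh = np.array([0.3, 0.1, 2.0, 2.0, 0.4])
        assert scc(y, yh) == pytest.approx(stats.spearmanr(y, yh).statistic, abs=1e-12)


# ---------------------------------------------------------------------------
# loss


def loss_oracle(y_ctrl, y_delta, y_dc, pc, pd):
    """Independent term-by-term evaluation of the training loss."""
    pdc = pc + pd
    total = 3.0
    for t, p in ((y_ctrl, pc), (y_delta, pd), (y_dc, pdc)):
        m = ~np.isnan(t)
        if m.sum() >= 2 and np.std(t[m]) > 0:
            total -= np.corrcoef(t[m], p[m])[0, 1]
    m = ~np.isnan(y_dc)
    total += np.abs(y_dc[m] - pdc[m]).mean()
    return total


def test_loss_zero_at_perfect_prediction(rng):
    y_ctrl = rng.random(12)
    y_delta = rng.normal(size=12)
    y_dc = y_ctrl + y_delta
    L = sample_loss(y_ctrl, y_delta, y_dc, Tensor(y_ctrl), Tensor(y_delta))
    assert float(L.data) == pytest.approx(0.0, abs=1e-9)


def test_loss_anticorrelated_prediction(rng):
    y_ctrl = rng.random(10)
    y_delta = rng.normal(size=10)
    y_dc = y_ctrl + y_delta
    pc, pd = Tensor(-y_ctrl), Tensor(-y_delta)
    L = float(sample_loss(y_ctrl, y_delta, y_dc, pc, pd).data)
    mae = np.abs(2 * y_dc).mean()
    assert L == pytest.approx(3 + 3 + mae, abs=1e-9)


def test_loss_matches_oracle_with_missing(rng):
    for _ in range(10):
        y_ctrl = rng.random(30)
        y_dc = rng.random(30)
        y_ctrl[rng.random(30) < 0.25] = np.nan
        y_dc[rng.random(30) < 0.25] = np.nan
        y_delta = y_dc - y_ctrl
        pc, pd = rng.normal(size=30), rng.normal(size=30)
        L = float(sample_loss(y_ctrl, y_delta, y_dc, Tensor(pc), Tensor(pd)).data)
        assert L == pytest.approx(loss_oracle(y_ctrl, y_delta, y_dc, pc, pd), abs=1e-6)


def test_loss_permutation_equivariance(rng):
    y_ctrl, y_dc = rng.random(20), rng.random(20)
    y_delta = y_dc - y_ctrl
    pc, pd = rng.normal(size=20), rng.normal(size=20)
    L1 = float(sample_loss(y_ctrl, y_delta, y_dc, Tensor(pc), Tensor(pd)).data)
    perm = rng.permutation(20)
    L2 = float(
        sample_loss(y_ctrl[perm], y_delta[perm], y_dc[perm], Tensor(pc[perm]), Tensor(pd[perm])).data
    )
    assert L1 == pytest.approx(L2, abs=1e-12)


def test_loss_degenerate_target_contributes_zero():
    y_ctrl = np.ones(5)  # zero variance: r term skipped
    y_delta = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
    y_dc = y_ctrl + y_delta
    L = float(sample_loss(y_ctrl, y_delta, y_dc, Tensor(y_ctrl), Tensor(y_delta)).data)
    assert L == pytest.approx(1.0, abs=1e-9)  # 3 - 0 - 1 - 1 + 0


def test_loss_gradient_matches_finite_differences(rng):
    y_ctrl = rng.random(10)
    y_dc = rng.random(10)
    y_ctrl[3] = np.nan
    y_delta = y_dc - y_ctrl
    pc0, pd0 = rng.normal(size=10), rng.normal(size=10)

    pc, pd = Tensor(pc0.copy(), requires_grad=True), Tensor(pd0.copy(), requires_grad=True)
    sample_loss(y_ctrl, y_delta, y_dc, pc, pd).backward()

    eps = 1e-6
    for leaf, base, grad in ((0, pc0, pc.grad), (1, pd0, pd.grad)):
        for i in range(10):
            bumped = [pc0.copy(), pd0.copy()]
            bumped[leaf][i] += eps
            up = float(sample_loss(y_ctrl, y_delta, y_dc, Tensor(bumped[0]), Tensor(bumped[1])).data)
            bumped[leaf][i] -= 2 * eps
            dn = float(sample_loss(y_ctrl, y_delta, y_dc, Tensor(bumped[0]), Tensor(bumped[1])).data)
            fd = (up - dn) / (2 * eps)
            assert fd == pytest.approx(grad[i], rel=1e-4, abs=1e-7)


def test_model_parameter_gradient_matches_finite_differences(rng):
    cfg = ModelConfig(d_model=16, n_layers=2, n_heads=2, d_ff=32, dtype="float64", seed=1)
    m = DwellModel(cfg)
    tokens = rng.integers(0, 64, (1, 10))
    conds = np.array([3])
    y_ctrl, y_dc = rng.random(10), rng.random(10)
    y_delta = y_dc - y_ctrl

    def f():
        yc, yd = m.forward(tokens, conds)
        return sample_loss(y_ctrl, y_delta, y_dc, yc[0], yd[0])

    f().backward()
    eps = 1e-6
    for name in ("layer0.Wkr", "layer1.ff_W1", "codon_emb", "head_delta_w"):
        p = m.params[name]
        idx = tuple(ax // 2 for ax in p.data.shape)
        g = p.grad[idx]
        p.data[idx] += eps
        up = float(f().data)
        p.data[idx] -= 2 * eps
        dn = float(f().data)
        p.data[idx] += eps
        assert (up - dn) / (2 * eps) == pytest.approx(g, rel=1e-4, abs=1e-8)


def test_relative_encoding_symmetries():
    R = relative_encoding(5, 8)
    assert R.shape == (9, 8)
    np.testing.assert_allclose(R[4, 0::2], 0.0, atol=1e-12)  # sin(0)
    np.testing.assert_allclose(R[4, 1::2], 1.0, atol=1e-12)  # cos(0)
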