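"""Adapter contracts: identity at initialization, detachability, freeze
semantics, hand-computed toy forwards, and closed-form parameter counts."""

import numpy as np
import pytest

import scadapt as sa
from scadapt.adapters import AdapterState
from scadapt.autodiff import Tensor


@pytest.fixture()
def sub(tokens):
    return tokens.subset_cells(np.arange(12))


@pytest.mark.parametrize("kind", ["token", "lora", "encoder"])
def test_identity_at_init_and_detach(kind, tiny_model, sub):
    native = tiny_model.forward(sub)
    sa.attach_adapter(tiny_model, sa.AdapterConfig(kind=kind, zero_init=True))
    adapted = tiny_model.forward(sub)
    assert np.array_equal(adapted.hidden.data, native.hidden.data)  # bit-equal
    assert np.array_equal(adapted.cell.data, native.cell.data)
    sa.detach_adapter(tiny_model)
    assert np.array_equal(tiny_model.forward(sub).hidden.data, native.hidden.data)


def test_token_adapter_hand_computation(vocab):
    """s=1, d=2 toy with hand-set weights: e + up(relu(down(e)))."""
    model = sa.CellTransformer(sa.BackboneConfig(vocab=vocab, n_blocks=1, d_model=2, n_heads=1, m_bins=3))
    sa.attach_token_adapter(model, sa.AdapterConfig(kind="token", bottleneck_dim=1))
    a = model.adapter
    a.params["down_W"].data[...] = np.array([[1.0], [2.0]])
    a.params["down_b"].data[...] = np.array([0.5])
    a.params["up_W"].data[...] = np.array([[3.0, -1.0]])
    a.params["up_b"].data[...] = np.array([0.25, 0.25])
    e = Tensor(np.array([[1.0, -2.0]]))
    got = a.apply_token(e).data
    hidden = max(1.0 * 1 + (-2.0) * 2 + 0.5, 0.0)  # relu(-2.5) = 0
    expect = np.array([[1.0 + hidden * 3.0 + 0.25, -2.0 + hidden * -1.0 + 0.25]])
    assert np.allclose(got, expect)
    e2 = Tensor(np.array([[2.0, 0.0]]))  # relu active: hidden = 2.5
    expect2 = np.array([[2.0 + 2.5 * 3.0 + 0.25, 0.0 + 2.5 * -1.0 + 0.25]])
    assert np.allclose(a.apply_token(e2).data, expect2)


def test_lora_hand_matrix_product(vocab):
    """r=1, d=2, A=[[1,0]], B=[[1],[0]]: delta = [h_0, 0]."""
    model = sa.CellTransformer(sa.BackboneConfig(vocab=vocab, n_blocks=1, d_model=2, n_heads=1))
    sa.attach_lora(model, sa.AdapterConfig(kind="lora", lora_rank=1))
    a = model.adapter
    a.params["A0_q"].data[...] = np.array([[1.0, 0.0]])
    a.params["B0_q"].data[...] = np.array([[1.0], [0.0]])
    h = Tensor(np.array([[[3.0, 7.0]]]))
    delta = a.apply_lora(h, 0, "q").data
    assert np.allclose(delta, [[[3.0, 0.0]]])


def test_prefix_extends_sequence_and_renormalized_attention(vocab, tokens):
    model = sa.CellTransformer(sa.BackboneConfig(vocab=vocab, n_blocks=1, d_model=16, n_heads=2, m_bins=10))
    sub = tokens.subset_cells(np.arange(4))
    native = model.forward(sub, capture_attention=True)
    sa.attach_prefix_adapter(model, sa.AdapterConfig(kind="prefix", prefix_len=3))
    out = model.forward(sub, capture_attention=True)
    assert out.hidden.shape[1] == sub.seq_len + 3
    assert out.n_prefix == 3
    # prefix keys only renormalize block-1 attention over the original columns
    att_p = out.attention[0][:, :, 3:, 3:]
    att_p = att_p / att_p.sum(axis=-1, keepdims=True)
    assert np.allclose(att_p, native.attention[0], atol=1e-10)
    sa.detach_adapter(model)
    assert np.array_equal(model.forward(sub).hidden.data, native.hidden.data)
    with pytest.raises(ValueError, match="prefix_len"):
        sa.attach_prefix_adapter(model, sa.AdapterConfig(kind="prefix", prefix_len=0))


def test_encoder_adapter_placement(vocab, tokens):
    """An adapter in block 0 changes what block 1 receives once trained."""
    from scadapt.tasks import Adam, _set_requires_grad
    from scadapt.backbone import cross_entropy

    model = sa.CellTransformer(sa.BackboneConfig(vocab=vocab, n_blocks=2, d_model=16, n_heads=2, m_bins=10))
    sub = tokens.subset_cells(np.arange(8))
    sa.attach_encoder_adapter(model, sa.AdapterConfig(kind="encoder", target_blocks=(0,)))
    before = model.forward(sub).hidden.data.copy()
    trainables = _set_requires_grad(model, [])
    opt = Adam(trainables, lr=1e-2)
    loss = (model.forward(sub).cell ** 2.0).sum()
    opt.zero_grad()
    loss.backward()
    opt.step()
    after = model.forward(sub).hidden.data
    assert not np.array_equal(before, after)
    with pytest.raises(ValueError, match="out of range"):
        sa.attach_encoder_adapter(model, sa.AdapterConfig(kind="encoder", target_blocks=(5,)))


def test_adapter_validations(vocab):
    model = sa.CellTransformer(sa.BackboneConfig(vocab=vocab, n_blocks=1, d_model=8, n_heads=2))
    with pytest.raises(ValueError, match="compress"):
        sa.attach_token_adapter(model, sa.AdapterConfig(kind="token", bottleneck_dim=8))
    with pytest.raises(ValueError, match="rank"):
        sa.attach_lora(model, sa.AdapterConfig(kind="lora", lora_rank=8))
    with pytest.raises(ValueError, match="kind"):
        sa.attach_lora(model, sa.AdapterConfig(kind="token"))


def test_parameter_counts_closed_form(vocab):
    d, s, r, n = 16, 4, 2, 3
    model = sa.CellTransformer(sa.BackboneConfig(vocab=vocab, n_blocks=n, d_model=d, n_heads=2))
    sa.attach_token_adapter(model, sa.AdapterConfig(kind="token", bottleneck_dim=s))
    assert model.adapter.n_params() == d * s + s + s * d + d
    sa.attach_lora(model, sa.AdapterConfig(kind="lora", lora_rank=r))
    assert model.adapter.n_params() == n * 2 * (2 * r * d)  # Q and V per block
    sa.attach_prefix_adapter(model, sa.AdapterConfig(kind="prefix", prefix_len=5))
    assert model.adapter.n_params() == 5 * d
    sa.attach_encoder_adapter(model, sa.AdapterConfig(kind="encoder", bottleneck_dim=s))
    assert model.adapter.n_params() == n * (d * s + s + s * d + d)


def test_freeze_and_count_fractions(vocab):
    model = sa.CellTransformer(sa.BackboneConfig(vocab=vocab, n_blocks=1, d_model=8, n_heads=2))
    model.set_backbone_trainable(False)
    rep = sa.freeze_and_count(model)
    assert rep["fraction"] == 0.0
    model.set_backbone_trainable(True)
    assert sa.freeze_and_count(model)["fraction"] == 1.0
    model.set_backbone_trainable(False)
    sa.attach_lora(model, sa.AdapterConfig(kind="lora", lora_rank=2))
    rep = sa.freeze_and_count(model)
    expect = model.adapter.n_params() / (model.n_backbone_params() + model.adapter.n_params())
    assert np.isclose(rep["fraction"], expect)


def test_frozen_checksum_stable_under_adapter_updates(vocab, tokens):
    from scadapt.tasks import Adam, _set_requires_grad

    model = sa.CellTransformer(sa.BackboneConfig(vocab=vocab, n_blocks=1, d_model=16, n_heads=2, m_bins=10))
    sa.attach_lora(model, sa.AdapterConfig(kind="lora", lora_rank=2))
    ck = model.frozen_checksum()
    trainables = _set_requires_grad(model, [])
    opt = Adam(trainables, lr=1e-2)
    sub = tokens.subset_cells(np.arange(6))
    for _ in range(5):
        loss = (model.forward(sub).cell ** 2.0).sum()
        opt.zero_grad()
        loss.backward()
        opt.step()
    assert model.frozen_checksum() == ck


def test_efficiency_bound_small_standin(vocab):
    """Scaled-down analogue of the efficiency property: every default adapter
    plus a linear head stays under 4% trainable on a d=64 backbone."""
    big_vocab = sa.GeneVocabulary.from_genes([f"G{i}" for i in range(3000)])
    model = sa.CellTransformer(sa.BackboneConfig(vocab=big_vocab, n_blocks=4, d_model=64, n_heads=4))
    rng = np.random.default_rng(0)
    head = {
        "W": Tensor(rng.normal(size=(64, 8)), requires_grad=True),
        "b": Tensor(np.zeros(8), requires_grad=True),
    }
    for kind in ["token", "prefix", "lora", "encoder"]:
        sa.attach_adapter(model, sa.AdapterConfig(kind=kind))
        assert sa.freeze_and_count(model, [head])["fraction"] <= 0.04
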