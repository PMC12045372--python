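"""The Transformer backbone: forward determinism, attention normalization,
permutation equivariance, masking, and the two reconstruction objectives."""

import numpy as np
import pytest

import scadapt as sa
from scadapt.autodiff import Tensor
from scadapt.backbone import gep_loss, gepc_loss, layer_norm, sample_mask
from scadapt.tokenizer import TokenizedBatch


def take(batch, n):
    return batch.subset_cells(np.arange(n))


def test_forward_deterministic_and_attention_normalized(tiny_model, tokens):
    sub = take(tokens, 8)
    out1 = tiny_model.forward(sub, capture_attention=True)
    out2 = tiny_model.forward(sub)
    assert np.array_equal(out1.hidden.data, out2.hidden.data)
    for att in out1.attention:
        assert np.allclose(att.sum(axis=-1), 1.0, atol=1e-5)
    # two identical cells give identical outputs
    twin = tokens.subset_cells(np.array([0, 0]))
    out = tiny_model.forward(twin)
    assert np.array_equal(out.cell.data[0], out.cell.data[1])


def test_permutation_equivariance(vocab, tiny_model):
    """Without positional encodings, permuting the gene order permutes the
    gene embeddings and leaves the cell embedding unchanged."""
    rng = np.random.default_rng(0)
    n_genes = 5
    gene_ids = np.array([[0, 1, 2, 3, 4, vocab.cls_id]])
    vt = np.array([[1, 0, 3, 2, 5, 0]])
    values = rng.random((1, 6))
    base = TokenizedBatch(
        gene_ids=gene_ids, values=values, value_tokens=vt,
        attention_mask=np.ones((1, 6), bool), gene_names=np.array(list("ABCDE"), dtype=object),
        mode="binned", cls_index=5,
    )
    perm = np.array([3, 0, 4, 2, 1])
    permuted = TokenizedBatch(
        gene_ids=np.hstack([gene_ids[:, perm], gene_ids[:, 5:]]),
        values=np.hstack([values[:, perm], values[:, 5:]]),
        value_tokens=np.hstack([vt[:, perm], vt[:, 5:]]),
        attention_mask=np.ones((1, 6), bool), gene_names=base.gene_names[perm],
        mode="binned", cls_index=5,
    )
    o1 = tiny_model.forward(base)
    o2 = tiny_model.forward(permuted)
    assert np.allclose(o1.hidden.data[0, perm], o2.hidden.data[0, :5], atol=1e-10)
    assert np.allclose(o1.cell.data, o2.cell.data, atol=1e-10)


def test_layer_norm_matches_manual():
    x = Tensor(np.array([[1.0, 2.0, 3.0, 4.0]]))
    out = layer_norm(x, Tensor(np.ones(4)), Tensor(np.zeros(4))).data
    manual = (x.data - 2.5) / np.sqrt(np.var(x.data) + 1e-5)
    assert np.allclose(out, manual)


def test_sample_mask_properties(tokens):
    sub = take(tokens, 10)
    m0 = sample_mask(sub, 0.0, seed=1)
    assert not m0.any()
    m = sample_mask(sub, 0.5, seed=1)
    m_again = sample_mask(sub, 0.5, seed=1)
    assert np.array_equal(m, m_again)
    for i in range(10):
        nnz = (sub.values[i, :-1] > 0).sum()
        assert m[i].sum() == int(0.5 * nnz)
        assert np.all(sub.values[i][m[i]] > 0)  # only non-zero positions masked
    assert not m[:, sub.cls_index].any()


def test_gep_loss_binned_and_continuous(vocab, tiny_model, small_data, tokens):
    sub = take(tokens, 6)
    mask = sample_mask(sub, 0.3, seed=0)
    out = tiny_model.forward(sub, mask=mask)
    loss = gep_loss(tiny_model, out, sub, mask)
    assert loss.item() > 0
    with pytest.raises(ValueError, match="nothing to reconstruct"):
        gep_loss(tiny_model, out, sub, np.zeros_like(mask))
    # continuous flavor: exact MSE oracle on a hand-made prediction path
    cont = sa.assemble_tokens(small_data, vocab, mode="continuous", task="annotation", with_cls=True)
    csub = cont.subset_cells(np.arange(6))
    cmask = sample_mask(csub, 0.3, seed=0)
    cout = tiny_model.forward(csub, mask=cmask)
    closs = gep_loss(tiny_model, cout, csub, cmask)
    # brute-force recomputation of the projector MSE
    p = tiny_model.params
    hm = cout.hidden.data[np.where(cmask)[0], np.where(cmask)[1]]
    pred = np.maximum(hm @ p["proj_mse_W1"].data + p["proj_mse_b1"].data, 0) @ p["proj_mse_W2"].data + p["proj_mse_b2"].data
    expect = np.mean((pred.ravel() - csub.values[cmask]) ** 2)
    assert np.isclose(closs.item(), expect)


def test_gepc_scalar_hand_example(vocab):
    """d=1 toy: q=2, W=1, h_c=3, target 5 -> (2*3-5)^2 = 1."""
    model = sa.CellTransformer(sa.BackboneConfig(vocab=vocab, n_blocks=1, d_model=1, n_heads=1, m_bins=3, seed=0))
    batch = TokenizedBatch(
        gene_ids=np.array([[0, vocab.cls_id]]), values=np.array([[5.0, 0.0]]),
        value_tokens=np.array([[1, 0]]), attention_mask=np.ones((1, 2), bool),
        gene_names=np.array(["G0"], dtype=object), mode="binned", cls_index=1,
    )
    mask = np.array([[True, False]])
    # force the pieces of the bilinear prediction to the hand values
    p = model.params
    p["gepc_W"].data[...] = 1.0
    p["gepc_W1"].data[...] = 0.0
    p["gepc_b1"].data[...] = 0.0
    p["gepc_W2"].data[...] = 0.0
    p["gepc_b2"].data[...] = 2.0  # q = 2 regardless of the gene embedding
    out = model.forward(batch, mask=mask)
    hc = out.cell.data[0, 0]
    loss = gepc_loss(model, out, batch, mask)
    assert np.isclose(loss.item(), (2.0 * hc - 5.0) ** 2)
    mean_model = sa.CellTransformer(sa.BackboneConfig(vocab=vocab, n_blocks=1, d_model=2, n_heads=1, pooling="mean"))
    with pytest.raises(ValueError, match="cls"):
        gepc_loss(mean_model, out, batch, mask)


def test_gep_loss_decreases_with_training(vocab, small_data):
    """Gradient sanity: 50 optimization steps reduce the GEP loss on a
    fixed synthetic batch of an untrained model."""
    from scadapt.tasks import Adam
    from scadapt.tasks import _set_requires_grad

    model = sa.CellTransformer(sa.BackboneConfig(vocab=vocab, n_blocks=2, d_model=16, n_heads=2, m_bins=10, seed=0))
    batch = sa.assemble_tokens(small_data, vocab, mode="binned", m=10, with_cls=True).subset_cells(np.arange(32))
    mask = sample_mask(batch, 0.25, seed=0)
    model.set_backbone_trainable(True)
    trainables = _set_requires_grad(model, [])
    opt = Adam(trainables, lr=1e-3)
    losses = []
    for _ in range(50):
        out = model.forward(batch, mask=mask)
        loss = gep_loss(model, out, batch, mask)
        opt.zero_grad()
        loss.backward()
        opt.step()
        losses.append(loss.item())
    assert losses[-1] < losses[0]


def test_divisibility_enforced_at_forward_only(vocab, tokens):
    model = sa.CellTransformer(sa.BackboneConfig(vocab=vocab, n_blocks=1, d_model=16, n_heads=10))
    assert model.n_backbone_params() > 0  # construction and counting allowed
    with pytest.raises(ValueError, match="divisible"):
        model.forward(tokens.subset_cells(np.arange(2)))
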