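"""Attention profiles, differential attention statistics, kNN label
transfer, ortholog mapping and Leiden clustering."""

import numpy as np
import pytest

import scadapt as sa
from scadapt.interpret import differential_attention, extract_attention


def _dirichlet_profiles(rng, n, G, boost_gene=None, boost=0.0):
    base = rng.dirichlet(np.full(G, 2.0), size=n)
    if boost_gene is not None:
        base[:, boost_gene] += boost
        base = base / base.sum(axis=1, keepdims=True)
    return base


def test_extract_attention_normalized_rows(tiny_model, tokens):
    prof = extract_attention(tiny_model, tokens.subset_cells(np.arange(10)), layers=[0, 1])
    for l in (0, 1):
        P = prof.layer(l)
        assert P.shape == (10, 60)
        assert np.all(P >= 0) and np.allclose(P.sum(axis=1), 1.0, atol=1e-5)


def test_extract_attention_single_head_hand_softmax(vocab):
    """1 head, d=1, 2 genes + cls: cls row equals the scalar softmax of the
    query-key logits computed by hand."""
    from scadapt.tokenizer import TokenizedBatch

    model = sa.CellTransformer(sa.BackboneConfig(vocab=vocab, n_blocks=1, d_model=1, n_heads=1, m_bins=3, seed=3))
    batch = TokenizedBatch(
        gene_ids=np.array([[0, 1, vocab.cls_id]]), values=np.array([[1.0, 2.0, 0.0]]),
        value_tokens=np.array([[1, 2, 0]]), attention_mask=np.ones((1, 3), bool),
        gene_names=np.array(["G0", "G1"], dtype=object), mode="binned", cls_index=2,
    )
    p = model.params
    h0 = p["emb_g"].data[batch.gene_ids[0], 0] + p["emb_e"].data[batch.value_tokens[0], 0]
    q = h0 * p["blk0.Wq"].data[0, 0] + p["blk0.qb"].data[0]
    k = h0 * p["blk0.Wk"].data[0, 0] + p["blk0.kb"].data[0]
    logits = q[2] * k  # cls row, scale 1/sqrt(d)=1
    expect = np.exp(logits - logits.max())
    expect /= expect.sum()
    expect_genes = expect[:2] / expect[:2].sum()
    prof = extract_attention(model, batch, layers=[0])
    assert np.allclose(prof.layer(0)[0], expect_genes, atol=1e-12)


def test_extract_attention_requires_cls(vocab, tokens):
    model = sa.CellTransformer(sa.BackboneConfig(vocab=vocab, n_blocks=1, d_model=16, n_heads=2, pooling="mean"))
    with pytest.raises(ValueError, match="cls"):
        extract_attention(model, tokens.subset_cells(np.arange(2)))


def test_differential_attention_recovers_planted_shift():
    rng = np.random.default_rng(0)
    G = 100
    A = _dirichlet_profiles(rng, 200, G, boost_gene=7, boost=0.1)
    B = _dirichlet_profiles(rng, 200, G)
    res = differential_attention(A, B)
    assert res.ranking[0] == 7
    assert res.q_values[7] < 0.05
    assert np.all(res.q_values >= res.p_values - 1e-12)
    assert sorted(res.ranking) == list(range(G))
    # BY q-values are monotone in p-values
    order = np.argsort(res.p_values)
    assert np.all(np.diff(res.q_values[order]) >= -1e-12)


def test_differential_attention_null_is_flat():
    rng = np.random.default_rng(1)
    X = _dirichlet_profiles(rng, 100, 40)
    res = differential_attention(X[:50], X[50:])
    assert (res.q_values < 0.05).mean() <= 0.07
    # identical (permuted) values: deltas 0, q ~= 1
    res2 = differential_attention(X[:50], X[:50][::-1])
    assert np.allclose(res2.delta, 0)
    assert np.all(res2.q_values > 0.9)
    with pytest.raises(ValueError, match="two cells"):
        differential_attention(X[:1], X[1:])


def test_export_ranked_genes_roundtrip(tmp_path):
    rng = np.random.default_rng(2)
    res = differential_attention(_dirichlet_profiles(rng, 20, 15), _dirichlet_profiles(rng, 20, 15))
    path = sa.export_ranked_genes(res, tmp_path / "out.rnk")
    lines = path.read_text().strip().split("\n")
    assert len(lines) == 15
    deltas = [float(l.split("\t")[1]) for l in lines]
    assert deltas == sorted(deltas, reverse=True)
    names = [l.split("\t")[0] for l in lines]
    assert sorted(names) == sorted(res.gene_names)


def test_knn_label_transfer_votes_and_ties():
    ref = np.array([[0.0], [0.1], [1.0], [1.1], [2.0]])
    labels = np.array(["A", "A", "B", "B", "C"])
    assert sa.knn_label_transfer(ref, labels, np.array([[0.05]]), k=1)[0] == "A"
    # neighbors [A, A, B] -> A
    assert sa.knn_label_transfer(ref, labels, np.array([[0.3]]), k=3)[0] == "A"
    # query identical to a reference point
    assert sa.knn_label_transfer(ref, labels, np.array([[2.0]]), k=1)[0] == "C"
    # vote tie 1-1 resolved by the nearer neighbor
    assert sa.knn_label_transfer(ref, labels, np.array([[0.4]]), k=2)[0] == "A"
    with pytest.raises(ValueError):
        sa.knn_label_transfer(ref, labels, np.array([[0.0]]), k=9)
    with pytest.raises(ValueError):
        sa.knn_label_transfer(np.empty((0, 1)), np.array([]), np.array([[0.0]]), k=1)


def test_knn_transfer_separated_embeddings():
    rng = np.random.default_rng(3)
    centers = np.array([[0, 0], [6, 0], [0, 6]], dtype=float)
    ref = np.vstack([rng.normal(c, 0.3, (50, 2)) for c in centers])
    ref_labels = np.repeat(["a", "b", "c"], 50)
    qry = np.vstack([rng.normal(c, 0.3, (30, 2)) for c in centers])
    qry_labels = np.repeat(["a", "b", "c"], 30)
    pred = sa.knn_label_transfer(ref, ref_labels, qry, k=10)
    assert sa.balanced_accuracy(qry_labels, pred) >= 0.95


def test_map_orthologs(small_data, vocab):
    # identity table: vocabulary filtering only
    table = {g: g for g in small_data.gene_names}
    out = sa.map_orthologs(small_data, table, vocab)
    assert out.n_genes == 60
    # mouse-style names: 2 mapped, 1 of them in vocab
    renamed = small_data.copy()
    renamed.gene_names = np.array([f"m{g}" for g in small_data.gene_names], dtype=object)
    out2 = sa.map_orthologs(renamed, {"mG0": "G0", "mG1": "NOTINVOCAB"}, vocab)
    assert list(out2.gene_names) == ["G0"]
    with pytest.raises(ValueError, match="empty"):
        sa.map_orthologs(small_data, {}, vocab)
    with pytest.raises(ValueError, match="one-to-one"):
        sa.map_orthologs(renamed, {"mG0": "X", "mG1": "X"}, vocab)


def test_cluster_embeddings_blobs_and_determinism():
    rng = np.random.default_rng(4)
    X = np.vstack([rng.normal([5, 0], 0.2, (100, 2)), rng.normal([0, 5], 0.2, (100, 2))])
    # at a coarse resolution the two blobs are recovered exactly
    lab = sa.cluster_embeddings(X, resolution=0.01, seed=0)
    from sklearn.metrics import adjusted_rand_score

    assert adjusted_rand_score(np.repeat([0, 1], 100), lab) == 1.0
    assert np.array_equal(lab, sa.cluster_embeddings(X, resolution=0.01, seed=0))
    # higher resolution never reduces the community count on the same graph
    counts = [sa.cluster_embeddings(X, resolution=r, seed=0).max() + 1 for r in (0.01, 0.5, 3.0)]
    assert counts == sorted(counts)
    with pytest.raises(ValueError):
        sa.cluster_embeddings(X[:1])
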