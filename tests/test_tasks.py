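"""Task protocols: training mechanics, freeze contract, early stopping,
validation holdouts, and the batch-correction loss components."""

import numpy as np
import pytest

import scadapt as sa
from scadapt.autodiff import Tensor
from scadapt.tasks import _donor_holdout, _ecs_loss


def small_protocol(**kw):
    defaults = dict(initial_lr=5e-3, lr_decay=0.97, max_epochs=6, patience=4, batch_size=64, seed=0)
    defaults.update(kw)
    return sa.TrainProtocol(**defaults)


def test_protocol_validation():
    with pytest.raises(ValueError):
        sa.TrainProtocol(patience=10, max_epochs=5)
    with pytest.raises(ValueError):
        sa.TrainProtocol(lr_decay=0.0)
    p = sa.TrainProtocol()
    assert p.initial_lr == 1e-5 and p.max_epochs == 100 and p.patience == 5


def test_donor_holdout_partitions():
    donors = np.array(["d0", "d1", "d2"] * 10, dtype=object)
    train, val = _donor_holdout(donors, seed=0)
    assert set(train) | set(val) == set(range(30))
    assert len(set(donors[val])) == 1 and set(donors[train]).isdisjoint(donors[val])
    with pytest.raises(ValueError, match="single donor"):
        _donor_holdout(np.repeat("d0", 10), seed=0)


def test_fit_annotation_freeze_and_learning(vocab, small_data, tiny_model):
    sa.attach_adapter(tiny_model, sa.AdapterConfig(kind="lora"))
    ck = tiny_model.frozen_checksum()
    fitted = sa.fit_annotation(tiny_model, small_data, small_protocol(), vocab, mode="binned")
    assert tiny_model.frozen_checksum() == ck  # backbone untouched
    losses = [h["train_loss"] for h in fitted.history]
    assert losses[-1] < losses[0]
    pred, probs = sa.predict_annotation(fitted, small_data)
    assert np.allclose(probs.sum(axis=1), 1.0)
    assert probs.shape == (300, 3)
    # identical cells get identical labels
    twin = small_data.subset_cells(np.array([0, 0]))
    p2, _ = sa.predict_annotation(fitted, twin)
    assert p2[0] == p2[1]


def test_fit_annotation_errors(vocab, small_data, tiny_model):
    single = small_data.subset_cells(np.where(small_data.donor == "donor0")[0])
    with pytest.raises(ValueError, match="single donor"):
        sa.fit_annotation(tiny_model, single, small_protocol(), vocab)
    one_type = small_data.subset_cells(np.where(small_data.cell_type == "type0")[0])
    with pytest.raises(ValueError, match="cell types"):
        sa.fit_annotation(tiny_model, one_type, small_protocol(), vocab)


def test_predict_annotation_gene_space_mismatch(vocab, small_data, tiny_model):
    sa.attach_adapter(tiny_model, sa.AdapterConfig(kind="token"))
    fitted = sa.fit_annotation(tiny_model, small_data, small_protocol(max_epochs=2, patience=1), vocab)
    query = small_data.subset_genes(np.arange(30))
    with pytest.raises(ValueError, match="gene-space mismatch"):
        sa.predict_annotation(fitted, query)


def test_early_stopping_on_flat_validation(vocab, small_data, tiny_model):
    """Zero learning rate freezes the validation loss, so patience halts
    training after exactly patience epochs."""
    sa.attach_adapter(tiny_model, sa.AdapterConfig(kind="lora"))
    proto = sa.TrainProtocol(initial_lr=0.0, lr_decay=0.9, max_epochs=30, patience=3, batch_size=64, seed=0)
    fitted = sa.fit_annotation(tiny_model, small_data, proto, vocab)
    # epoch 0 sets the best loss; 3 stale epochs follow
    assert len(fitted.history) == 4


def test_fit_unsupervised_reduces_loss_and_ignores_labels(vocab, small_data, tiny_model):
    sa.attach_adapter(tiny_model, sa.AdapterConfig(kind="lora"))
    ck = tiny_model.frozen_checksum()
    shuffled = small_data.copy()
    shuffled.cell_type = np.random.default_rng(0).permutation(shuffled.cell_type)
    batch, hist = sa.fit_unsupervised(tiny_model, shuffled, small_protocol(), vocab, mask_ratio=0.25)
    assert hist[-1]["train_loss"] < hist[0]["train_loss"]
    assert tiny_model.frozen_checksum() == ck
    with pytest.raises(ValueError, match="mask_ratio"):
        sa.fit_unsupervised(tiny_model, small_data, small_protocol(), vocab, mask_ratio=0.0)


def test_ecs_loss_formula():
    # cos = beta exactly -> zero contribution
    cell = Tensor(np.array([[1.0, 0.0], [2.0, 0.0]]))
    ids = np.array([0, 0])
    assert np.isclose(_ecs_loss(cell, ids, beta=1.0).item(), 0.0)  # cos=1, beta=1
    # cos = 1, beta = 0.5 -> pair contributes -(1 - 0.5) = -0.5
    assert np.isclose(_ecs_loss(cell, ids, beta=0.5).item(), -0.5)
    # orthogonal pair: cos = 0, beta = 0.5 -> +0.5
    cell2 = Tensor(np.array([[1.0, 0.0], [0.0, 1.0]]))
    assert np.isclose(_ecs_loss(cell2, ids, beta=0.5).item(), 0.5)
    # no same-batch pair -> zero
    assert _ecs_loss(cell, np.array([0, 1]), beta=0.5).item() == 0.0


def test_batch_loss_weights_validation():
    with pytest.raises(ValueError):
        sa.BatchLossWeights(margin_beta=2.0)
    with pytest.raises(ValueError):
        sa.BatchLossWeights(dar_lambda=0.0)


def test_fit_batch_correction_mechanics(vocab, small_data, tiny_model):
    sa.attach_adapter(tiny_model, sa.AdapterConfig(kind="lora"))
    ck = tiny_model.frozen_checksum()
    batch, hist = sa.fit_batch_correction(tiny_model, small_data, small_protocol(max_epochs=3, patience=2), vocab)
    assert tiny_model.frozen_checksum() == ck
    assert len(hist) >= 1 and np.isfinite(hist[-1]["train_loss"])
    single = small_data.copy()
    single.batch = np.repeat("b0", 300)
    with pytest.raises(ValueError, match="two batches"):
        sa.fit_batch_correction(tiny_model, single, small_protocol(), vocab)


def test_fit_perturbation_and_prediction_determinism(vocab, small_data, tiny_model):
    effect = np.zeros(60)
    pairs = sa.simulate_perturbation(small_data, "G2", effect, n_pairs=60, seed=0, noise_sigma=0.05)
    sa.attach_adapter(tiny_model, sa.AdapterConfig(kind="lora"))
    ck = tiny_model.frozen_checksum()
    fitted = sa.fit_perturbation(tiny_model, pairs, small_protocol(max_epochs=3, patience=2), vocab)
    assert tiny_model.frozen_checksum() == ck
    pred1 = sa.predict_perturbation(fitted, pairs.control_log1p[:5], "G2", gene_names=pairs.gene_names)
    pred2 = sa.predict_perturbation(fitted, pairs.control_log1p[:5], "G2", gene_names=pairs.gene_names)
    assert np.array_equal(pred1, pred2)
    assert pred1.shape == (5, 60)  # output shape matches input gene space
    with pytest.raises(ValueError, match="unknown perturbation target"):
        sa.predict_perturbation(fitted, pairs.control_log1p[:2], "NOPE", gene_names=pairs.gene_names)
    bad = sa.PerturbationPairs(
        control_log1p=pairs.control_log1p[:3], perturbed_log1p=pairs.perturbed_log1p[:2],
        condition_tokens=pairs.condition_tokens, gene_names=pairs.gene_names,
        cell_type=pairs.cell_type[:3], target_gene="G2", source_index=pairs.source_index[:2],
    )
    with pytest.raises(ValueError, match="unpaired"):
        sa.fit_perturbation(tiny_model, bad, small_protocol(), vocab)
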