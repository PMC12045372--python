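import numpy as np
import pytest

import scadapt as sa


@pytest.fixture(scope="session")
def small_data() -> sa.LabeledMatrix:
    spec = sa.SyntheticSpec(
        n_cells=300, n_genes=60, n_cell_types=3, n_donors=4, n_batches=2,
        program_size=8, program_log_fold=1.2, batch_log_fold=0.3, seed=1,
    )
    return sa.simulate_profiles(spec)


@pytest.fixture(scope="session")
def vocab(small_data) -> sa.GeneVocabulary:
    return sa.GeneVocabulary.from_genes(list(small_data.gene_names))


@pytest.fixture()
def tiny_model(vocab) -> sa.CellTransformer:
    return sa.CellTransformer(
        sa.BackboneConfig(vocab=vocab, n_blocks=2, d_model=16, n_heads=2, m_bins=10, seed=0)
    )


@pytest.fixture(scope="session")
def tokens(small_data, vocab) -> sa.TokenizedBatch:
    return sa.assemble_tokens(small_data, vocab, mode="binned", m=10, with_cls=True)
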