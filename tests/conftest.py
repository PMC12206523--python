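import numpy as np
import pytest

import scintbench as sb


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_bundle_ds():
    """4 cells x 3 genes, two batches, with an embedding and a graph."""
    counts = np.array([[1, 0, 2], [0, 3, 1], [5, 0, 0], [2, 2, 2]])
    emb = np.array([[0.0, 0.0], [1.0, 0.5], [2.0, 2.0], [3.0, 1.0]])
    g = sb.knn_graph(emb, 2)
    return sb.CellDataset(
        layers={"counts": counts, "data": np.log1p(counts.astype(float))},
        batch=np.array(["A", "A", "B", "B"]),
        celltype=np.array(["t1", "t2", "t1", "t2"]),
        embeddings={"pca": emb},
        graphs={"knn": g},
        var_features=np.array([True, False, True]),
    )


@pytest.fixture
def shifted_small():
    """Small shifted-batches latent dataset with known truth."""
    truth = sb.SyntheticTruth(
        n_batches=3, n_types=4, cells=np.full((3, 4), 30),
        batch_shift=6.0, seed=7,
    )
    return truth, sb.simulate_latent(truth)
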