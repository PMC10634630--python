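import numpy as np
import pytest

from race_rsa import SimilarityMatrix, build_similarity_matrix
from race_rsa.rsm import FeatureSet


def block_similarity(n_per_race, races=("Asian", "Black", "White"),
                     within=0.8, between=0.2):
    """Noise-free block-structured similarity matrix (within/between race)."""
    labels = np.repeat(list(races), n_per_race)
    V = np.where(labels[:, None] == labels[None, :], within, between).astype(float)
    np.fill_diagonal(V, 1.0)
    ids = [f"im{i:02d}" for i in range(labels.size)]
    return SimilarityMatrix(values=V, image_ids=ids, race_labels=labels,
                            identity_labels=ids, layer_name="block")


def random_similarity(n_images=12, n_features=20, races=("Asian", "Black", "White"),
                      seed=0):
    """Similarity matrix of random features with cyclic race labels."""
    rng = np.random.default_rng(seed)
    labels = [races[i % len(races)] for i in range(n_images)]
    fs = FeatureSet(
        layer_name="rand",
        activations=rng.standard_normal((n_images, n_features)),
        race_labels=labels,
        identity_labels=[f"id{i}" for i in range(n_images)],
        image_ids=[f"im{i:02d}" for i in range(n_images)],
    )
    return build_similarity_matrix(fs)


@pytest.fixture
def block_sm():
    return block_similarity(n_per_race=4)


@pytest.fixture
def random_sm():
    return random_similarity()
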