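import numpy as np
import pytest

from acpfuse import io, network, synthetic
from acpfuse.tables import ALPHABET


def make_random_peptides(seed: int, n: int, min_len: int = 11, max_len: int = 60):
    rng = np.random.default_rng(seed)
    letters = list(ALPHABET)
    return [
        "".join(rng.choice(letters, size=int(rng.integers(min_len, max_len + 1))))
        for _ in range(n)
    ]


@pytest.fixture(scope="session")
def random_peptides():
    """100 random peptides over the canonical alphabet, lengths 11-60."""
    return make_random_peptides(seed=2024, n=100)


@pytest.fixture(scope="session")
def small_trained_model():
    """A small fused model trained on a separable synthetic dataset,
    shared by the inference/persistence tests (training it once keeps the
    suite fast). Returns (model, validation dataset)."""
    ds = synthetic.generate(
        synthetic.GeneratorSpec(n_pos=60, n_neg=60, length_range=(11, 30), seed=11)
    )
    train_ds, val_ds = io.split(ds, io.SplitSpec(seed=11))
    config = network.ModelConfig(
        mode="MS+AE",
        max_len=30,
        embed_dim=12,
        rnn_units=12,
        batch_size=16,
        max_epochs=12,
        patience=6,
        seed=11,
    )
    model = network.train_on_datasets(train_ds, val_ds, config)
    return model, val_ds
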