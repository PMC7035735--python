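import numpy as np
import pytest
from hypothesis import settings

from dra import io, synthetic, train

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def three_cluster_data():
    """Reference simulation: counts, labels and an 80/20 split."""
    spec = synthetic.three_cluster_spec(seed=0)
    counts, labels = synthetic.generate_zinb_counts(spec)
    split = io.split_train_test(counts.n_cells, 0.8, seed=0)

    def subset(idx):
        return io.CountMatrix(
            counts.values[idx], [counts.cell_ids[i] for i in idx], counts.gene_ids
        )

    train_counts, test_counts = subset(split.train), subset(split.test)
    return {
        "counts": counts,
        "labels": labels,
        "split": split,
        "train_counts": train_counts,
        "test_counts": test_counts,
        "train_processed": io.log_transform(train_counts),
        "test_processed": io.log_transform(test_counts),
        "train_labels": labels.subset(split.train),
        "test_labels": labels.subset(split.test),
    }


@pytest.fixture(scope="session")
def quick_model(three_cluster_data):
    """A briefly trained AVAE-DM for determinism/shape/viz tests."""
    d = three_cluster_data
    cfg = train.demo_config(seed=0, epochs=25, early_stopping_patience=25)
    model, history = train.train_model(d["train_processed"], d["train_counts"], cfg)
    return model, history, cfg
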