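import numpy as np
import pytest

from spermhead.dataset_io import ImageRecord, LabeledDataset

SMOKE_CONFIG = dict(
    synthetic=dict(image_size=16,
                   class_counts={"Normal": 6, "Tapered": 6, "Pyriform": 6,
                                 "Amorphous": 6, "Small": 6},
                   seed=3),
    preprocess="none",
    k=2, runs=1, dev_fraction=0.2, cap=4, rotation_limit=5,
    architecture=dict(stem_filters=4, bottleneck_filters=4, branch_filters=2,
                      repetitions=(1, 1)),
    training=dict(learning_rate=1e-3, decay=0.0, batch_size=8, epochs=2),
    base_seed=0,
)


@pytest.fixture(scope="session")
def smoke_bundle(tmp_path_factory):
    """One tiny end-to-end experiment (k=2, runs=1), shared across tests."""
    from spermhead.experiment import ExperimentConfig, run_experiment
    out = tmp_path_factory.mktemp("bundle")
    cfg = ExperimentConfig(out_dir=str(out / "exp"), **SMOKE_CONFIG)
    return run_experiment(cfg), cfg


def counts_dataset(class_counts: dict[str, int]) -> LabeledDataset:
    """A dataset with the requested per-class counts and 1-px images —
    enough structure for partition/augmentation-count logic."""
    records = [ImageRecord(f"{c}_{i}", np.zeros((1, 1)), c)
               for c, n in class_counts.items() for i in range(n)]
    return LabeledDataset(records, list(class_counts))


@pytest.fixture(scope="session")
def scian_partial_counts() -> dict[str, int]:
    """Class totals of the 1132-image partial-agreement gold-standard set."""
    return {"Normal": 100, "Tapered": 228, "Pyriform": 76,
            "Amorphous": 656, "Small": 72}


@pytest.fixture(scope="session")
def scian_total_counts() -> dict[str, int]:
    """Class totals of the 384-image total-agreement subset."""
    return {"Normal": 35, "Tapered": 69, "Pyriform": 7,
            "Amorphous": 262, "Small": 11}
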