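import warnings

import numpy as np
import pytest

from coexpipe.core import ExpressionMatrix, Space, SubmissionRecord
from coexpipe.synth import SynthConfig, CategorySpec, generate_compendium

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture
def tiny_raw_matrix() -> ExpressionMatrix:
    values = np.array([[10.0, 20.0, 30.0],
                       [100.0, 50.0, 25.0],
                       [5.0, 5.0, 5.0]])
    return ExpressionMatrix(values, ["g1", "g2", "g3"], ["a1", "a2", "a3"],
                            Space.RAW)


@pytest.fixture(scope="session")
def small_compendium():
    """A light multi-category compendium with duplicates and outliers."""
    cfg = SynthConfig(
        n_genes=300,
        n_probes_per_set=5,
        categories=(
            CategorySpec("tissue", "Root", 3, 10),
            CategorySpec("tissue", "Leaf", 3, 10),
            CategorySpec("process", "Stress", 3, 10),
            CategorySpec("process", "Light", 3, 10),
            CategorySpec("process", "Hormone", 3, 10),
            CategorySpec("tissue", "Flower", 3, 10),
        ),
        n_exact_duplicates=2,
        n_near_duplicates=1,
        n_outlier_arrays=2,
        n_spikein_failures=1,
        seed=42,
    )
    return cfg, generate_compendium(cfg)


def make_submission(sub_id: str, arrays, description: str = "",
                    hashes=None) -> SubmissionRecord:
    return SubmissionRecord(sub_id, "other", description, list(arrays),
                            dict(hashes or {}))
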