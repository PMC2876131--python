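import numpy as np
import pandas as pd
import pytest

from mvpfilter import (
    BetaMatrix,
    ReplicateDesign,
    SimulationConfig,
    generate_dataset,
)


@pytest.fixture(scope="session")
def default_dataset():
    """One dataset from the generator's documented default configuration."""
    return generate_dataset(SimulationConfig(seed=0))


@pytest.fixture
def tiny_matrix():
    """3 probes x 4 samples (2 replicate pairs) with hand-set values."""
    data = pd.DataFrame(
        {
            "A1": [0.1, 0.5, 0.9],
            "A2": [0.12, 0.48, 0.88],
            "B1": [0.3, 0.6, 0.2],
            "B2": [0.31, 0.59, 0.22],
        },
        index=pd.Index(["p1", "p2", "p3"], name="probe_id"),
    )
    return BetaMatrix(data)


@pytest.fixture
def tiny_design():
    return ReplicateDesign(
        pd.DataFrame(
            {
                "pair_id": ["P1", "P2"],
                "sample_rep1": ["A1", "B1"],
                "sample_rep2": ["A2", "B2"],
            }
        )
    )


def make_paired_matrix(rep1: np.ndarray, rep2: np.ndarray) -> tuple[BetaMatrix, ReplicateDesign]:
    """Build a BetaMatrix + design where every sample is replicated.

    ``rep1``/``rep2`` are probe x pair arrays.
    """
    n_probes, n_pairs = rep1.shape
    r1 = [f"S{i}" for i in range(n_pairs)]
    r2 = [f"S{i}_r2" for i in range(n_pairs)]
    data = pd.DataFrame(
        np.concatenate([rep1, rep2], axis=1),
        index=pd.Index([f"p{j}" for j in range(n_probes)], name="probe_id"),
        columns=r1 + r2,
    )
    design = ReplicateDesign(
        pd.DataFrame(
            {"pair_id": [f"P{i}" for i in range(n_pairs)],
             "sample_rep1": r1, "sample_rep2": r2}
        )
    )
    return BetaMatrix(data), design
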