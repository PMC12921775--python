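import numpy as np
import pandas as pd
import pytest

from proteffect import AnalysisConfig, ProteinMatrix, SampleDesign


@pytest.fixture
def small_matrix() -> ProteinMatrix:
    """4 proteins × 4 samples raw matrix with one missing cell."""
    values = pd.DataFrame(
        {
            "s1": [1024.0, 2048.0, 512.0, 4096.0],
            "s2": [2048.0, 1024.0, np.nan, 8192.0],
            "s3": [1024.0, 4096.0, 256.0, 2048.0],
            "s4": [512.0, 2048.0, 1024.0, 4096.0],
        },
        index=pd.Index(["P1", "P2", "P3", "P4"], name="Protein.Group"),
    )
    return ProteinMatrix(values=values, scale="raw")


@pytest.fixture
def two_diet_design() -> SampleDesign:
    """16 samples: one tissue, two diets × 8 replicates, halves assigned."""
    rows = []
    for diet in ("A", "B"):
        for rep in range(1, 9):
            rows.append(
                {
                    "sample_id": f"{diet}{rep}",
                    "tissue": "brain",
                    "diet": diet,
                    "replicate": rep,
                    "half": 1 if rep <= 4 else 2,
                }
            )
    return SampleDesign(pd.DataFrame(rows))


@pytest.fixture
def default_cfg() -> AnalysisConfig:
    return AnalysisConfig(seed=0)


def make_matrix(values: np.ndarray, sample_ids=None, scale="log2") -> ProteinMatrix:
    values = np.asarray(values, dtype=float)
    n, s = values.shape
    cols = sample_ids or [f"s{i + 1}" for i in range(s)]
    df = pd.DataFrame(
        values, index=pd.Index([f"P{i + 1}" for i in range(n)], name="Protein.Group"),
        columns=cols,
    )
    return ProteinMatrix(values=df, scale=scale)


def make_design(sample_ids, diets, tissue="brain") -> SampleDesign:
    reps: dict = {}
    rows = []
    for sid, diet in zip(sample_ids, diets):
        reps[diet] = reps.get(diet, 0) + 1
        rows.append(
            {
                "sample_id": sid,
                "tissue": tissue,
                "diet": diet,
                "replicate": reps[diet],
            }
        )
    return SampleDesign(pd.DataFrame(rows))
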