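import numpy as np
import pandas as pd
import pytest

from isodyn.core import STAGES, ExpressionMatrix, SampleMetadata


def make_metadata(breeds=("AA", "LS"), stages=STAGES, n_replicates=3,
                  library_size=20_000_000):
    rows = []
    for breed in breeds:
        for stage in stages:
            for rep in range(1, n_replicates + 1):
                rows.append({"sample_id": f"{breed}_{stage}_{rep}",
                             "breed": breed, "stage": stage,
                             "replicate": rep, "library_size": library_size})
    return SampleMetadata(pd.DataFrame(rows).set_index("sample_id"),
                          stages=tuple(stages))


@pytest.fixture(scope="session")
def meta42():
    """The standard study layout: 2 breeds x 7 stages x 3 replicates."""
    return make_metadata()


@pytest.fixture(scope="session")
def meta21():
    """One breed's half of the layout (21 samples)."""
    return make_metadata(breeds=("AA",))


def random_fpkm(meta, n_transcripts=100, seed=0):
    rng = np.random.default_rng(seed)
    values = rng.gamma(2.0, 10.0, (n_transcripts, len(meta.sample_ids)))
    return ExpressionMatrix(
        pd.DataFrame(values, index=[f"T{i:05d}" for i in range(n_transcripts)],
                     columns=meta.sample_ids), "fpkm")
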