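import numpy as np
import pandas as pd
import pytest

from hepnet.expression import ExpressionMatrix, StudyDesign


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_matrix(values, gene_ids=None, sample_ids=None, scale="intensity", flags=None):
    values = np.asarray(values, dtype=float)
    g, s = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(g)]
    sample_ids = sample_ids or [f"s{j}" for j in range(s)]
    df = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    fdf = None
    if flags is not None:
        fdf = pd.DataFrame(np.asarray(flags, dtype=bool), index=gene_ids, columns=sample_ids)
    return ExpressionMatrix(df, scale, fdf)


def make_design(rows):
    """rows: list of (sample_id, system, compound, dose, time_h, replicate, is_control)."""
    return StudyDesign(
        pd.DataFrame(
            rows,
            columns=[
                "sample_id",
                "system",
                "compound",
                "dose",
                "time_h",
                "replicate",
                "is_control",
            ],
        )
    )


@pytest.fixture
def random_intensity_matrix(rng):
    # per-gene baselines dominate (bright probes bright on every array), as
    # on real chips, so arrays correlate strongly unless corrupted
    baseline = rng.normal(5.0, 1.2, size=(30, 1))
    noise = rng.normal(0.0, 0.2, size=(30, 8))
    return make_matrix(np.exp(baseline + noise) + 5.0)


@pytest.fixture
def two_group_design():
    rows = []
    for r in range(1, 4):
        rows.append((f"c{r}", "vitro", "TNT", 0.0, 24.0, r, True))
        rows.append((f"t{r}", "vitro", "TNT", 10.0, 24.0, r, False))
    return make_design(rows)
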