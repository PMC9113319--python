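import numpy as np
import pandas as pd
import pytest

from omicsvd import OmicBlock


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def toy_blocks():
    """Two small aligned omic blocks with different scales and one NaN."""
    rng = np.random.default_rng(7)
    samples = [f"S{i:02d}" for i in range(12)]
    expr = OmicBlock(
        values=rng.standard_normal((12, 20)),
        sample_ids=samples,
        feature_ids=[f"g{j}" for j in range(20)],
        block_label="expr",
    )
    meth = OmicBlock(
        values=rng.standard_normal((12, 15)) * 10.0,
        sample_ids=samples,
        feature_ids=[f"m{j}" for j in range(15)],
        block_label="meth",
    )
    expr.values[2, 3] = np.nan
    expr.missing_mask[2, 3] = True
    return [expr, meth]


@pytest.fixture
def block_files(tmp_path):
    """Two toy 10x20 TSV blocks on disk, as the CLI reads them."""
    rng = np.random.default_rng(11)
    samples = [f"S{i}" for i in range(10)]
    paths = []
    for label in ("expr", "meth"):
        df = pd.DataFrame(
            rng.standard_normal((10, 20)),
            index=samples,
            columns=[f"{label}_f{j}" for j in range(20)],
        )
        path = tmp_path / f"{label}.tsv"
        df.to_csv(path, sep="\t", index_label="sample_id")
        paths.append((label, path))
    return paths
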