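import numpy as np
import pandas as pd
import pytest

from mirkd.io import CtMatrix, SampleSheet


@pytest.fixture
def samples_2v2() -> SampleSheet:
    return SampleSheet(pd.DataFrame({
        "sample_id": ["KD1", "KD2", "CTL1", "CTL2"],
        "group": ["knockdown", "knockdown", "control", "control"],
        "label": ["si-1", "si-2", "nt-1", "nt-2"],
    }))


def make_ct(rows, max_cycle=40.0) -> CtMatrix:
    """Build a CtMatrix from (assay, mirna, plate, sample, ct, dupgroup) tuples."""
    df = pd.DataFrame(rows, columns=["assay_id", "mirna_name", "plate",
                                     "sample_id", "ct", "duplicate_group"])
    return CtMatrix(df, max_cycle=max_cycle)


def ct_from_grid(grid: pd.DataFrame, plate="A") -> CtMatrix:
    """CtMatrix from an assay x sample CT frame (NaN = undetermined)."""
    rows = []
    for assay in grid.index:
        for sample in grid.columns:
            rows.append((assay, assay, plate, sample, grid.loc[assay, sample], ""))
    return make_ct(rows)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160113)
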