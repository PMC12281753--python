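import numpy as np
import pandas as pd
import pytest

from nodsource.core_io import RANKS, CountTable, SampleMetadata, TaxonomyTable


def make_counts(matrix, asv_ids=None, sample_ids=None) -> CountTable:
    arr = np.asarray(matrix)
    asv_ids = asv_ids or [f"A{i+1}" for i in range(arr.shape[0])]
    sample_ids = sample_ids or [f"s{j+1}" for j in range(arr.shape[1])]
    return CountTable(pd.DataFrame(arr, index=asv_ids, columns=sample_ids))


def make_meta(rows) -> SampleMetadata:
    """rows: (sample_id, compartment, treatment, block, replicate)."""
    df = pd.DataFrame(
        rows, columns=["sample_id", "compartment", "treatment", "block", "replicate"]
    ).set_index("sample_id")
    return SampleMetadata(df)


def make_taxonomy(families: dict) -> TaxonomyTable:
    """families: asv_id -> family name (other ranks unassigned)."""
    df = pd.DataFrame(
        {asv: ["Bacteria"] + ["unassigned"] * 3 + [fam, "unassigned", "unassigned"]
         for asv, fam in families.items()},
        index=list(RANKS),
    ).T
    return TaxonomyTable(df)


@pytest.fixture
def plot_meta():
    """One plot with full compartment structure, plus a second block."""
    rows = []
    for blk in (1, 2):
        rows.append((f"bs{blk}", "bulk_soil", "P0", blk, 1))
        rows.append((f"rz{blk}", "rhizosphere", "P0", blk, 1))
        for r in (1, 2, 3):
            rows.append((f"rt{blk}_{r}", "root", "P0", blk, r))
            rows.append((f"nd{blk}_{r}", "nodule", "P0", blk, r))
    return make_meta(rows)
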