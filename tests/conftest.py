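import numpy as np
import pandas as pd
import pytest

from fosmap.data import ActivityDataset


def make_dataset(counts_by_condition: dict, regions=None) -> ActivityDataset:
    """Build an ActivityDataset from {condition: 2-D array-like} blocks."""
    rows, subjects, conditions = [], [], []
    for cond, block in counts_by_condition.items():
        block = np.atleast_2d(np.asarray(block, dtype=float))
        for i, row in enumerate(block):
            rows.append(row)
            subjects.append(f"{cond}_{i}")
            conditions.append(cond)
    n_regions = len(rows[0])
    if regions is None:
        regions = [f"R{i}" for i in range(n_regions)]
    counts = pd.DataFrame(rows, index=subjects, columns=regions)
    return ActivityDataset(counts, pd.Series(conditions, index=subjects))


@pytest.fixture
def toy_counts_csv(tmp_path):
    """A minimal 3-subject x 4-region counts file plus region metadata."""
    counts = tmp_path / "counts.csv"
    counts.write_text(
        "subject_id,condition,NacSh,NacC,ACC,PrL\n"
        "s1,HBT_ingroup,10,20,30,40\n"
        "s2,HBT_outgroup,11,21,31,41\n"
        "s3,baseline,12,22,32,42\n"
    )
    regions = tmp_path / "regions.csv"
    regions.write_text(
        "region_id,full_name,category,ap_mm\n"
        "NacSh,nucleus accumbens shell,striatal,2.0\n"
        "NacC,nucleus accumbens core,striatal,2.0\n"
        "ACC,anterior cingulate cortex,frontal,1.5\n"
        "PrL,prelimbic cortex,frontal,3.0\n"
    )
    return counts, regions
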