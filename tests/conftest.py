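import numpy as np
import pandas as pd
import pytest

from brainvar import BrainExpressionDataset, GenotypeCounts2x3


@pytest.fixture
def gender_table():
    """Case/control male-female counts of the emulated association sample."""
    return (520, 82, 515, 89)


@pytest.fixture
def hippocampus_genotype_counts():
    """Genotype-class counts (AA, AG, GG) of the emulated eQTL panel."""
    return (16, 53, 64)


@pytest.fixture
def example_counts():
    return GenotypeCounts2x3(
        case_MM=100, case_Mm=120, case_mm=80, ctrl_MM=100, ctrl_Mm=100, ctrl_mm=100
    )


@pytest.fixture
def tiny_expression_dataset():
    """2 genes x 4 samples, values chosen as exact powers of two."""
    meta = pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3", "s4"],
            "donor_id": ["d1", "d1", "d2", "d2"],
            "region": ["HIP", "HIP", "DFC", "DFC"],
            "age": [8.0, 2.0, 12.0, 4.0],
            "age_unit": ["pcw", "yrs", "pcw", "mos"],
        }
    )
    values = pd.DataFrame(
        np.array([[1.0, 2.0, 4.0, 8.0], [8.0, 4.0, 2.0, 1.0]]),
        index=["gene_a", "gene_b"],
        columns=meta["sample_id"],
    )
    return BrainExpressionDataset(meta=meta, values=values)
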