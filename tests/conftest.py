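import numpy as np
import pandas as pd
import pytest

from biletyper import SyntheticCohortConfig, generate_cohort, rank_genera_by_auc
from biletyper.data import AbundanceTable, CohortMetadata


@pytest.fixture(scope="session")
def default_cohort():
    """The default planted cohort: 20/20 samples, 150 genera, 17-genus
    signature at fold 4 with a 7-genus aggressive sub-signature."""
    return generate_cohort(SyntheticCohortConfig(seed=1))


@pytest.fixture(scope="session")
def default_ranking(default_cohort):
    table, records, _ = default_cohort
    return rank_genera_by_auc(table.relative(), records, "CCA", "BBD")


@pytest.fixture()
def tiny_table():
    """Two taxa x two samples counts table."""
    df = pd.DataFrame([[2, 0], [3, 5]], index=["A", "B"], columns=["s1", "s2"])
    return AbundanceTable(df, kind="counts")


def make_metadata(groups: dict[str, str], **kwargs) -> list[CohortMetadata]:
    return [CohortMetadata(sample_id=s, group=g, **kwargs) for s, g in groups.items()]
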