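import numpy as np
import pandas as pd
import pytest

from otutriage import AbundanceTable, GroupProfile, datasets


@pytest.fixture(scope="session")
def table1() -> pd.DataFrame:
    """Published group-mean abundance table (24 OTUs x 5 groups, percent)."""
    return datasets.group_mean_table()


@pytest.fixture(scope="session")
def table1_profiles(table1) -> dict[str, GroupProfile]:
    return {g: GroupProfile(g, table1[g]) for g in datasets.GROUPS}


@pytest.fixture()
def group_mean_fixture_table(table1) -> AbundanceTable:
    """A study table whose samples exactly replicate the published group means.

    Each group contributes three identical samples equal to its mean column,
    so group means recover the published columns exactly.
    """
    rows, meta = [], []
    for group in datasets.GROUPS:
        genotype = "nonDKO" if group == "nonDKO" else "DKO"
        treatment = "none" if group == "nonDKO" else group
        for i in range(3):
            sid = f"{group}_{i}"
            rows.append(pd.Series(table1[group].to_numpy(), index=table1.index, name=sid))
            meta.append({"sample_id": sid, "genotype": genotype, "treatment": treatment, "sex": "M"})
    data = pd.DataFrame(rows)
    metadata = pd.DataFrame(meta).set_index("sample_id")
    return AbundanceTable(data, metadata)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
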