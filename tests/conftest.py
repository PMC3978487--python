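import numpy as np
import pandas as pd
import pytest

from poolmark.data_model import (
    CLINICAL_COLUMNS,
    ClinicalTable,
    DatasetBundle,
    GeneMatrix,
    StudyCollection,
)


def make_clinical(sample_ids, **columns) -> ClinicalTable:
    """Clinical table with only the stated columns filled (rest missing)."""
    df = pd.DataFrame(index=pd.Index(list(sample_ids)), columns=list(CLINICAL_COLUMNS))
    df[:] = np.nan
    for col, values in columns.items():
        df[col] = values
    for col in CLINICAL_COLUMNS:
        if col not in ("er_status", "pr_status", "her2_status", "ln_status", "chemo", "hormone"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return ClinicalTable(df)


def make_bundle(dataset_id, genes, values, sample_ids=None, **clinical) -> DatasetBundle:
    """Bundle from a gene->list-of-values mapping plus clinical columns."""
    n = len(next(iter(values.values()))) if isinstance(values, dict) else np.shape(values)[1]
    sample_ids = list(sample_ids) if sample_ids is not None else [f"s{i+1}" for i in range(n)]
    if isinstance(values, dict):
        data = pd.DataFrame(values, index=sample_ids).T
        data = data.loc[list(genes)]
    else:
        data = pd.DataFrame(np.asarray(values, dtype=float), index=list(genes), columns=sample_ids)
    return DatasetBundle(
        dataset_id, GeneMatrix(dataset_id, data), make_clinical(sample_ids, **clinical)
    )


@pytest.fixture
def simple_bundle() -> DatasetBundle:
    """Six samples, one prognostic-looking gene, complete DFS follow-up."""
    return make_bundle(
        "d1",
        ["gA", "gB"],
        {"gA": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0], "gB": [6.0, 5.0, 4.0, 3.0, 2.0, 1.0]},
        dfs_time=[10.0, 20.0, 30.0, 15.0, 25.0, 35.0],
        dfs_event=[1.0, 1.0, 0.0, 1.0, 1.0, 0.0],
        er_status=["pos", "pos", "neg", "pos", np.nan, "neg"],
        ln_status=["neg", "neg", "neg", "pos", "pos", "neg"],
    )


@pytest.fixture
def simple_collection(simple_bundle) -> StudyCollection:
    other = make_bundle(
        "d2",
        ["gA", "gC"],
        {"gA": [2.0, 4.0, 6.0, 8.0], "gC": [1.0, 3.0, 5.0, 7.0]},
        dfs_time=[12.0, 18.0, 24.0, 30.0],
        dfs_event=[1.0, 0.0, 1.0, 0.0],
        os_time=[40.0, 50.0, 60.0, 70.0],
        os_event=[1.0, 1.0, 0.0, 0.0],
    )
    return StudyCollection([simple_bundle, other])
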