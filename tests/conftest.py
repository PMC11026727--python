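import numpy as np
import pandas as pd
import pytest

from nanoqsar import (
    ColumnSpec,
    DerivedRule,
    DescriptorSchema,
    FixtureConfig,
    TreatmentTable,
    generate_dataset,
    stratified_split,
)


@pytest.fixture(scope="session")
def dataset():
    """The default 110-row synthetic treatment table + schema."""
    return generate_dataset(FixtureConfig(seed=0))


@pytest.fixture(scope="session")
def splits(dataset):
    """Blind (30%), then test (25% of the rest), then train."""
    table, _ = dataset
    blind_split = stratified_split(table, 0.30, seed=11)
    tt = stratified_split(blind_split.train, 0.25, seed=12)
    return {"blind": blind_split.held_out, "test": tt.held_out, "train": tt.train}


@pytest.fixture()
def tiny_schema():
    """Two base descriptors and one difference-derived descriptor."""
    return DescriptorSchema(
        columns=[
            ColumnSpec("a", "numeric"),
            ColumnSpec("b", "numeric"),
            ColumnSpec("d", "numeric"),
        ],
        derived_rules=[DerivedRule(target="d", op="difference", a="a", b="b")],
    )


def make_table(values: dict, endpoint: list) -> TreatmentTable:
    """Build a small TreatmentTable from column -> values plus endpoint labels."""
    n = len(endpoint)
    df = pd.DataFrame(values)
    df["treatment_id"] = [f"t{i}" for i in range(n)]
    df["endpoint"] = endpoint
    df["provenance"] = "original"
    return TreatmentTable(df)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
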