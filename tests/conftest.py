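import numpy as np
import pandas as pd
import pytest

from iggseq import (
    CohortScenario,
    FlowSummary,
    FractionCountTable,
    RelAbundanceTable,
    SortSpec,
    generate_cohort,
)


@pytest.fixture(scope="session")
def small_scenario():
    return CohortScenario(n_pairs=2, n_taxa=25, n_gene_families=30)


@pytest.fixture(scope="session")
def small_bundle(small_scenario):
    """Two household pairs, sequenced shallowly: fast but fully structured."""
    return generate_cohort(small_scenario, SortSpec(read_depth=20_000), seed=42)


@pytest.fixture
def toy_rel_tables():
    """Hand-sized bound/unbound abundance tables over 3 taxa, 2 samples."""
    taxa = ["t1", "t2", "t3"]
    samples = ["s1", "s2"]
    pos = pd.DataFrame(
        [[0.5, 0.2], [0.3, 0.5], [0.2, 0.3]], index=taxa, columns=samples
    )
    neg = pd.DataFrame(
        [[0.1, 0.6], [0.6, 0.2], [0.3, 0.2]], index=taxa, columns=samples
    )
    flow = FlowSummary(
        pd.DataFrame(
            {
                "igg_pos_size": [0.4, 0.25],
                "igg_neg_size": [0.55, 0.7],
                "isotype_pct": [0.0, 0.0],
                "microbial_load": [2e11, 1e11],
            },
            index=samples,
        )
    )
    return (
        RelAbundanceTable(pos, "igg_pos"),
        RelAbundanceTable(neg, "igg_neg"),
        flow,
    )


@pytest.fixture
def count_table():
    df = pd.DataFrame(
        {"s1": [10.0, 30.0, 0.0], "s2": [5.0, 5.0, 10.0]},
        index=["t1", "t2", "t3"],
    )
    return FractionCountTable(df, "all")
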