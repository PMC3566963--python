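import io

import numpy as np
import pandas as pd
import pytest

from metadiff import (
    AbundanceTable,
    FixtureConfig,
    SampleMetadata,
    define_groups,
    generate_abundance,
    generate_hierarchy,
    parse_hierarchy,
)

KEGG_LIKE = "category\tpathway\tKO\nA\tpwX\tko1\nA\tpwX\tko2\nA\tpwY\tko2\n"


@pytest.fixture
def kegg_db():
    """Three-path KEGG-shaped hierarchy with one multi-parent leaf (ko2)."""
    return parse_hierarchy(io.StringIO(KEGG_LIKE))


@pytest.fixture
def kegg_counts():
    return AbundanceTable(
        pd.DataFrame(
            {"s1": [10.0, 6.0], "s2": [2.0, 4.0], "s3": [0.0, 8.0]},
            index=pd.Index(["ko1", "ko2"], name="feature_id"),
        )
    )


@pytest.fixture(scope="session")
def small_fixture():
    """Seeded synthetic benchmark shared across tests (db, table, metadata, truth)."""
    config = FixtureConfig(
        n_leaves=60,
        n_samples_per_group=8,
        n_spiked=5,
        sequencing_depth=8000,
        rng_seed=11,
    )
    db = generate_hierarchy(config)
    table, md_df, truth = generate_abundance(db, config)
    md = SampleMetadata(md_df, {"group": "categorical", "bmi": "numerical"})
    return config, db, table, md, truth


@pytest.fixture(scope="session")
def small_groups(small_fixture):
    _, _, _, md, _ = small_fixture
    return define_groups(md, ["group==caseA"], ["group==caseB"], "caseA", "caseB")


def random_tree_lineage(rng, n_leaves, n_levels):
    """Strict random tree lineage rows (root-first), for oracle tests."""
    sizes = [n_leaves]
    for _ in range(1, n_levels):
        sizes.append(max(1, sizes[-1] // 3))
    parent = {}
    for lvl in range(n_levels - 1):
        for i in range(sizes[lvl]):
            parent[(lvl, i)] = int(rng.integers(sizes[lvl + 1]))
    rows = []
    for i in range(n_leaves):
        chain = [f"L0_{i}"]
        j = i
        for lvl in range(n_levels - 1):
            j = parent[(lvl, j)]
            chain.append(f"L{lvl + 1}_{j}")
        rows.append("\t".join(reversed(chain)))
    header = "\t".join(f"level{l}" for l in reversed(range(n_levels)))
    return header + "\n" + "\n".join(rows) + "\n"
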