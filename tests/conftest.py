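import pandas as pd
import pytest

import genefabric as gf

BLOCK = ["G0002", "G0003", "G0004", "G0005", "G0006"]


@pytest.fixture(scope="session")
def small_config():
    return gf.SyntheticConfig(
        n_genes=60,
        cv_range=(0.08, 0.3),
        planted_folds={("G0001", "PTA"): 3.0, ("G0010", "PTB"): -2.5},
        correlation_blocks=[(BLOCK, 0.99)],
        spots_per_gene={"G0020": 2, "G0021": 3},
        failing_spot_fraction=0.1,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return gf.generate_dataset(small_config)


@pytest.fixture(scope="session")
def expression_set(small_dataset):
    table, _ = small_dataset
    return gf.normalize(gf.filter_probes(table))


@pytest.fixture(scope="session")
def gene_stats(expression_set):
    return gf.compute_descriptors(expression_set)


@pytest.fixture()
def toy_probe_table():
    """3 genes, 1 spot each, 1 condition, 4 replicas; bg = 0.

    Gene T2 sits at the sample median; T3 is exactly 3x the median in
    every replica.
    """
    rows = []
    values = {"T1": [1.0, 1.1, 0.9, 1.0], "T2": [2.0, 2.0, 2.0, 2.0], "T3": [6.0, 6.0, 6.0, 6.0]}
    for gene, vals in values.items():
        for k, v in enumerate(vals, 1):
            rows.append(
                {"probe_id": f"{gene}_s1", "gene": gene, "condition": "NOR",
                 "replica": k, "fg": v, "bg": 0.0}
            )
    return pd.DataFrame(rows)
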