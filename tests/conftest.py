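import numpy as np
import pandas as pd
import pytest

from tickmicro import synthdata
from tickmicro.tables_io import CountTable


@pytest.fixture
def tiny_table() -> CountTable:
    """Hand-written 4-sample, 4-taxon table with two groups."""
    counts = pd.DataFrame(
        {
            "TaxA": [3, 0, 5, 2],
            "TaxB": [0, 3, 1, 4],
            "TaxC": [1, 1, 0, 0],
            "TaxD": [10, 8, 12, 9],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    group = pd.Series(["g1", "g1", "g2", "g2"], index=counts.index, name="group")
    return CountTable(counts, group)


@pytest.fixture(scope="session")
def default_synth():
    """One default synthetic dataset shared across read-only tests."""
    return synthdata.generate_seasonal_counts(seed=7)


@pytest.fixture(scope="session")
def toy_suite():
    """Small named graphs used as oracles for topology/robustness checks."""
    return {
        "star8": synthdata.generate_toy_graph("star", 8),
        "path7": synthdata.generate_toy_graph("path", 7),
        "complete6": synthdata.generate_toy_graph("complete", 6),
        "two_cliques8": synthdata.generate_toy_graph("two_cliques", 8),
        "er12": synthdata.generate_toy_graph("erdos_renyi", 12, p=0.3, seed=4),
        "er10": synthdata.generate_toy_graph("erdos_renyi", 10, p=0.25, seed=9),
    }
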