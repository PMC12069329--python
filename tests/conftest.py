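import numpy as np
import pandas as pd
import pytest

from phytorank import datasets
from phytorank.molgraph import MolecularGraph


@pytest.fixture(scope="session")
def tiglic():
    return datasets.load_compound_graph("tiglic_acid")


@pytest.fixture(scope="session")
def six_cycle():
    labels = [f"c{i}" for i in range(6)]
    return MolecularGraph.from_edges(
        [(labels[i], labels[(i + 1) % 6]) for i in range(6)], name="cyclohexane"
    )


@pytest.fixture(scope="session")
def star4():
    return MolecularGraph.from_edges(
        [("hub", f"leaf{i}") for i in range(4)], name="star4"
    )


@pytest.fixture(scope="session")
def property_table():
    return datasets.load_property_table()


@pytest.fixture(scope="session")
def printed_indices():
    return datasets.load_printed_index_table()


@pytest.fixture(scope="session")
def decision_matrix():
    return datasets.load_decision_matrix()


@pytest.fixture(scope="session")
def weights():
    return datasets.load_weights()
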