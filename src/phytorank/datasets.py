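"""Bundled fixture data for the 11-compound neem phytochemical study.

Two kinds of fixtures ship with the package:

* **Structure-derived**: hydrogen-suppressed heavy-atom skeletons of the
  eleven phytochemicals as edge-list files, frozen from SMILES encodings of
  the published structure depictions (PubChem neutral forms).  The tiglic
  acid skeleton (7 heavy atoms) is unambiguous; the larger skeletons are
  best-effort reconstructions whose molecular formulas match the reported
  monoisotopic masses.
* **Printed tables**: the published per-compound physicochemical property
  values, topological-index values, ranking decision matrix and criterion
  weights, transcribed verbatim.  The ranking stage defaults to the printed
  decision matrix so published reference rankings reproduce exactly.
"""

from __future__ import annotations

from importlib.resources import as_file, files
from pathlib import Path

import pandas as pd

from .mcdm import DecisionMatrix, WeightVector, read_decision_matrix, read_weights
from .molgraph import MolecularGraph, read_edge_list
from .qspr import read_property_table

__all__ = [
    "COMPOUNDS",
    "graph_fixture_dir",
    "load_compound_graph",
    "load_compound_graphs",
    "load_property_table",
    "load_printed_index_table",
    "load_decision_matrix",
    "load_weights",
    "load_smiles",
]

#: Compound identifiers in published table order.
COMPOUNDS: tuple[str, ...] = (
    "azadirone",
    "azadirachtin",
    "stigmasterol",
    "tiglic_acid",
    "catechin",
    "scopoletin",
    "odoratone",
    "tirucallol",
    "nimbin",
    "nimbolide",
    "sugiol",
)

_DATA = files("phytorank.data")


def _data_path(name: str) -> Path:
    with as_file(_DATA / name) as p:
        return Path(p)


def graph_fixture_dir() -> Path:
    """Directory containing the bundled ``*.edges`` skeleton files."""
    return _data_path("graphs")


def load_compound_graph(compound_id: str) -> MolecularGraph:
    """Load one bundled compound skeleton by identifier."""
    if compound_id not in COMPOUNDS:
        raise KeyError(f"unknown compound {compound_id!r}")
    return read_edge_list(graph_fixture_dir() / f"{compound_id}.edges")


def load_compound_graphs() -> dict[str, MolecularGraph]:
    """All eleven bundled skeletons, keyed by compound identifier."""
    return {c: load_compound_graph(c) for c in COMPOUNDS}


def load_property_table() -> pd.DataFrame:
    """Published physicochemical properties (catechin enthalpy is missing)."""
    return read_property_table(_data_path("properties.csv"))


def load_printed_index_table() -> pd.DataFrame:
    """Published topological-index table, transcribed as printed."""
    return pd.read_csv(_data_path("indices_printed.csv"), index_col="compound_id")


def load_decision_matrix() -> DecisionMatrix:
    """Published ranking decision matrix (11 compounds x 6 index criteria)."""
    return read_decision_matrix(_data_path("decision_matrix.csv"))


def load_weights() -> WeightVector:
    """Published criterion weights (sum to one)."""
    return read_weights(_data_path("weights.csv"))


def load_smiles() -> pd.DataFrame:
    """SMILES encodings the edge-list fixtures were frozen from."""
    return pd.read_csv(_data_path("smiles.csv"), index_col="compound_id")
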