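"""Ten valency-based (degree-based) topological indices.

Every index here is a sum over edges of a function of the two endpoint
degrees, so the edge partition is a sufficient statistic: an index equals
``sum over classes of count * term(i, j)``.

Implemented indices (per-edge term for endpoint degrees ``i``, ``j``):

========  ====================================  ==========================
id        per-edge term                         common name
========  ====================================  ==========================
ABC       sqrt((i + j - 2) / (i * j))           atom-bond connectivity
M1        i + j                                 first Zagreb
AUZ       (i * j / (i + j - 2)) ** 3            augmented Zagreb
RLI       ln(i) * ln(j)                         Randic-type lodeg
SLI       ln(i) + ln(j)                         sum lordeg
ISI       i * j / (i + j)                       inverse sum indeg
MLI       |ln(i) - ln(j)|                       misbalance lodeg
MDI       |i - j|                               misbalance indeg
MMRDI     sqrt(max(i, j) / min(i, j))           max-min rodeg
ISLI      i * j / (i + j)                       inverse sum lordeg
========  ====================================  ==========================

ISLI is published with a defining formula identical to ISI, yet reference
tables list distinct values for the two columns; we implement the printed
formula literally and keep ISLI as a separate identifier so that decision
matrices built from published tables retain their ISLI column.  See
``docs/methods.md`` for the full discrepancy discussion.

The augmented Zagreb term divides by ``i + j - 2`` and is therefore
undefined on an edge whose endpoints are both pendant (degree-1) vertices;
such graphs are rejected rather than silently truncated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import IO, Callable, Iterable, Mapping, Sequence

import pandas as pd

from .molgraph import EdgePartition, MolecularGraph, edge_partition

__all__ = [
    "IndexId",
    "IndexVector",
    "TABLE_ORDER",
    "DegenerateEdgeClassError",
    "edge_term",
    "compute_index",
    "compute_all",
    "index_table",
    "write_index_table",
]


class DegenerateEdgeClassError(ValueError):
    """An edge class on which an index term is undefined (AUZ on (1, 1))."""


class IndexId(str, Enum):
    """Closed enumeration of the ten supported topological indices."""

    ABC = "ABC"
    M1 = "M1"
    AUZ = "AUZ"
    RLI = "RLI"
    SLI = "SLI"
    ISI = "ISI"
    MLI = "MLI"
    MDI = "MDI"
    MMRDI = "MMRDI"
    ISLI = "ISLI"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Column order used by published index tables and by the CSV writer.
TABLE_ORDER: tuple[IndexId, ...] = (
    IndexId.ISI,
    IndexId.MDI,
    IndexId.MMRDI,
    IndexId.ISLI,
    IndexId.ABC,
    IndexId.M1,
    IndexId.RLI,
    IndexId.SLI,
    IndexId.AUZ,
    IndexId.MLI,
)


def _auz(i: int, j: int) -> float:
    if i + j == 2:
        raise DegenerateEdgeClassError(
            "augmented Zagreb term undefined on edge class (1, 1)"
        )
    return (i * j / (i + j - 2)) ** 3


_TERMS: dict[IndexId, Callable[[int, int], float]] = {
    IndexId.ABC: lambda i, j: math.sqrt((i + j - 2) / (i * j)),
    IndexId.M1: lambda i, j: float(i + j),
    IndexId.AUZ: _auz,
    IndexId.RLI: lambda i, j: math.log(i) * math.log(j),
    IndexId.SLI: lambda i, j: math.log(i) + math.log(j),
    IndexId.ISI: lambda i, j: i * j / (i + j),
    IndexId.MLI: lambda i, j: abs(math.log(i) - math.log(j)),
    IndexId.MDI: lambda i, j: float(abs(i - j)),
    IndexId.MMRDI: lambda i, j: math.sqrt(max(i, j) / min(i, j)),
    # Printed defining formula; identical to ISI (kept distinct on purpose).
    IndexId.ISLI: lambda i, j: i * j / (i + j),
}


def edge_term(index_id: IndexId | str, i: int, j: int) -> float:
    """Per-edge contribution of one index for endpoint degrees ``i``, ``j``."""
    if i < 1 or j < 1:
        raise ValueError(f"degrees must be >= 1, got ({i}, {j})")
    return _TERMS[IndexId(index_id)](i, j)


def compute_index(partition: EdgePartition, index_id: IndexId | str) -> float:
    """Sum ``count * edge_term`` over the degree classes of *partition*.

    Classes are visited in sorted order so the floating-point sum is
    reproducible across runs and platforms.
    """
    index_id = IndexId(index_id)
    total = 0.0
    for (i, j), count in partition.sorted_items():
        total += count * edge_term(index_id, i, j)
    return total


@dataclass(frozen=True)
class IndexVector:
    """All ten index values for one compound."""

    compound_id: str
    values: Mapping[IndexId, float]

    def __post_init__(self) -> None:
        missing = set(IndexId) - set(self.values)
        if missing:
            raise ValueError(f"missing indices: {sorted(m.value for m in missing)}")
        bad = [k for k, v in self.values.items() if not math.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite index values: {bad}")

    def __getitem__(self, index_id: IndexId | str) -> float:
        return self.values[IndexId(index_id)]


def compute_all(g: MolecularGraph, compound_id: str | None = None) -> IndexVector:
    """Compute all ten indices of *g* from a single edge partition."""
    part = edge_partition(g)
    try:
        values = {iid: compute_index(part, iid) for iid in IndexId}
    except DegenerateEdgeClassError as exc:
        raise DegenerateEdgeClassError(
            f"graph {compound_id or g.name or '<unnamed>'}: {exc}"
        ) from exc
    return IndexVector(compound_id or g.name or "<unnamed>", values)


def index_table(vectors: Iterable[IndexVector]) -> pd.DataFrame:
    """Tabulate index vectors: one row per compound, columns in table order."""
    rows = {v.compound_id: [v[c] for c in TABLE_ORDER] for v in vectors}
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=[c.value for c in TABLE_ORDER]
    )
    df.index.name = "compound_id"
    return df


def write_index_table(
    vectors: Iterable[IndexVector] | pd.DataFrame, target: str | Path | IO[str]
) -> None:
    """Write an index table as CSV (compound_id column + ten index columns)."""
    df = vectors if isinstance(vectors, pd.DataFrame) else index_table(vectors)
    df.to_csv(target, float_format="%.6g")
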