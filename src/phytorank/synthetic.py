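"""Seeded generators for chemistry-like test inputs.

The generators mirror the statistical structure the analysis stages assume:

* molecular graphs — connected simple graphs with all degrees in
  ``[1, max_degree]`` (default 4, the carbon-skeleton bound), built as a
  uniform random labelled tree (Pruefer sequence, rejection-sampled to the
  degree cap) plus a controllable fraction of extra cycle-forming edges;
* property tables — ``PC = A + B*TI + C*TI^2 + eps`` with homoscedastic
  Gaussian noise, the generative inversion of the QSPR model;
* decision matrices — positive performance values, optionally with one
  alternative dominating every criterion, plus Dirichlet weights.

Every generator is fully determined by its seed (or an explicit
``numpy.random.Generator``); identical seeds give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .indices import IndexId, compute_all
from .mcdm import DecisionMatrix, WeightVector
from .molgraph import MolecularGraph, write_edge_list
from .qspr import PROPERTY_COLUMNS

__all__ = [
    "SynthesisConfig",
    "random_molecular_graph",
    "synth_property_table",
    "synth_decision_matrix",
    "make_fixtures",
]


@dataclass(frozen=True)
class SynthesisConfig:
    """Defaults for one synthetic study.

    ``n_vertices=20`` sits in the middle of the 7-51 heavy-atom range of
    the bundled phytochemicals; ``max_degree=4`` is the organic-skeleton
    valence bound; ``extra_edge_fraction=0.15`` yields the few rings per
    molecule typical of small natural products; ``noise_sd`` is expressed
    on the property scale.
    """

    n_vertices: int = 20
    max_degree: int = 4
    extra_edge_fraction: float = 0.15
    noise_sd: float = 1.0
    true_coefficients: tuple[float, float, float] = (10.0, 2.0, 0.0)
    n_compounds: int = 11
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vertices < 3:
            raise ValueError("n_vertices must be >= 3")
        if self.max_degree < 2:
            raise ValueError("max_degree must be >= 2")
        if not 0.0 <= self.extra_edge_fraction <= 1.0:
            raise ValueError("extra_edge_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _pruefer_tree(
    n: int, max_degree: int, rng: np.random.Generator, max_tries: int = 10_000
) -> list[tuple[int, int]]:
    """Uniform random labelled tree with degree cap, by rejection sampling.

    A vertex's tree degree is its multiplicity in the Pruefer sequence plus
    one, so the cap is checked on the sequence before decoding.
    """
    for _ in range(max_tries):
        seq = rng.integers(0, n, size=n - 2)
        counts = np.bincount(seq, minlength=n)
        if (counts + 1 > max_degree).any():
            continue
        degree = counts + 1
        edges: list[tuple[int, int]] = []
        leaves = sorted(v for v in range(n) if degree[v] == 1)
        seq_list = list(seq)
        import heapq

        heap = leaves[:]
        heapq.heapify(heap)
        for v in seq_list:
            leaf = heapq.heappop(heap)
            edges.append((leaf, v))
            degree[leaf] -= 1
            degree[v] -= 1
            if degree[v] == 1:
                heapq.heappush(heap, v)
        u, v = (w for w in range(n) if degree[w] == 1)
        edges.append((u, v))
        return edges
    raise ValueError(
        f"could not draw a tree on {n} vertices with max degree {max_degree}"
    )


def random_molecular_graph(
    n_vertices: int,
    max_degree: int = 4,
    extra_edge_fraction: float = 0.0,
    seed: int | np.random.Generator = 0,
    name: str = "",
) -> MolecularGraph:
    """Connected chemistry-like random graph with degrees in [1, max_degree].

    A uniform random spanning tree is drawn first; then
    ``round(extra_edge_fraction * (n - 1))`` extra edges are added, each
    chosen uniformly among vertex pairs that are not yet adjacent and whose
    endpoints both have degree below the cap.  Trees on >= 3 vertices have
    no edge between two degree-1 vertices, so every generated graph
    satisfies the augmented-Zagreb precondition.
    """
    cfg = SynthesisConfig(
        n_vertices=n_vertices,
        max_degree=max_degree,
        extra_edge_fraction=extra_edge_fraction,
    )
    rng = _rng(seed)
    n = cfg.n_vertices
    if n == 3:
        # the only labelled trees on 3 vertices are paths; skip sampling
        centre = int(rng.integers(0, 3))
        others = [v for v in range(3) if v != centre]
        edges = [(others[0], centre), (centre, others[1])]
    else:
        edges = _pruefer_tree(n, cfg.max_degree, rng)
    degree = np.bincount([w for e in edges for w in e], minlength=n)
    adjacent = {frozenset(e) for e in edges}
    n_extra = round(cfg.extra_edge_fraction * (n - 1))
    for _ in range(n_extra):
        candidates = [
            (u, v)
            for u in range(n)
            for v in range(u + 1, n)
            if degree[u] < cfg.max_degree
            and degree[v] < cfg.max_degree
            and frozenset((u, v)) not in adjacent
        ]
        if not candidates:
            break
        u, v = candidates[rng.integers(0, len(candidates))]
        edges.append((u, v))
        adjacent.add(frozenset((u, v)))
        degree[u] += 1
        degree[v] += 1
    return MolecularGraph.from_edges(
        [(f"v{u}", f"v{v}") for u, v in edges], name=name
    )


def synth_property_table(
    graphs: list[MolecularGraph],
    index_id: IndexId | str,
    A: float,
    B: float,
    C: float = 0.0,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    property_name: str = "boiling_point",
) -> pd.DataFrame:
    """Property table generated as ``PC = A + B*TI + C*TI^2 + N(0, sd^2)``."""
    if len(graphs) < 3:
        raise ValueError("need at least 3 graphs")
    if property_name not in PROPERTY_COLUMNS:
        raise ValueError(f"unknown property {property_name!r}")
    rng = _rng(seed)
    ids, ti = [], []
    for k, g in enumerate(graphs):
        vec = compute_all(g, g.name or f"synthetic_{k}")
        ids.append(vec.compound_id)
        ti.append(vec[index_id])
    ti_arr = np.asarray(ti)
    pc = A + B * ti_arr + C * ti_arr**2 + rng.normal(0.0, noise_sd, len(ti_arr))
    df = pd.DataFrame({property_name: pc}, index=pd.Index(ids, name="compound_id"))
    return df


def synth_decision_matrix(
    m: int,
    n: int,
    dominance: str = "none",
    seed: int | np.random.Generator = 0,
) -> tuple[DecisionMatrix, WeightVector]:
    """Positive random decision matrix and Dirichlet criterion weights.

    With ``dominance='one_dominant'`` the first alternative is rescaled to
    strictly exceed every other alternative on every criterion, so both
    VIKOR and SAW must rank it first.
    """
    if m < 2 or n < 1:
        raise ValueError("need m >= 2 alternatives and n >= 1 criteria")
    if dominance not in ("none", "one_dominant"):
        raise ValueError(f"unknown dominance mode {dominance!r}")
    rng = _rng(seed)
    # lognormal keeps entries positive with criterion-scale heterogeneity
    scales = rng.uniform(1.0, 50.0, size=n)
    values = rng.lognormal(mean=0.0, sigma=0.4, size=(m, n)) * scales
    if dominance == "one_dominant":
        values[0] = values.max(axis=0) * 1.25
    alternatives = [f"alt{i + 1}" for i in range(m)]
    criteria = [f"crit{j + 1}" for j in range(n)]
    matrix = DecisionMatrix(pd.DataFrame(values, index=alternatives, columns=criteria))

    raw = rng.dirichlet(np.ones(n))
    w = np.round(raw, 6)
    w[np.argmax(w)] += 1.0 - w.sum()  # force exact unit sum after rounding
    weights = WeightVector(pd.Series(w, index=criteria))
    return matrix, weights


def make_fixtures(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Regenerate every synthetic test asset under *out_dir*.

    Writes a directory of random molecular graphs, a property table planted
    on the M1 index, and a decision matrix with weights; returns the paths.
    """
    out = Path(out_dir)
    (out / "graphs").mkdir(parents=True, exist_ok=True)
    rng = _rng(seed)
    cfg = SynthesisConfig(seed=seed)
    graphs = [
        random_molecular_graph(
            cfg.n_vertices,
            cfg.max_degree,
            cfg.extra_edge_fraction,
            seed=rng,
            name=f"synthetic_{k}",
        )
        for k in range(cfg.n_compounds)
    ]
    paths: dict[str, Path] = {}
    for g in graphs:
        p = out / "graphs" / f"{g.name}.edges"
        write_edge_list(g, p, header=f"{g.name}: synthetic random molecular graph")
        paths[g.name] = p
    a, b, c = cfg.true_coefficients
    props = synth_property_table(
        graphs, IndexId.M1, a, b, c, noise_sd=cfg.noise_sd, seed=rng
    )
    paths["properties"] = out / "properties.csv"
    props.to_csv(paths["properties"])
    matrix, weights = synth_decision_matrix(cfg.n_compounds, 6, seed=rng)
    paths["decision_matrix"] = out / "decision_matrix.csv"
    matrix.values.to_csv(paths["decision_matrix"], index_label="alternative")
    paths["weights"] = out / "weights.csv"
    weights.weights.rename_axis("criterion").rename("weight").to_csv(paths["weights"])
    return paths
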