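"""Multi-criteria ranking of compounds: VIKOR, SAW and rank concordance.

VIKOR (compromise ranking)
    For a decision matrix ``theta[m, n]`` with weights ``w[n]`` summing to
    one, each criterion column is normalized to its distance from the
    per-criterion ideal ``A*`` relative to the ideal/anti-ideal span, then
    weighted.  Group utility ``S_i`` is the row sum, individual regret
    ``R_i`` the row maximum, and the compromise index

        Omega_i = lam * (S_i - S*) / (S- - S*) + (1 - lam) * (R_i - R*) / (R- - R*)

    with trade-off parameter ``lam`` (default 0.5) balances the two.
    Smaller Omega is better; rank 1 is the smallest.

SAW (simple additive weighting)
    Each column is normalized (default: divide by the column maximum, the
    scheme that published reference tables follow; vector normalization by
    the column Euclidean norm is available), multiplied by its weight and
    summed per alternative.  Larger totals are better; rank 1 is the
    largest.

Agreement between two rankings is quantified by the Spearman rank
correlation for tie-free rankings, ``rho = 1 - 6*sum(d^2)/(N*(N^2-1))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "DecisionMatrix",
    "WeightVector",
    "IdealSolutions",
    "VikorResult",
    "SawResult",
    "read_decision_matrix",
    "read_weights",
    "ideal_solutions",
    "vikor_normalize",
    "vikor_rank",
    "saw_normalize",
    "saw_rank",
    "spearman_rho",
]

Orientation = Literal["beneficial", "non_beneficial"]


@dataclass(frozen=True)
class DecisionMatrix:
    """Alternatives x criteria performance matrix with orientations.

    All criteria default to beneficial (larger is better); a per-criterion
    orientation flag supports cost-type criteria for generality.
    """

    values: pd.DataFrame
    orientation: Mapping[str, Orientation] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.values
        if df.shape[0] < 2:
            raise ValueError("need at least 2 alternatives")
        if df.shape[1] < 1:
            raise ValueError("need at least 1 criterion")
        if df.isna().any().any():
            raise ValueError("decision matrix must be complete (no missing cells)")
        unknown = set(self.orientation) - set(df.columns)
        if unknown:
            raise ValueError(f"orientation for unknown criteria: {sorted(unknown)}")

    @property
    def alternatives(self) -> list[str]:
        return list(self.values.index)

    @property
    def criteria(self) -> list[str]:
        return list(self.values.columns)

    def orientation_of(self, criterion: str) -> Orientation:
        return self.orientation.get(criterion, "beneficial")


@dataclass(frozen=True)
class WeightVector:
    """Non-negative criterion weights summing to one."""

    weights: pd.Series

    def __post_init__(self) -> None:
        w = self.weights
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        if abs(float(w.sum()) - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {float(w.sum()):.12g}")

    def aligned(self, criteria: Sequence[str]) -> np.ndarray:
        missing = set(criteria) - set(self.weights.index)
        if missing:
            raise ValueError(f"no weight for criteria: {sorted(missing)}")
        return self.weights.loc[list(criteria)].to_numpy(dtype=float)


@dataclass(frozen=True)
class IdealSolutions:
    """Per-criterion best (A*) and worst (A-) performance."""

    best: pd.Series
    worst: pd.Series


@dataclass(frozen=True)
class VikorResult:
    """Per-alternative S (utility), R (regret), Omega and rank, plus extremes."""

    table: pd.DataFrame  # columns: S, R, Omega, rank
    normalized: pd.DataFrame
    s_best: float
    s_worst: float
    r_best: float
    r_worst: float
    lam: float

    @property
    def ranking(self) -> pd.Series:
        return self.table["rank"]


@dataclass(frozen=True)
class SawResult:
    """Normalized and weighted matrices, per-alternative totals and ranks."""

    normalized: pd.DataFrame
    weighted: pd.DataFrame
    totals: pd.Series
    ranks: pd.Series
    scheme: str

    @property
    def table(self) -> pd.DataFrame:
        out = self.weighted.copy()
        out["total"] = self.totals
        out["rank"] = self.ranks
        return out


def read_decision_matrix(source: str | Path | IO[str]) -> DecisionMatrix:
    """Read a decision-matrix CSV: first column alternatives, header criteria."""
    df = pd.read_csv(source, index_col=0)
    df.index = df.index.astype(str)
    return DecisionMatrix(df.astype(float))


def read_weights(source: str | Path | IO[str]) -> WeightVector:
    """Read a weights CSV with columns ``criterion, weight``."""
    df = pd.read_csv(source)
    if not {"criterion", "weight"} <= set(df.columns):
        raise ValueError("weights CSV needs 'criterion' and 'weight' columns")
    return WeightVector(pd.Series(df["weight"].to_numpy(float), index=df["criterion"]))


def ideal_solutions(matrix: DecisionMatrix) -> IdealSolutions:
    """Column-wise best/worst performance respecting criterion orientation."""
    best, worst = {}, {}
    for c in matrix.criteria:
        col = matrix.values[c]
        if matrix.orientation_of(c) == "beneficial":
            best[c], worst[c] = float(col.max()), float(col.min())
        else:
            best[c], worst[c] = float(col.min()), float(col.max())
    return IdealSolutions(pd.Series(best), pd.Series(worst))


def vikor_normalize(matrix: DecisionMatrix, weights: WeightVector) -> pd.DataFrame:
    """Weighted normalized distance from the ideal, ``w*(A*-x)/(A*-A-)``.

    Entries lie in ``[0, w]`` per criterion: the best alternative scores 0,
    the worst scores the full criterion weight.
    """
    ideals = ideal_solutions(matrix)
    w = weights.aligned(matrix.criteria)
    span = ideals.best - ideals.worst
    constant = span[span == 0]
    if not constant.empty:
        raise ValueError(
            f"criterion with constant column (A* = A-): {list(constant.index)}"
        )
    normalized = (ideals.best - matrix.values) / span
    return normalized * w


def vikor_rank(
    matrix: DecisionMatrix, weights: WeightVector, lam: float = 0.5
) -> VikorResult:
    """Full VIKOR procedure; rank 1 has the smallest compromise index."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    normalized = vikor_normalize(matrix, weights)
    s = normalized.sum(axis=1)
    r = normalized.max(axis=1)
    s_best, s_worst = float(s.min()), float(s.max())
    r_best, r_worst = float(r.min()), float(r.max())
    if s_worst == s_best or r_worst == r_best:
        raise ValueError("all alternatives perform identically; VIKOR undefined")
    omega = lam * (s - s_best) / (s_worst - s_best) + (1 - lam) * (r - r_best) / (
        r_worst - r_best
    )
    ranks = pd.Series(
        rankdata(omega.to_numpy(), method="min").astype(int), index=omega.index
    )
    table = pd.DataFrame({"S": s, "R": r, "Omega": omega, "rank": ranks})
    return VikorResult(table, normalized, s_best, s_worst, r_best, r_worst, lam)


def saw_normalize(
    matrix: DecisionMatrix, scheme: Literal["max", "vector"] = "max"
) -> pd.DataFrame:
    """Normalize columns by their maximum (default) or Euclidean norm."""
    df = matrix.values
    if scheme == "max":
        col_max = df.max(axis=0)
        if (col_max <= 0).any():
            bad = list(col_max[col_max <= 0].index)
            raise ValueError(f"non-positive column maxima under max scheme: {bad}")
        return df / col_max
    if scheme == "vector":
        norms = np.sqrt((df**2).sum(axis=0))
        if (norms == 0).any():
            bad = list(norms[norms == 0].index)
            raise ValueError(f"zero column norm under vector scheme: {bad}")
        return df / norms
    raise ValueError(f"unknown normalization scheme {scheme!r}")


def saw_rank(
    matrix: DecisionMatrix,
    weights: WeightVector,
    scheme: Literal["max", "vector"] = "max",
) -> SawResult:
    """Simple additive weighting; rank 1 has the largest weighted total."""
    normalized = saw_normalize(matrix, scheme)
    w = weights.aligned(matrix.criteria)
    weighted = normalized * w
    totals = weighted.sum(axis=1)
    ranks = pd.Series(
        rankdata(-totals.to_numpy(), method="min").astype(int), index=totals.index
    )
    return SawResult(normalized, weighted, totals, ranks, scheme)


def spearman_rho(rank_a: Sequence[int], rank_b: Sequence[int]) -> float:
    """Spearman rank correlation for two tie-free rankings of the same items.

    Implements ``1 - 6*sum(d_i^2)/(N*(N^2-1))`` directly, the closed form
    valid when both arguments are permutations of 1..N.
    """
    a = np.asarray(rank_a, dtype=float)
    b = np.asarray(rank_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("rankings must have equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 ranked items")
    d = a - b
    return float(1.0 - 6.0 * float(d @ d) / (n * (n**2 - 1)))
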