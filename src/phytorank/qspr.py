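"""QSPR regression: physicochemical properties on topological indices.

Two model forms are fitted by ordinary least squares,

    linear      PC = A + B*TI
    quadratic   PC = A + B*TI + C*TI^2

where PC is a physicochemical property and TI a topological index.  Model
admissibility follows the usual QSPR screening thresholds: the F-test
p-value must fall below 0.05 and the correlation R must reach 0.6.  Among
admissible fits the best index for a property is the one maximizing R^2.

Missing property cells are handled by listwise deletion per property-index
pair, so each fit reports its own sample size N.  No multiple-testing
correction is applied across the property x index grid; with 5 properties
and 10 indices this is a deliberately exploratory screen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "PROPERTY_COLUMNS",
    "RegressionFit",
    "read_property_table",
    "fit_linear",
    "fit_quadratic",
    "correlation_matrix",
    "fit_all",
    "rank_models",
    "fits_to_frame",
]

#: Closed set of supported property columns (annotation units in comments).
PROPERTY_COLUMNS: tuple[str, ...] = (
    "enthalpy_of_vaporization",  # kJ/mol
    "boiling_point",  # degC
    "polarizability",  # A^3
    "molar_refractivity",  # cm^3
    "monoisotopic_mass",  # Da
)

_MISSING_TOKENS = {"", "-", "—", "–", "na", "nan", "none"}


@dataclass(frozen=True)
class RegressionFit:
    """One fitted property-index model with its statistical metrics.

    ``R`` is the signed square root of ``R2`` for linear fits (sign of B)
    and the Pearson correlation between fitted and observed values for
    quadratic fits, where a signed convention has no analogue.
    """

    property_name: str
    index_id: str
    form: Literal["linear", "quadratic"]
    A: float
    B: float
    C: float | None
    N: int
    R: float
    R2: float
    F: float
    p: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = self.A + self.B * x
        if self.C is not None:
            y = y + self.C * x**2
        return y


def read_property_table(source: str | Path | IO[str]) -> pd.DataFrame:
    """Read a property CSV: ``compound_id`` column + property columns.

    Dash-like tokens ('—', '-', empty) are treated as missing values.
    Column names must come from :data:`PROPERTY_COLUMNS`.
    """
    df = pd.read_csv(source, dtype=str)
    if "compound_id" not in df.columns:
        raise ValueError("property table needs a 'compound_id' column")
    df = df.set_index("compound_id")
    unknown = set(df.columns) - set(PROPERTY_COLUMNS)
    if unknown:
        raise ValueError(f"unknown property columns: {sorted(unknown)}")
    cleaned = df.apply(
        lambda col: pd.to_numeric(
            col.map(
                lambda v: np.nan
                if v is np.nan or str(v).strip().lower() in _MISSING_TOKENS
                else v
            )
        )
    )
    return cleaned


def _paired(x: Sequence[float], y: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def fit_linear(
    x: Sequence[float],
    y: Sequence[float],
    property_name: str = "",
    index_id: str = "",
) -> RegressionFit:
    """OLS fit of ``y = A + B*x`` after listwise deletion of missing pairs."""
    x, y = _paired(x, y)
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant; slope is unidentifiable")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    a, b = model.params
    r2 = float(model.rsquared)
    r = float(np.sign(b) * np.sqrt(max(r2, 0.0)))
    return RegressionFit(
        property_name=property_name,
        index_id=index_id,
        form="linear",
        A=float(a),
        B=float(b),
        C=None,
        N=n,
        R=r,
        R2=r2,
        F=float(model.fvalue),
        p=float(model.f_pvalue),
    )


def fit_quadratic(
    x: Sequence[float],
    y: Sequence[float],
    property_name: str = "",
    index_id: str = "",
) -> RegressionFit:
    """OLS fit of ``y = A + B*x + C*x^2`` after listwise deletion."""
    x, y = _paired(x, y)
    n = len(x)
    if n < 4:
        raise ValueError(f"need at least 4 complete pairs, got {n}")
    design = np.column_stack([np.ones(n), x, x**2])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("design matrix is rank deficient (constant or two-level x)")
    model = sm.OLS(y, design).fit()
    a, b, c = model.params
    fitted = model.fittedvalues
    r = float(np.corrcoef(fitted, y)[0, 1])
    return RegressionFit(
        property_name=property_name,
        index_id=index_id,
        form="quadratic",
        A=float(a),
        B=float(b),
        C=float(c),
        N=n,
        R=r,
        R2=float(model.rsquared),
        F=float(model.fvalue),
        p=float(model.f_pvalue),
    )


def correlation_matrix(
    properties: pd.DataFrame, index_values: pd.DataFrame, min_pairs: int = 3
) -> pd.DataFrame:
    """Pairwise Pearson correlations between properties (rows) and indices.

    Each cell uses the compounds complete for that pair; cells with fewer
    than *min_pairs* complete pairs are NaN with a warning.
    """
    common = properties.index.intersection(index_values.index)
    props = properties.loc[common]
    idx = index_values.loc[common]
    out = pd.DataFrame(
        np.nan, index=list(props.columns), columns=list(idx.columns)
    )
    for p in props.columns:
        for q in idx.columns:
            x, y = _paired(idx[q].to_numpy(), props[p].to_numpy())
            if len(x) < min_pairs:
                warnings.warn(
                    f"fewer than {min_pairs} complete pairs for {p} vs {q}",
                    stacklevel=2,
                )
                continue
            out.loc[p, q] = float(np.corrcoef(x, y)[0, 1])
    return out


def fit_all(
    properties: pd.DataFrame,
    index_values: pd.DataFrame,
    form: Literal["linear", "quadratic"],
) -> list[RegressionFit]:
    """Fit every property x index pair that has enough complete data."""
    fitter = fit_linear if form == "linear" else fit_quadratic
    common = properties.index.intersection(index_values.index)
    props = properties.loc[common]
    idx = index_values.loc[common]
    fits: list[RegressionFit] = []
    for p in props.columns:
        for q in idx.columns:
            try:
                fits.append(
                    fitter(
                        idx[q].to_numpy(),
                        props[p].to_numpy(),
                        property_name=p,
                        index_id=str(q),
                    )
                )
            except ValueError as exc:
                warnings.warn(f"skipping {p} ~ {q} ({form}): {exc}", stacklevel=2)
    return fits


def rank_models(
    properties: pd.DataFrame,
    index_values: pd.DataFrame,
    form: Literal["linear", "quadratic"],
    max_p: float = 0.05,
    min_r: float = 0.6,
) -> tuple[pd.DataFrame, dict[str, RegressionFit]]:
    """All fits plus, per property, the admissible fit maximizing R^2.

    Admissibility: ``p < max_p`` and ``R >= min_r``.  A property with no
    admissible fit is absent from the best-fit mapping.
    """
    fits = fit_all(properties, index_values, form)
    table = fits_to_frame(fits)
    best: dict[str, RegressionFit] = {}
    for fit in fits:
        if fit.p < max_p and fit.R >= min_r:
            cur = best.get(fit.property_name)
            if cur is None or fit.R2 > cur.R2:
                best[fit.property_name] = fit
    return table, best


def fits_to_frame(fits: Iterable[RegressionFit]) -> pd.DataFrame:
    """Tabulate fits as a DataFrame, one row per property-index pair."""
    rows = [
        {
            "property": f.property_name,
            "index": f.index_id,
            "form": f.form,
            "A": f.A,
            "B": f.B,
            "C": f.C,
            "N": f.N,
            "R": f.R,
            "R2": f.R2,
            "F": f.F,
            "p": f.p,
        }
        for f in fits
    ]
    return pd.DataFrame(rows)


def plot_fit(
    fit: RegressionFit,
    x: Sequence[float],
    y: Sequence[float],
    target: str | Path,
) -> None:
    """Diagnostic scatter of observed data with the fitted curve (matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x, y = _paired(x, y)
    grid = np.linspace(x.min(), x.max(), 200)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, y, color="tab:blue", label="observed")
    ax.plot(grid, fit.predict(grid), color="tab:red", label=f"{fit.form} fit")
    ax.set_xlabel(fit.index_id or "index")
    ax.set_ylabel(fit.property_name or "property")
    ax.set_title(f"R² = {fit.R2:.4f} (N = {fit.N})")
    ax.legend()
    fig.tight_layout()
    fig.savefig(target, dpi=120)
    plt.close(fig)
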