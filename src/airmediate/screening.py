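"""Pearson correlation screening.

Candidate mediators and moderators are shortlisted by the pairwise
Pearson product-moment correlation between the outcome, pollutant and
meteorological series, with two-sided p-values from the exact t
reference distribution on n−2 degrees of freedom and the conventional
star flags (* p<0.05, ** p<0.01).  Correlation magnitudes are binned
into weak / moderate / strong bands at 0.36 and 0.68.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import TimeSeriesTable
from .errors import DegenerateColumnError, InsufficientDataError

__all__ = ["CorrelationMatrix", "pearson_matrix", "categorize_strength"]

# |r| below the first bound is weak, below the second moderate, else strong.
_STRENGTH_BOUNDS = (0.36, 0.68)


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix with p-values.

    ``r`` and ``p`` are DataFrames indexed by variable name; the
    diagonal of ``r`` is exactly 1 and the diagonal of ``p`` is NaN
    (self-correlation has no sampling distribution).
    """

    variables: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    n: int

    def stars(self) -> pd.DataFrame:
        """Significance flags: '**' for p<0.01, '*' for p<0.05, else ''."""
        flags = np.where(self.p.values < 0.01, "**", np.where(self.p.values < 0.05, "*", ""))
        flags = np.where(np.isnan(self.p.values), "", flags)
        return pd.DataFrame(flags, index=self.variables, columns=self.variables)

    def to_long(self) -> pd.DataFrame:
        """Lower-triangle long format: var1, var2, r, p, stars, strength."""
        stars = self.stars()
        rows = []
        for i, v1 in enumerate(self.variables):
            for v2 in self.variables[:i]:
                r = float(self.r.loc[v1, v2])
                rows.append(
                    {
                        "var1": v1,
                        "var2": v2,
                        "r": r,
                        "p": float(self.p.loc[v1, v2]),
                        "stars": stars.loc[v1, v2],
                        "strength": categorize_strength(r),
                    }
                )
        return pd.DataFrame(rows, columns=["var1", "var2", "r", "p", "stars", "strength"])


def pearson_matrix(table: TimeSeriesTable, columns: Sequence[str] | None = None) -> CorrelationMatrix:
    """Pairwise Pearson correlations among the named columns.

    The coefficient uses the product-moment formula; the p-value is the
    two-sided tail of ``t = r sqrt((n-2)/(1-r^2))`` on n−2 degrees of
    freedom.  Perfect correlations (|r| = 1) get p = 0.

    Raises
    ------
    DegenerateColumnError
        If a named column has zero variance (its correlation is
        undefined); the error names the column.
    """
    cols = list(columns) if columns is not None else table.columns
    table.require_columns(cols)
    n = table.n
    if n < 3:
        raise InsufficientDataError("need at least 3 rows for correlation p-values")
    data = table.frame[cols].to_numpy(dtype=float)
    sd = data.std(axis=0, ddof=1)
    for name, s in zip(cols, sd):
        if s == 0.0:
            raise DegenerateColumnError(f"column {name!r} has zero variance")
    r = np.corrcoef(data, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    np.fill_diagonal(p, np.nan)
    return CorrelationMatrix(
        variables=cols,
        r=pd.DataFrame(r, index=cols, columns=cols),
        p=pd.DataFrame(p, index=cols, columns=cols),
        n=n,
    )


def categorize_strength(r: float) -> str:
    """Bin a correlation magnitude into 'weak', 'moderate' or 'strong'.

    Bands are half-open: |r| < 0.36 weak, 0.36 ≤ |r| < 0.68 moderate,
    |r| ≥ 0.68 strong — a continuous version of the integer-rounded
    screening bands so every |r| ≤ 1 maps to exactly one label.
    """
    a = abs(float(r))
    if a > 1.0:
        raise ValueError(f"|r| must be ≤ 1, got {r}")
    if a < _STRENGTH_BOUNDS[0]:
        return "weak"
    if a < _STRENGTH_BOUNDS[1]:
        return "moderate"
    return "strong"
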