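"""Core table type for daily environmental-epidemiology series.

A :class:`TimeSeriesTable` is a thin, validated wrapper around a
date-indexed :class:`pandas.DataFrame` of numeric columns (an outcome such
as daily case counts, one or more candidate mediators such as pollutant
indices, and meteorological covariates).  The wrapper enforces the
contracts every downstream stage relies on: equal-length numeric columns,
strictly increasing daily dates, and no missing values after load-time
complete-case deletion.  It also carries the bookkeeping for mean
centering so effects can be mapped back to the original scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataFormatError, InsufficientDataError

__all__ = ["TimeSeriesTable", "VariableRoles", "read_table", "center"]

logger = logging.getLogger(__name__)

_MIN_ROWS = 3


@dataclass(frozen=True)
class TimeSeriesTable:
    """Validated daily table of numeric analysis variables.

    Parameters
    ----------
    frame
        DataFrame with a :class:`pandas.DatetimeIndex` (strictly
        increasing) and float columns.  No missing values are allowed;
        use :func:`read_table` to load raw CSV with complete-case
        deletion.
    center_shifts
        Means already subtracted from columns, keyed by column name.
        Empty for a raw table; populated by :func:`center`.
    """

    frame: pd.DataFrame
    center_shifts: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        frame = self.frame
        if not isinstance(frame.index, pd.DatetimeIndex):
            raise DataFormatError("table index must be a DatetimeIndex")
        if len(frame) < _MIN_ROWS:
            raise InsufficientDataError(
                f"need at least {_MIN_ROWS} complete rows, got {len(frame)}"
            )
        if not frame.index.is_monotonic_increasing or frame.index.has_duplicates:
            raise DataFormatError("dates must be strictly increasing")
        non_numeric = [
            c for c in frame.columns if not np.issubdtype(frame[c].dtype, np.number)
        ]
        if non_numeric:
            raise DataFormatError(f"non-numeric data columns: {non_numeric}")
        if frame.isna().any().any():
            raise DataFormatError("table contains missing values after validation")

    @property
    def n(self) -> int:
        """Number of rows."""
        return len(self.frame)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.frame.index

    def column(self, name: str) -> np.ndarray:
        """Return one column as a float array (raises ``KeyError`` if absent)."""
        return self.frame[name].to_numpy(dtype=float)

    def require_columns(self, names: Iterable[str]) -> None:
        missing = [c for c in names if c not in self.frame.columns]
        if missing:
            raise KeyError(f"unknown column(s): {missing}")

    def to_csv(self, path, date_column: str = "date") -> None:
        """Write the table as CSV with an ISO-8601 date column."""
        out = self.frame.copy()
        out.insert(0, date_column, out.index.strftime("%Y-%m-%d"))
        out.to_csv(path, index=False)

    def with_frame(self, frame: pd.DataFrame) -> "TimeSeriesTable":
        return replace(self, frame=frame)


@dataclass(frozen=True)
class VariableRoles:
    """Assignment of table columns to the mediation roles.

    ``x`` is the focal antecedent (e.g. a meteorological driver), ``m``
    the mediator (e.g. an air-quality index), ``y`` the outcome (daily
    case counts).  ``w`` and ``z`` are optional moderators of the X→M
    and/or X→Y paths; which of them a given model structure requires is
    checked by :class:`airmediate.mediation.ModelSpec`.
    """

    x: str
    m: str
    y: str
    w: str | None = None
    z: str | None = None

    def __post_init__(self) -> None:
        core = [self.x, self.m, self.y]
        if len(set(core)) != 3:
            raise ValueError(f"x, m, y must be distinct, got {core}")
        mods = [v for v in (self.w, self.z) if v is not None]
        if len(mods) != len(set(mods)):
            raise ValueError("moderators w and z must be distinct")
        overlap = set(mods) & set(core)
        if overlap:
            raise ValueError(f"moderator(s) {sorted(overlap)} collide with x/m/y roles")

    @property
    def assigned(self) -> list[str]:
        """All assigned column names, x, m, y first."""
        return [self.x, self.m, self.y] + [v for v in (self.w, self.z) if v]


def read_table(path, date_column: str = "date") -> TimeSeriesTable:
    """Load and validate a daily CSV table.

    Rows with any missing value (empty cell or ``NA``) are dropped and
    the drop count is logged.  Dates must parse as ISO-8601 and be
    strictly increasing after the drop.

    Raises
    ------
    DataFormatError
        Unparseable dates, non-numeric data columns, or non-increasing
        dates.
    InsufficientDataError
        Fewer than 3 complete rows remain.
    """
    raw = pd.read_csv(path, na_values=["NA"], keep_default_na=True)
    if date_column not in raw.columns:
        raise DataFormatError(f"date column {date_column!r} not found in {path}")
    try:
        dates = pd.to_datetime(raw[date_column], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise DataFormatError(f"unparseable dates in {date_column!r}: {exc}") from exc
    data = raw.drop(columns=[date_column])
    for col in data.columns:
        if not np.issubdtype(data[col].dtype, np.number):
            coerced = pd.to_numeric(data[col], errors="coerce")
            # distinguish "text column" from "numeric with missing markers"
            if coerced.isna().sum() > data[col].isna().sum():
                raise DataFormatError(f"non-numeric values in column {col!r}")
            data[col] = coerced
    complete = ~data.isna().any(axis=1) & ~dates.isna()
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("read_table: dropped %d incomplete row(s) from %s", n_dropped, path)
    frame = data.loc[complete].astype(float)
    frame.index = pd.DatetimeIndex(dates[complete])
    if len(frame) < _MIN_ROWS:
        raise InsufficientDataError(
            f"only {len(frame)} complete rows in {path}; need at least {_MIN_ROWS}"
        )
    table = TimeSeriesTable(frame)
    object.__setattr__(table, "n_dropped", n_dropped)  # informational, not part of equality
    return table


def center(table: TimeSeriesTable, columns: Sequence[str]) -> TimeSeriesTable:
    """Subtract the sample mean from each named column.

    The subtracted means are recorded in ``center_shifts`` (accumulating
    across repeated calls) so results can be reported on the original
    scale.  Centering an already-centered column is a no-op up to
    floating-point rounding, making the operation idempotent.
    """
    table.require_columns(columns)
    frame = table.frame.copy()
    shifts = dict(table.center_shifts)
    for col in columns:
        mean = float(frame[col].mean())
        frame[col] = frame[col] - mean
        shifts[col] = shifts.get(col, 0.0) + mean
    return TimeSeriesTable(frame, shifts)
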