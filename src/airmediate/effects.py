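"""Direct, indirect, conditional and total effect assembly.

Under every structure the direct effect of X on Y and the indirect
effect through M are linear functions of the moderators:

* direct effect     c_x + c_xw·W + c_xz·Z
* indirect effect   (a_x + a_xw·W + a_xz·Z)·b  =  a_x·b + a_xw·b·W + a_xz·b·Z

with slopes of zero wherever the structure has no such product term.
The slope of the indirect effect in a moderator (a_xw·b or a_xz·b) is
the index of moderated mediation: a single number that tells whether
the mediation channel itself depends on that moderator.

In simple mediation (structure 1) the OLS total effect — the slope of Y
on X alone — decomposes exactly as total = direct + indirect on the
same sample, which this module exposes both as an estimator and as the
package's strongest internal consistency check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import TimeSeriesTable, center as center_table
from .errors import SpecificationError
from .mediation import FitResult

__all__ = [
    "EffectFunction",
    "ProbeGrid",
    "direct_effect_function",
    "indirect_effect_function",
    "index_of_moderated_mediation",
    "total_effect",
    "probe",
]

#: Default probe percentiles for moderator values (low / typical / high).
DEFAULT_PROBE_PERCENTILES = (16.0, 50.0, 84.0)


@dataclass(frozen=True)
class EffectFunction:
    """A conditional effect that is linear in the moderators.

    ``intercept`` is the effect at W = Z = 0 (i.e. at average moderator
    values when the analysis variables were centered); ``w_slope`` and
    ``z_slope`` are the per-unit changes with each moderator, zero for
    structures without the corresponding moderation.
    """

    kind: str  # "direct" or "indirect"
    intercept: float
    w_slope: float = 0.0
    z_slope: float = 0.0

    def __call__(self, w: float = 0.0, z: float = 0.0) -> float:
        return self.intercept + self.w_slope * w + self.z_slope * z


@dataclass(frozen=True)
class ProbeGrid:
    """Moderator values at which conditional effects are evaluated."""

    w_values: tuple[float, ...] = (0.0,)
    z_values: tuple[float, ...] = (0.0,)

    def __post_init__(self) -> None:
        vals = np.asarray(self.w_values + self.z_values, dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("probe values must be finite")

    @classmethod
    def from_table(
        cls,
        table: TimeSeriesTable,
        w: str | None,
        z: str | None,
        percentiles: Sequence[float] = DEFAULT_PROBE_PERCENTILES,
    ) -> "ProbeGrid":
        """Probe points at percentiles of each moderator's centered sample."""

        def pts(name: str | None) -> tuple[float, ...]:
            if name is None:
                return (0.0,)
            col = table.column(name)
            return tuple(np.percentile(col - col.mean(), percentiles))

        return cls(w_values=pts(w), z_values=pts(z))


def direct_effect_function(fit: FitResult) -> EffectFunction:
    """Conditional direct effect of X on Y as a function of (W, Z).

    Structures with an unmoderated direct path (1, 3, 5) yield a
    constant function.
    """
    c = fit.y_coefficients
    return EffectFunction(
        kind="direct",
        intercept=float(c["x"]),
        w_slope=float(c.get("x:w", 0.0)),
        z_slope=float(c.get("x:z", 0.0)),
    )


def indirect_effect_function(fit: FitResult) -> EffectFunction:
    """Conditional indirect effect of X on Y through M.

    The product-of-coefficients form (a_x + a_xw·W + a_xz·Z)·b expanded
    into intercept and moderator slopes.
    """
    a = fit.m_coefficients
    b = float(fit.y_coefficients["m"])
    return EffectFunction(
        kind="indirect",
        intercept=float(a["x"]) * b,
        w_slope=float(a.get("x:w", 0.0)) * b,
        z_slope=float(a.get("x:z", 0.0)) * b,
    )


def index_of_moderated_mediation(fit: FitResult, moderator: str) -> float:
    """Slope of the indirect effect in the named moderator ('w' or 'z').

    Defined only when the structure moderates the X→M path by that
    moderator (structures 3–4 for w; 5–6 for w or z).
    """
    if moderator not in ("w", "z"):
        raise SpecificationError(f"moderator must be 'w' or 'z', got {moderator!r}")
    term = f"x:{moderator}"
    if term not in fit.spec.m_terms:
        raise SpecificationError(
            f"structure {fit.spec.structure} does not moderate the mediator path by {moderator!r}"
        )
    return float(fit.m_coefficients[term]) * float(fit.y_coefficients["m"])


def total_effect(fit: FitResult, table: TimeSeriesTable) -> float:
    """OLS total effect of X on Y (structure 1 only): slope of Y on X.

    Computed on the same centering the fit used, so that the same-sample
    identity total = direct + indirect holds exactly.
    """
    if fit.spec.structure != 1:
        raise SpecificationError("total effect decomposition is defined for structure 1")
    roles = fit.spec.roles
    work = center_table(table, [roles.x, roles.y]) if fit.center_shifts else table
    x = work.column(roles.x)
    y = work.column(roles.y)
    xc = x - x.mean()
    return float(np.dot(xc, y) / np.dot(xc, xc))


def probe(effect: EffectFunction, grid: ProbeGrid, decimals: int | None = None) -> pd.DataFrame:
    """Evaluate an effect function over the Cartesian probe grid.

    Returns a DataFrame with columns ``w``, ``z``, ``effect``.  Internal
    values are full precision; pass ``decimals`` to round the reported
    effect column (conventionally 4) for display.
    """
    rows = [
        {"w": w, "z": z, "effect": effect(w, z)}
        for w in grid.w_values
        for z in grid.z_values
    ]
    out = pd.DataFrame(rows, columns=["w", "z", "effect"])
    if decimals is not None:
        out["effect"] = out["effect"].round(decimals)
    return out
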