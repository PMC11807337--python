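"""Six (moderated) mediation model structures and their OLS fits.

Each structure is a pair of linear equations estimated independently by
ordinary least squares on the same sample:

* the mediator equation  M = i_M + a_x·X [+ a_w·W + a_z·Z + a_xw·X·W + a_xz·X·Z] + ε_M
* the outcome equation   Y = i_Y + c_x·X [+ c_w·W + c_z·Z + c_xw·X·W + c_xz·X·Z] + b·M + ε_Y

The six structures differ only in which moderation (product) terms are
present:

=========  ==========================  ===========================
structure  X→M path                    X→Y (direct) path
=========  ==========================  ===========================
1          unmoderated                 unmoderated
2          unmoderated                 moderated by W
3          moderated by W              unmoderated
4          moderated by W              moderated by W
5          moderated by W and Z        unmoderated
6          moderated by W and Z        moderated by W and Z
=========  ==========================  ===========================

Coefficients are keyed by design term — ``const``, ``x``, ``w``, ``z``,
``x:w``, ``x:z`` and (outcome equation only) ``m`` — so the same key
always names the same role in every structure.

Analysis variables are mean-centered before product terms are formed
(products themselves are not re-centered), the standard conditional
process convention: it makes ``x`` directly interpretable as the effect
at average moderator values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datamodel import TimeSeriesTable, VariableRoles, center as center_table
from .errors import CollinearityError, DegenerateColumnError, SpecificationError

__all__ = ["ModelSpec", "FitResult", "build_designs", "fit", "r_squared", "M_TERMS", "Y_TERMS"]

# Design terms per structure (order = design-matrix column order).
M_TERMS: dict[int, tuple[str, ...]] = {
    1: ("const", "x"),
    2: ("const", "x"),
    3: ("const", "x", "w", "x:w"),
    4: ("const", "x", "w", "x:w"),
    5: ("const", "x", "w", "z", "x:w", "x:z"),
    6: ("const", "x", "w", "z", "x:w", "x:z"),
}
Y_TERMS: dict[int, tuple[str, ...]] = {
    1: ("const", "x", "m"),
    2: ("const", "x", "w", "x:w", "m"),
    3: ("const", "x", "m"),
    4: ("const", "x", "w", "x:w", "m"),
    5: ("const", "x", "m"),
    6: ("const", "x", "w", "z", "x:w", "x:z", "m"),
}

_COND_LIMIT = 1e10

CenterMode = Literal["all", "predictors", "none"]


@dataclass(frozen=True)
class ModelSpec:
    """A structure number (1–6) plus the variable-role assignment."""

    structure: int
    roles: VariableRoles

    def __post_init__(self) -> None:
        if self.structure not in M_TERMS:
            raise SpecificationError(f"structure must be 1..6, got {self.structure}")
        needs_w = self.structure >= 2
        needs_z = self.structure >= 5
        if needs_w and self.roles.w is None:
            raise SpecificationError(f"structure {self.structure} requires moderator w")
        if needs_z and self.roles.z is None:
            raise SpecificationError(f"structure {self.structure} requires moderator z")

    @property
    def m_terms(self) -> tuple[str, ...]:
        return M_TERMS[self.structure]

    @property
    def y_terms(self) -> tuple[str, ...]:
        return Y_TERMS[self.structure]

    @property
    def moderates_m_path(self) -> tuple[str, ...]:
        """Which moderators ('w', 'z') enter the X→M path."""
        return tuple(t.split(":")[1] for t in self.m_terms if ":" in t)

    @property
    def moderates_direct_path(self) -> tuple[str, ...]:
        return tuple(t.split(":")[1] for t in self.y_terms if ":" in t)


@dataclass(frozen=True)
class FitResult:
    """OLS estimates for one model structure on one table.

    ``m_*`` fields describe the mediator equation, ``y_*`` the outcome
    equation.  Coefficients and covariances are keyed/labelled by design
    term.  ``center_shifts`` records the means subtracted from each
    analysis variable before fitting.
    """

    spec: ModelSpec
    m_coefficients: Mapping[str, float]
    y_coefficients: Mapping[str, float]
    m_cov: pd.DataFrame | None = None
    y_cov: pd.DataFrame | None = None
    m_residuals: np.ndarray | None = None
    y_residuals: np.ndarray | None = None
    r2_m: float | None = None
    r2_y: float | None = None
    m_pvalue: float | None = None
    y_pvalue: float | None = None
    n: int | None = None
    center_shifts: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.m_coefficients) != set(self.spec.m_terms):
            raise SpecificationError(
                f"m_coefficients keys {sorted(self.m_coefficients)} do not match "
                f"structure-{self.spec.structure} terms {sorted(self.spec.m_terms)}"
            )
        if set(self.y_coefficients) != set(self.spec.y_terms):
            raise SpecificationError(
                f"y_coefficients keys {sorted(self.y_coefficients)} do not match "
                f"structure-{self.spec.structure} terms {sorted(self.spec.y_terms)}"
            )

    @classmethod
    def from_coefficients(
        cls,
        spec: ModelSpec,
        m_coefficients: Mapping[str, float],
        y_coefficients: Mapping[str, float],
        n: int | None = None,
        **extra,
    ) -> "FitResult":
        """Build a coefficients-only result, e.g. from a published table.

        Such a result supports effect assembly and probing but not
        interval estimation (no covariance or residuals).
        """
        return cls(
            spec=spec,
            m_coefficients=dict(m_coefficients),
            y_coefficients=dict(y_coefficients),
            n=n,
            **extra,
        )

    def se(self, equation: Literal["m", "y"], term: str) -> float:
        cov = self.m_cov if equation == "m" else self.y_cov
        if cov is None:
            raise ValueError("fit has no covariance information")
        return float(np.sqrt(cov.loc[term, term]))

    def coefficient_table(self, equation: Literal["m", "y"], level: float = 0.95) -> pd.DataFrame:
        """Per-term summary: estimate, se, t, p, and a t-based interval."""
        from scipy import stats as _stats  # local: avoid import cost at module load

        coefs = self.m_coefficients if equation == "m" else self.y_coefficients
        terms = self.spec.m_terms if equation == "m" else self.spec.y_terms
        dof = self.n - len(terms)
        tcrit = _stats.t.ppf(0.5 + level / 2.0, dof)
        rows = []
        for term in terms:
            est = float(coefs[term])
            se = self.se(equation, term)
            tval = est / se if se > 0 else np.inf * np.sign(est) if est else 0.0
            pval = 2.0 * _stats.t.sf(abs(tval), dof) if np.isfinite(tval) else 0.0
            rows.append(
                {
                    "term": term,
                    "estimate": est,
                    "se": se,
                    "t": tval,
                    "p": pval,
                    "ll": est - tcrit * se,
                    "ul": est + tcrit * se,
                }
            )
        return pd.DataFrame(rows)


def _product_name(a: str, b: str) -> str:
    return f"{a}:{b}"


def build_designs(spec: ModelSpec, table: TimeSeriesTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the mediator- and outcome-equation design matrices.

    The table is used as given (centering, if wanted, must already have
    been applied — :func:`fit` does this).  Product columns are computed
    from the table's columns as stored and are not re-centered.
    """
    roles = spec.roles
    table.require_columns([c for c in roles.assigned])
    cols: dict[str, np.ndarray] = {
        "const": np.ones(table.n),
        "x": table.column(roles.x),
        "m": table.column(roles.m),
    }
    if roles.w is not None:
        cols["w"] = table.column(roles.w)
        cols["x:w"] = cols["x"] * cols["w"]
    if roles.z is not None:
        cols["z"] = table.column(roles.z)
        cols["x:z"] = cols["x"] * cols["z"]
    try:
        m_design = pd.DataFrame({t: cols[t] for t in spec.m_terms}, index=table.frame.index)
        y_design = pd.DataFrame({t: cols[t] for t in spec.y_terms}, index=table.frame.index)
    except KeyError as exc:
        raise SpecificationError(f"structure {spec.structure} needs moderator {exc}") from exc
    return m_design, y_design


def _check_conditioning(design: pd.DataFrame, equation: str) -> None:
    cond = np.linalg.cond(design.to_numpy())
    if cond > _COND_LIMIT:
        # try to name the culprits: near-perfectly correlated column pairs
        data = design.to_numpy()
        names = list(design.columns)
        culprits = []
        sd = data.std(axis=0)
        varying = [i for i, s in enumerate(sd) if s > 0]
        if len(varying) >= 2:
            sub = np.corrcoef(data[:, varying], rowvar=False)
            for ii, i in enumerate(varying):
                for jj in range(ii):
                    if abs(sub[ii, jj]) > 1 - 1e-10:
                        culprits.append((names[varying[jj]], names[i]))
        detail = f"; aliased columns: {culprits}" if culprits else ""
        raise CollinearityError(
            f"{equation}-equation design is ill-conditioned (cond={cond:.3g}){detail}"
        )


def fit(
    spec: ModelSpec,
    table: TimeSeriesTable,
    center: CenterMode = "all",
) -> FitResult:
    """Estimate both equations of a model structure by OLS.

    Parameters
    ----------
    spec, table
        Model structure/roles and the (raw) analysis table.
    center
        ``"all"`` (default): mean-center every analysis variable,
        including the outcome, before building designs.
        ``"predictors"``: center x, m, w, z but not y.
        ``"none"``: fit on the table as given.

    Returns a :class:`FitResult` with coefficient maps, coefficient
    covariances (σ̂²(XᵀX)⁻¹ with the unbiased σ̂², n−p degrees of
    freedom per equation), residual series, R² per equation, and the
    overall F-test p-values.
    """
    roles = spec.roles
    if center == "all":
        to_center = roles.assigned
    elif center == "predictors":
        to_center = [c for c in roles.assigned if c != roles.y]
    elif center == "none":
        to_center = []
    else:
        raise ValueError(f"unknown centering mode {center!r}")
    work = center_table(table, to_center) if to_center else table

    m_design, y_design = build_designs(spec, work)
    if work.n <= max(len(spec.m_terms), len(spec.y_terms)):
        raise SpecificationError(
            f"n={work.n} does not exceed the number of design columns"
        )
    _check_conditioning(m_design, "M")
    _check_conditioning(y_design, "Y")

    m_obs = work.column(roles.m)
    y_obs = work.column(roles.y)
    m_res = sm.OLS(m_obs, m_design).fit()
    y_res = sm.OLS(y_obs, y_design).fit()

    return FitResult(
        spec=spec,
        m_coefficients={t: float(v) for t, v in m_res.params.items()},
        y_coefficients={t: float(v) for t, v in y_res.params.items()},
        m_cov=m_res.cov_params(),
        y_cov=y_res.cov_params(),
        m_residuals=np.asarray(m_res.resid),
        y_residuals=np.asarray(y_res.resid),
        r2_m=r_squared(m_obs, np.asarray(m_res.fittedvalues)),
        r2_y=r_squared(y_obs, np.asarray(y_res.fittedvalues)),
        m_pvalue=float(m_res.f_pvalue),
        y_pvalue=float(y_res.f_pvalue),
        n=work.n,
        center_shifts=work.center_shifts,
    )


def r_squared(observed: np.ndarray, fitted: np.ndarray) -> float:
    """Coefficient of determination, 1 − Σ(y−ŷ)² / Σ(y−ȳ)².

    Raises
    ------
    DegenerateColumnError
        If the observed series has zero variance (R² undefined).
    """
    observed = np.asarray(observed, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    if observed.shape != fitted.shape:
        raise ValueError("observed and fitted must have equal length")
    sst = float(np.sum((observed - observed.mean()) ** 2))
    if sst == 0.0:
        raise DegenerateColumnError("observed series has zero variance; R² undefined")
    sse = float(np.sum((observed - fitted) ** 2))
    return 1.0 - sse / sst
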