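"""Interval estimation and model selection.

Direct effects (single OLS coefficients, or sums of them) admit the
usual analytic t intervals.  Indirect effects are products of
coefficients from two equations, whose sampling distribution is skewed
in finite samples, so inference uses the percentile bootstrap: rows are
resampled with replacement, both equations are re-estimated on each
replicate (including the mean-centering step), and the interval is read
off the empirical α/2 and 1−α/2 quantiles of the replicated effect.

Model selection fits every candidate (structure, roles) combination and
ranks the ones with significant overall F-tests by the outcome-equation
R² (ties: mediator-equation R², then lower structure number) — the
higher the variance explained, the better the structure captures how
the meteorological driver, pollutant mediator and outcome hang
together.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import TimeSeriesTable, VariableRoles
from .effects import (
    EffectFunction,
    ProbeGrid,
    direct_effect_function,
    indirect_effect_function,
    index_of_moderated_mediation,
)
from .errors import SpecificationError
from .mediation import CenterMode, FitResult, ModelSpec, fit as fit_model

__all__ = [
    "EffectEstimate",
    "BootstrapResult",
    "InferenceConfig",
    "SelectionReport",
    "analytic_ci",
    "bootstrap_indirect",
    "select_models",
]

# replicates whose resampled design is numerically singular are dropped
_BOOT_COND_LIMIT = 1e12
_CHUNK = 256  # bootstrap replicates solved per batch (memory/speed balance)


@dataclass(frozen=True)
class EffectEstimate:
    """A point estimate with a confidence interval.

    ``significant`` is True exactly when the interval excludes zero.
    """

    estimate: float
    ll: float
    ul: float
    method: Literal["analytic_t", "percentile_bootstrap"]
    level: float
    n_boot: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.ll > self.ul + 1e-12:
            raise ValueError(f"interval bounds out of order: [{self.ll}, {self.ul}]")

    @property
    def significant(self) -> bool:
        return self.ll > 0.0 or self.ul < 0.0


@dataclass(frozen=True)
class InferenceConfig:
    """Settings shared by bootstrap inference and the selection sweep."""

    n_boot: int = 5000
    seed: int = 0
    level: float = 0.95
    center: CenterMode = "all"


@dataclass(frozen=True)
class BootstrapResult:
    """Percentile-bootstrap inference for one fitted model.

    ``conditional`` has one row per probe point (w, z, estimate, ll, ul,
    significant); ``indices`` maps moderator name → EffectEstimate for
    the index of moderated mediation, for each moderator of the X→M
    path.
    """

    conditional: pd.DataFrame
    indices: dict[str, EffectEstimate]
    n_boot: int
    n_dropped: int
    seed: int
    level: float
    estimates: tuple[EffectEstimate, ...] = field(default=())

    @property
    def drop_fraction(self) -> float:
        return self.n_dropped / self.n_boot


def analytic_ci(
    fit: FitResult,
    term: str,
    level: float = 0.95,
    equation: Literal["m", "y"] = "y",
) -> EffectEstimate:
    """Two-sided t interval for one coefficient: est ± t_{n−p} · se."""
    coefs = fit.y_coefficients if equation == "y" else fit.m_coefficients
    if term not in coefs:
        raise KeyError(f"term {term!r} not in {equation}-equation coefficients")
    terms = fit.spec.y_terms if equation == "y" else fit.spec.m_terms
    est = float(coefs[term])
    se = fit.se(equation, term)
    dof = fit.n - len(terms)
    tcrit = float(stats.t.ppf(0.5 + level / 2.0, dof))
    return EffectEstimate(
        estimate=est,
        ll=est - tcrit * se,
        ul=est + tcrit * se,
        method="analytic_t",
        level=level,
    )


def _gather_centered_designs(
    spec: ModelSpec,
    raw: dict[str, np.ndarray],
    idx: np.ndarray,
    center: CenterMode,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Resampled, re-centered design stacks and outcomes for one chunk.

    Returns (m_design, y_design, m_outcome, y_outcome) with designs of
    shape (B, n, p) — the same construction `mediation.fit` applies to
    the full sample, vectorised over replicates.
    """
    B, n = idx.shape
    cols: dict[str, np.ndarray] = {}
    for name, series in raw.items():
        v = series[idx]
        if center == "all" or (center == "predictors" and name != "y"):
            v = v - v.mean(axis=1, keepdims=True)
        cols[name] = v
    ones = np.ones((B, n))
    cols["const"] = ones
    if "w" in cols:
        cols["x:w"] = cols["x"] * cols["w"]
    if "z" in cols:
        cols["x:z"] = cols["x"] * cols["z"]
    m_design = np.stack([cols[t] for t in spec.m_terms], axis=2)
    y_design = np.stack([cols[t] for t in spec.y_terms], axis=2)
    return m_design, y_design, cols["m"], cols["y"]


def _batched_ols(design: np.ndarray, outcome: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Solve OLS for a (B, n, p) design stack.

    Returns (coefficients (B, p), ok-mask (B,)); ill-conditioned
    replicates get NaN coefficients and ok=False.
    """
    xtx = np.einsum("bnp,bnq->bpq", design, design)
    xty = np.einsum("bnp,bn->bp", design, outcome)
    ok = np.linalg.cond(xtx) <= _BOOT_COND_LIMIT
    coefs = np.full(xty.shape, np.nan)
    if ok.any():
        coefs[ok] = np.linalg.solve(xtx[ok], xty[ok, :, None])[:, :, 0]
    return coefs, ok


def bootstrap_indirect(
    table: TimeSeriesTable,
    spec: ModelSpec,
    grid: ProbeGrid | None = None,
    n_boot: int = 5000,
    seed: int = 0,
    level: float = 0.95,
    center: CenterMode = "all",
) -> BootstrapResult:
    """Percentile-bootstrap intervals for the conditional indirect effect.

    Rows are resampled with replacement ``n_boot`` times; both equations
    are re-estimated on every replicate (re-centering within the
    replicate); the conditional indirect effect is recomputed at every
    probe point, as is the index of moderated mediation for every
    moderator of the X→M path.  Results are deterministic given
    ``seed``.  Replicates with a numerically singular design are
    dropped and counted; a warning is emitted if more than 5% drop.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be ≥ 1")
    point_fit = fit_model(spec, table, center=center)
    if grid is None:
        grid = ProbeGrid.from_table(table, spec.roles.w, spec.roles.z)
    point_fn = indirect_effect_function(point_fit)

    roles = spec.roles
    raw = {"x": table.column(roles.x), "m": table.column(roles.m), "y": table.column(roles.y)}
    if roles.w is not None:
        raw["w"] = table.column(roles.w)
    if roles.z is not None:
        raw["z"] = table.column(roles.z)
    n = table.n
    rng = np.random.default_rng(seed)

    m_terms = list(spec.m_terms)
    y_terms = list(spec.y_terms)
    i_ax = m_terms.index("x")
    i_axw = m_terms.index("x:w") if "x:w" in m_terms else None
    i_axz = m_terms.index("x:z") if "x:z" in m_terms else None
    i_b = y_terms.index("m")

    points = [(w, z) for w in grid.w_values for z in grid.z_values]
    reps = np.empty((n_boot, len(points)))
    mods = spec.moderates_m_path
    index_reps = {mod: np.empty(n_boot) for mod in mods}
    ok_all = np.empty(n_boot, dtype=bool)

    done = 0
    while done < n_boot:
        b = min(_CHUNK, n_boot - done)
        idx = rng.integers(0, n, size=(b, n))
        m_design, y_design, m_out, y_out = _gather_centered_designs(spec, raw, idx, center)
        a_coefs, ok_m = _batched_ols(m_design, m_out)
        c_coefs, ok_y = _batched_ols(y_design, y_out)
        ok = ok_m & ok_y
        a_x = a_coefs[:, i_ax]
        a_xw = a_coefs[:, i_axw] if i_axw is not None else np.zeros(b)
        a_xz = a_coefs[:, i_axz] if i_axz is not None else np.zeros(b)
        bb = c_coefs[:, i_b]
        for j, (w, z) in enumerate(points):
            reps[done : done + b, j] = (a_x + a_xw * w + a_xz * z) * bb
        if "w" in mods:
            index_reps["w"][done : done + b] = a_xw * bb
        if "z" in mods:
            index_reps["z"][done : done + b] = a_xz * bb
        ok_all[done : done + b] = ok
        done += b

    n_dropped = int((~ok_all).sum())
    if n_dropped > 0.05 * n_boot:
        warnings.warn(
            f"{n_dropped}/{n_boot} bootstrap replicates dropped (singular resampled design)",
            RuntimeWarning,
        )
    keep = ok_all
    alpha = 1.0 - level
    qs = (100 * alpha / 2.0, 100 * (1.0 - alpha / 2.0))

    est_list = []
    rows = []
    for j, (w, z) in enumerate(points):
        ll, ul = np.percentile(reps[keep, j], qs)
        est = EffectEstimate(
            estimate=point_fn(w, z),
            ll=float(ll),
            ul=float(ul),
            method="percentile_bootstrap",
            level=level,
            n_boot=n_boot,
            seed=seed,
        )
        est_list.append(est)
        rows.append(
            {"w": w, "z": z, "estimate": est.estimate, "ll": est.ll, "ul": est.ul,
             "significant": est.significant}
        )
    indices = {}
    for mod in mods:
        ll, ul = np.percentile(index_reps[mod][keep], qs)
        indices[mod] = EffectEstimate(
            estimate=index_of_moderated_mediation(point_fit, mod),
            ll=float(ll),
            ul=float(ul),
            method="percentile_bootstrap",
            level=level,
            n_boot=n_boot,
            seed=seed,
        )
    return BootstrapResult(
        conditional=pd.DataFrame(rows),
        indices=indices,
        n_boot=n_boot,
        n_dropped=n_dropped,
        seed=seed,
        level=level,
        estimates=tuple(est_list),
    )


@dataclass(frozen=True)
class SelectionReport:
    """Outcome of the model-selection sweep.

    ``table`` holds one row per attempted (structure, roles)
    combination; rows whose two F-tests are both significant are ranked
    by r2_y (desc), then r2_m (desc), then structure number (asc);
    rows that fail the F-tests get no rank and sort last.
    """

    table: pd.DataFrame

    @property
    def best(self) -> pd.Series:
        ranked = self.table[self.table["rank"].notna()]
        if ranked.empty:
            raise SpecificationError("no candidate model passed the overall F-tests")
        return ranked.iloc[0]


def select_models(
    table: TimeSeriesTable,
    candidate_roles: Sequence[VariableRoles],
    structures: Sequence[int] = (1, 2, 3, 4, 5, 6),
    config: InferenceConfig | None = None,
    grid: ProbeGrid | None = None,
) -> SelectionReport:
    """Fit every compatible (structure, roles) combination and rank.

    For each combination the report records both R² values, overall
    F-test significance, and Yes/No flags for the direct effect
    (analytic t interval for the X coefficient), the indirect effect at
    centered moderator values of zero (percentile bootstrap), and the
    index of moderated mediation per moderated mediator path
    (percentile bootstrap).
    """
    if not candidate_roles:
        raise SpecificationError("candidate role set is empty")
    config = config or InferenceConfig()
    # independent, reproducible bootstrap seed per combination
    child_seeds = iter(
        int(s) % (2**31)
        for s in np.random.SeedSequence(config.seed).generate_state(
            len(candidate_roles) * len(structures)
        )
    )
    zero_grid = ProbeGrid()  # probe at centered moderator values of zero
    rows = []
    for roles in candidate_roles:
        for structure in structures:
            sub_seed = next(child_seeds)
            compatible = not (
                (structure >= 2 and roles.w is None) or (structure >= 5 and roles.z is None)
            )
            if not compatible:
                continue
            spec = ModelSpec(structure, roles)
            res = fit_model(spec, table, center=config.center)
            direct = analytic_ci(res, "x", level=config.level, equation="y")
            boot = bootstrap_indirect(
                table,
                spec,
                grid=grid or zero_grid,
                n_boot=config.n_boot,
                seed=sub_seed,
                level=config.level,
                center=config.center,
            )
            at_zero = boot.estimates[_nearest_zero_point(boot)]
            row = {
                "structure": structure,
                "x": roles.x,
                "m": roles.m,
                "y": roles.y,
                "w": roles.w,
                "z": roles.z,
                "r2_m": res.r2_m,
                "r2_y": res.r2_y,
                "m_significant": res.m_pvalue < 0.05,
                "y_significant": res.y_pvalue < 0.05,
                "direct_significant": direct.significant,
                "indirect_significant": at_zero.significant,
                "index_w_significant": boot.indices["w"].significant if "w" in boot.indices else None,
                "index_z_significant": boot.indices["z"].significant if "z" in boot.indices else None,
            }
            rows.append(row)
    report = pd.DataFrame(rows)
    eligible = report["m_significant"] & report["y_significant"]
    order = report.loc[eligible].sort_values(
        by=["r2_y", "r2_m", "structure"], ascending=[False, False, True], kind="mergesort"
    )
    report["rank"] = np.nan
    report.loc[order.index, "rank"] = np.arange(1, len(order) + 1, dtype=float)
    report = pd.concat(
        [report.loc[order.index], report.loc[~eligible]], axis=0
    ).reset_index(drop=True)
    return SelectionReport(report)


def _nearest_zero_point(boot: BootstrapResult) -> int:
    """Index of the probe point closest to (w, z) = (0, 0)."""
    pts = boot.conditional[["w", "z"]].to_numpy()
    return int(np.argmin((pts**2).sum(axis=1)))
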