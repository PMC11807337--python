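"""End-to-end orchestration: descriptives → screening → selection → effects.

:func:`run_pipeline` reproduces the standard analysis order on one input
table (or a freshly simulated one) and writes plain CSV/JSON artifacts:

* ``descriptives.csv``  — min, Q1, median, Q3, max, mean, sd per column
* ``correlations.csv``  — long-format Pearson matrix with stars/strength
* ``selection.csv``     — the ranked model-selection report
* ``coefficients_m.csv`` / ``coefficients_y.csv`` — per-term estimate,
  se, t, p and 95% bounds for the best model
* ``probes.csv``        — conditional direct/indirect effects with
  bootstrap intervals over the probe grid
* ``manifest.json``     — seed, config hash and library versions, enough
  to reproduce every number

All randomness flows from the single configured seed, so two runs with
the same config produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datamodel import TimeSeriesTable, VariableRoles, read_table
from .effects import (
    DEFAULT_PROBE_PERCENTILES,
    ProbeGrid,
    direct_effect_function,
    probe,
)
from .errors import AirmediateError
from .inference import InferenceConfig, analytic_ci, bootstrap_indirect, select_models
from .mediation import ModelSpec, fit as fit_model
from .screening import pearson_matrix
from .simulate import GeneratorConfig, generate

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "descriptive_statistics", "aqi_level"]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.12g"

#: upper cut points of the six air-quality alert levels
_AQI_LEVELS = (
    (50.0, "excellent"),
    (100.0, "good"),
    (150.0, "lightly polluted"),
    (200.0, "moderately polluted"),
    (300.0, "heavily polluted"),
)


class PipelineError(AirmediateError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs.

    Leave ``input`` as None to analyse a freshly simulated dataset
    (``generator`` settings, default study conditions).
    """

    roles: VariableRoles
    input: str | None = None
    date_column: str = "date"
    structures: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    n_boot: int = 5000
    seed: int = 0
    level: float = 0.95
    probe_percentiles: tuple[float, ...] = DEFAULT_PROBE_PERCENTILES
    outdir: str = "airmediate_run"
    aqi_column: str | None = None
    generator: GeneratorConfig | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["roles"] = VariableRoles(**data["roles"])
        for key in ("structures", "probe_percentiles"):
            if key in data:
                data[key] = tuple(data[key])
        if "generator" in data and data["generator"] is not None:
            data["generator"] = GeneratorConfig(**data["generator"])
        return cls(**data)

    def digest(self) -> str:
        """Stable hash of the configuration (for the manifest)."""

        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [enc(v) for v in obj]
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            return obj

        blob = json.dumps(enc(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def aqi_level(value: float) -> str:
    """Air-quality alert level for one index value.

    Cut points 50/100/150/200/300 separate excellent, good, lightly /
    moderately / heavily polluted, and severely polluted above 300.
    """
    if not np.isfinite(value) or value < 0:
        raise ValueError(f"AQI value must be finite and ≥ 0, got {value}")
    for cut, label in _AQI_LEVELS:
        if value <= cut:
            return label
    return "severely polluted"


def descriptive_statistics(table: TimeSeriesTable) -> pd.DataFrame:
    """Min, quartiles, max and mean ± SD per column."""
    frame = table.frame
    out = pd.DataFrame(
        {
            "min": frame.min(),
            "q1": frame.quantile(0.25),
            "median": frame.median(),
            "q3": frame.quantile(0.75),
            "max": frame.max(),
            "mean": frame.mean(),
            "sd": frame.std(ddof=1),
        }
    )
    out.index.name = "variable"
    return out


def _write_csv(frame: pd.DataFrame, path: Path, **kw) -> None:
    frame.to_csv(path, float_format=_FLOAT_FMT, **kw)


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and write the artifact directory.

    Any stage failure aborts with a stage-tagged :class:`PipelineError`;
    artifacts written before the failure are retained.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    roles = config.roles

    stage = "load"
    try:
        if config.input is not None:
            table = read_table(config.input, date_column=config.date_column)
        else:
            gen = config.generator or GeneratorConfig(roles=roles, seed=config.seed)
            table, _ = generate(gen)
            table.to_csv(outdir / "simulated_input.csv", date_column=config.date_column)
        table.require_columns(roles.assigned)

        stage = "descriptives"
        desc = descriptive_statistics(table)
        _write_csv(desc, outdir / "descriptives.csv")
        if config.aqi_column is not None:
            levels = (
                table.frame[config.aqi_column]
                .clip(lower=0.0)  # Gaussian synthetic index can dip below zero
                .map(aqi_level)
                .value_counts()
                .rename_axis("level")
                .to_frame("days")
            )
            _write_csv(levels, outdir / "aqi_levels.csv")

        stage = "screening"
        corr = pearson_matrix(table, roles.assigned)
        _write_csv(corr.to_long(), outdir / "correlations.csv", index=False)

        stage = "selection"
        inf = InferenceConfig(n_boot=config.n_boot, seed=config.seed, level=config.level)
        report = select_models(table, [roles], structures=config.structures, config=inf)
        _write_csv(report.table, outdir / "selection.csv", index=False)
        best = report.best
        best_spec = ModelSpec(int(best["structure"]), roles)

        stage = "effects"
        best_fit = fit_model(best_spec, table)
        for eq in ("m", "y"):
            _write_csv(
                best_fit.coefficient_table(eq, level=config.level),
                outdir / f"coefficients_{eq}.csv",
                index=False,
            )
        grid = ProbeGrid.from_table(
            table, roles.w, roles.z, percentiles=config.probe_percentiles
        )
        boot = bootstrap_indirect(
            table, best_spec, grid=grid, n_boot=config.n_boot,
            seed=config.seed, level=config.level,
        )
        direct_fn = direct_effect_function(best_fit)
        probes = probe(direct_fn, grid).rename(columns={"effect": "direct"})
        direct_ci = analytic_ci(best_fit, "x", level=config.level, equation="y")
        probes["direct_significant"] = direct_ci.significant
        probes = probes.merge(
            boot.conditional.rename(
                columns={
                    "estimate": "indirect", "ll": "indirect_ll", "ul": "indirect_ul",
                    "significant": "indirect_significant",
                }
            ),
            on=["w", "z"],
        )
        _write_csv(probes, outdir / "probes.csv", index=False)

        stage = "manifest"
        manifest = {
            "seed": config.seed,
            "config_hash": config.digest(),
            "n_rows": table.n,
            "best_structure": int(best["structure"]),
            "versions": {
                "airmediate": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "artifacts": sorted(p.name for p in outdir.iterdir() if p.is_file()),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    logger.info("pipeline complete: %s", outdir)
    return outdir
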