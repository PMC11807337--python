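import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from scipy import stats

from airmediate import (
    GeneratorConfig,
    InferenceConfig,
    ModelSpec,
    ProbeGrid,
    TimeSeriesTable,
    VariableRoles,
    analytic_ci,
    bootstrap_indirect,
    center,
    fit,
    generate,
    select_models,
)
from airmediate.errors import SpecificationError
from airmediate.inference import _batched_ols, _gather_centered_designs
from airmediate.mediation import build_designs
from conftest import random_table

ROLES = VariableRoles(x="x", m="m", y="y", w="w", z="z")


class TestAnalyticCI:
    def test_matches_hand_computed_t_interval(self):
        # 5-row regression of y on [1, x]; textbook formulas throughout
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.1, 3.9, 6.2, 7.8, 10.1])
        m = np.array([0.5, 0.4, 0.6, 0.5, 0.4])  # mediator, needed for the fit
        frame = pd.DataFrame(
            {"x": x, "m": m, "y": y}, index=pd.date_range("2020-01-01", periods=5)
        )
        table = TimeSeriesTable(frame)
        res = fit(ModelSpec(1, VariableRoles(x="x", m="m", y="y")), table, center="none")
        ci = analytic_ci(res, "x", level=0.95, equation="y")
        # independent hand computation on the same design
        X = np.column_stack([np.ones(5), x, m])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        sigma2 = resid @ resid / (5 - 3)
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        tcrit = stats.t.ppf(0.975, 2)
        assert ci.estimate == pytest.approx(beta[1], abs=1e-10)
        assert ci.ll == pytest.approx(beta[1] - tcrit * se, abs=1e-10)
        assert ci.ul == pytest.approx(beta[1] + tcrit * se, abs=1e-10)

    def test_noiseless_outcome_equation_gives_zero_width_interval(self):
        # ε_Y ≡ 0 makes the outcome an exact interpolation of its design
        # (ordinary mediator noise keeps that design well-conditioned)
        cfg = GeneratorConfig(n_days=100, seed=9, y_noise_sd=0.0)
        table, _ = generate(cfg)
        res = fit(cfg.spec, table)
        ci = analytic_ci(res, "x", equation="y")
        assert ci.ul - ci.ll == pytest.approx(0.0, abs=1e-8)
        assert ci.ll <= ci.estimate <= ci.ul + 1e-12

    def test_wider_level_strictly_contains_narrower(self, small_table):
        res = fit(ModelSpec(6, ROLES), small_table)
        ci95 = analytic_ci(res, "x", level=0.95)
        ci99 = analytic_ci(res, "x", level=0.99)
        assert ci99.ll < ci95.ll and ci95.ul < ci99.ul

    def test_unknown_term(self, small_table):
        res = fit(ModelSpec(1, VariableRoles(x="x", m="m", y="y")), small_table)
        with pytest.raises(KeyError):
            analytic_ci(res, "x:w")

    def test_significance_flag_matches_interval(self, small_table):
        res = fit(ModelSpec(6, ROLES), small_table)
        for term in res.spec.y_terms:
            ci = analytic_ci(res, term)
            assert ci.significant == (ci.ll > 0 or ci.ul < 0)


class TestBootstrap:
    def test_identical_seed_gives_identical_intervals(self, small_table):
        spec = ModelSpec(6, ROLES)
        a = bootstrap_indirect(small_table, spec, n_boot=200, seed=42)
        b = bootstrap_indirect(small_table, spec, n_boot=200, seed=42)
        pd.testing.assert_frame_equal(a.conditional, b.conditional)
        assert a.indices["w"] == b.indices["w"]

    def test_constant_statistic_gives_degenerate_interval(self):
        # with b ≡ 0 and ε_Y ≡ 0 the outcome equation is exact in every
        # resample, so the replicated indirect effect is constant at zero
        # and the percentile interval must collapse onto it
        base = GeneratorConfig(n_days=120, seed=3, y_noise_sd=0.0)
        cfg = replace(base, y_coefficients={**base.y_coefficients, "m": 0.0})
        table, _ = generate(cfg)
        res = bootstrap_indirect(table, cfg.spec, grid=ProbeGrid(), n_boot=100, seed=0)
        est = res.estimates[0]
        assert est.ul - est.ll == pytest.approx(0.0, abs=1e-9)
        assert est.estimate == pytest.approx(0.0, abs=1e-9)
        assert est.ll == pytest.approx(est.estimate, abs=1e-9)

    def test_fast_resampling_path_matches_full_fit_on_identity_sample(self, small_table):
        """The batched bootstrap solver, fed the identity resample, must
        reproduce the reference OLS fit exactly."""
        spec = ModelSpec(6, ROLES)
        raw = {k: small_table.column(k) for k in ("x", "m", "y", "w", "z")}
        idx = np.arange(small_table.n)[None, :]
        md, yd, m_out, y_out = _gather_centered_designs(spec, raw, idx, "all")
        a, ok_m = _batched_ols(md, m_out)
        c, ok_y = _batched_ols(yd, y_out)
        assert ok_m[0] and ok_y[0]
        res = fit(spec, small_table, center="all")
        np.testing.assert_allclose(a[0], list(res.m_coefficients.values()), atol=1e-8)
        np.testing.assert_allclose(c[0], list(res.y_coefficients.values()), atol=1e-8)

    def test_interval_brackets_point_estimate_in_typical_data(self, default_dataset):
        cfg, table, _ = default_dataset
        res = bootstrap_indirect(table, cfg.spec, grid=ProbeGrid(), n_boot=400, seed=5)
        est = res.estimates[0]
        assert est.ll < est.estimate < est.ul
        assert res.n_dropped == 0

    def test_invalid_n_boot(self, small_table):
        with pytest.raises(ValueError):
            bootstrap_indirect(small_table, ModelSpec(6, ROLES), n_boot=0)


class TestSelectModels:
    def test_single_candidate_single_structure(self, small_table):
        report = select_models(
            small_table, [ROLES], structures=(6,), config=InferenceConfig(n_boot=50, seed=0)
        )
        assert len(report.table) == 1
        assert report.table.loc[0, "structure"] == 6

    def test_row_count_is_structures_times_candidates(self, small_table):
        candidates = [ROLES, VariableRoles(x="w", m="m", y="y", w="x", z="z")]
        report = select_models(
            small_table,
            candidates,
            structures=(1, 3, 6),
            config=InferenceConfig(n_boot=50, seed=1),
        )
        assert len(report.table) == 3 * 2

    def test_ranking_is_deterministic_and_r2_sorted(self, default_dataset):
        cfg, table, _ = default_dataset
        conf = InferenceConfig(n_boot=50, seed=2)
        r1 = select_models(table, [cfg.roles], config=conf)
        r2 = select_models(table, [cfg.roles], config=conf)
        pd.testing.assert_frame_equal(r1.table, r2.table)
        ranked = r1.table[r1.table["rank"].notna()]
        assert (ranked["r2_y"].diff().dropna() <= 1e-12).all()

    def test_empty_candidates_rejected(self, small_table):
        with pytest.raises(SpecificationError):
            select_models(small_table, [])
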