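import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from airmediate import (
    EffectFunction,
    FitResult,
    ModelSpec,
    ProbeGrid,
    TimeSeriesTable,
    VariableRoles,
    direct_effect_function,
    fit,
    indirect_effect_function,
    index_of_moderated_mediation,
    probe,
    total_effect,
    xian_ili_fit,
)
from airmediate.errors import SpecificationError
from conftest import random_table

ROLES = VariableRoles(x="x", m="m", y="y", w="w", z="z")


class TestPublishedWorkedExamples:
    """The published Xi'an conditional-effect formulas, reassembled from
    the printed per-equation coefficients."""

    def test_conditional_direct_effect_of_minimum_temperature(self):
        f = direct_effect_function(xian_ili_fit("temp_min"))
        assert round(f(0, 0), 4) == -1.5822
        assert round(f.w_slope, 4) == 0.0029
        assert round(f.z_slope, 4) == -0.0550
        # hand sum at one humidity/pressure unit each
        assert round(f(1, 1), 4) == round(-1.5822 + 0.0029 - 0.0550, 4)

    def test_conditional_indirect_effect_of_minimum_temperature(self):
        f = indirect_effect_function(xian_ili_fit("temp_min"))
        assert round(f.intercept, 4) == -0.0195
        assert round(f.w_slope, 4) == -0.0005
        assert round(f.z_slope, 4) == 0.0004

    def test_conditional_direct_effect_of_maximum_humidity(self):
        f = direct_effect_function(xian_ili_fit("humidity_max"))
        assert round(f(0, 0), 4) == -0.3267
        assert round(f.w_slope, 4) == -0.0087
        assert round(f.z_slope, 4) == -0.0116

    def test_conditional_indirect_effect_of_maximum_humidity(self):
        f = indirect_effect_function(xian_ili_fit("humidity_max"))
        assert round(f.intercept, 4) == 0.0008
        assert round(f.w_slope, 4) == 0.0009
        assert round(f.z_slope, 4) == 0.0001

    def test_moderated_mediation_index_is_interaction_times_b(self):
        res = xian_ili_fit("temp_min")
        assert index_of_moderated_mediation(res, "w") == pytest.approx(
            -0.0970 * 0.0049, abs=1e-12
        )


def _fit_with(m_coefs, y_coefs, structure=6):
    return FitResult.from_coefficients(
        ModelSpec(structure, ROLES), m_coefs, y_coefs, n=100
    )


class TestEffectAssembly:
    def test_zero_direct_coefficients_give_zero_function(self):
        res = _fit_with(
            {"const": 1, "x": 2, "w": 3, "z": 4, "x:w": 5, "x:z": 6},
            {t: 0.0 for t in ("const", "x", "w", "z", "x:w", "x:z", "m")},
        )
        f = direct_effect_function(res)
        assert f(0, 0) == f(3, -7) == 0.0

    def test_broken_second_path_kills_indirect_effect(self):
        res = _fit_with(
            {"const": 1, "x": 2, "w": 3, "z": 4, "x:w": 5, "x:z": 6},
            {"const": 0, "x": 1, "w": 1, "z": 1, "x:w": 1, "x:z": 1, "m": 0.0},
        )
        f = indirect_effect_function(res)
        assert f.intercept == f.w_slope == f.z_slope == 0.0
        assert index_of_moderated_mediation(res, "w") == 0.0
        assert index_of_moderated_mediation(res, "z") == 0.0

    def test_indirect_intercept_equals_product_of_raw_coefficients(self, small_table):
        res = fit(ModelSpec(6, ROLES), small_table)
        f = indirect_effect_function(res)
        assert f.intercept == pytest.approx(
            res.m_coefficients["x"] * res.y_coefficients["m"], abs=1e-12
        )

    def test_index_requires_a_moderated_mediator_path(self, small_table):
        res = fit(ModelSpec(2, ROLES), small_table)
        with pytest.raises(SpecificationError):
            index_of_moderated_mediation(res, "w")
        res3 = fit(ModelSpec(3, ROLES), small_table)
        with pytest.raises(SpecificationError):
            index_of_moderated_mediation(res3, "z")

    def test_structure_reductions(self, small_table):
        # unmoderated direct path -> constant direct effect
        res5 = fit(ModelSpec(5, ROLES), small_table)
        d5 = direct_effect_function(res5)
        assert d5.w_slope == d5.z_slope == 0.0
        # unmoderated mediator path -> constant indirect effect
        res2 = fit(ModelSpec(2, ROLES), small_table)
        i2 = indirect_effect_function(res2)
        assert i2.w_slope == i2.z_slope == 0.0


class TestTotalEffect:
    def test_noiseless_decomposition(self):
        # a = 2, b = 3, c' = 1 exactly: total must be c' + a·b = 7
        rng = np.random.default_rng(0)
        x = rng.normal(size=60)
        m = 2.0 * x
        y = 1.0 * x + 3.0 * m
        frame = pd.DataFrame(
            {"x": x, "m": m, "y": y}, index=pd.date_range("2020-01-01", periods=60)
        )
        table = TimeSeriesTable(frame)
        res = FitResult.from_coefficients(
            ModelSpec(1, VariableRoles(x="x", m="m", y="y")),
            {"const": 0.0, "x": 2.0},
            {"const": 0.0, "x": 1.0, "m": 3.0},
            n=60,
        )
        assert total_effect(res, table) == pytest.approx(7.0, abs=1e-10)
        assert direct_effect_function(res)(0, 0) + indirect_effect_function(
            res
        ).intercept == pytest.approx(7.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_total_equals_direct_plus_indirect_exactly(self, seed):
        table = random_table(n=40, seed=seed, moderated=False)
        res = fit(ModelSpec(1, VariableRoles(x="x", m="m", y="y")), table)
        total = total_effect(res, table)
        direct = direct_effect_function(res)(0, 0)
        indirect = indirect_effect_function(res).intercept
        assert total - (direct + indirect) == pytest.approx(0.0, abs=1e-10)

    def test_mediator_unrelated_to_x_gives_total_equal_direct(self):
        rng = np.random.default_rng(4)
        n = 2000
        x = rng.normal(size=n)
        m = rng.normal(size=n)  # a ≈ 0 by construction
        y = 1.3 * x + 0.8 * m + rng.normal(0, 0.1, n)
        frame = pd.DataFrame(
            {"x": x, "m": m, "y": y}, index=pd.date_range("2015-01-01", periods=n)
        )
        table = TimeSeriesTable(frame)
        res = fit(ModelSpec(1, VariableRoles(x="x", m="m", y="y")), table)
        total = total_effect(res, table)
        # identity still exact; and the indirect part is tiny
        direct = res.y_coefficients["x"]
        indirect = indirect_effect_function(res).intercept
        assert total == pytest.approx(direct + indirect, abs=1e-10)
        # â is pure sampling noise of order 1/sqrt(n); 0.06 ≈ 3 SD of â·b
        assert abs(indirect) < 0.06

    def test_wrong_structure_rejected(self, small_table):
        res = fit(ModelSpec(6, ROLES), small_table)
        with pytest.raises(SpecificationError):
            total_effect(res, small_table)


class TestRescalingEquivariance:
    def test_effects_scale_with_per_unit_reparametrisation(self, small_table):
        """Dividing X by k makes every per-unit-X effect k times larger."""
        k = 4.0
        spec = ModelSpec(6, ROLES)
        base_d = direct_effect_function(fit(spec, small_table))
        base_i = indirect_effect_function(fit(spec, small_table))
        frame = small_table.frame.copy()
        frame["x"] = frame["x"] / k
        scaled = fit(spec, TimeSeriesTable(frame))
        d = direct_effect_function(scaled)
        i = indirect_effect_function(scaled)
        for w, z in [(0, 0), (1.5, -2.0)]:
            assert d(w, z) == pytest.approx(k * base_d(w, z), rel=1e-8)
            assert i(w, z) == pytest.approx(k * base_i(w, z), rel=1e-8)


class TestProbe:
    def test_constant_function_probes_constant(self):
        f = EffectFunction(kind="direct", intercept=2.5)
        grid = ProbeGrid(w_values=(-1.0, 0.0, 1.0), z_values=(-2.0, 2.0))
        out = probe(f, grid)
        assert (out["effect"] == 2.5).all()

    def test_default_grid_is_cartesian_9_points(self, default_dataset):
        _, table, _ = default_dataset
        grid = ProbeGrid.from_table(table, "humidity_max", "pressure")
        f = EffectFunction(kind="indirect", intercept=1.0, w_slope=0.5, z_slope=-0.25)
        out = probe(f, grid)
        assert len(out) == 9
        for _, row in out.iterrows():
            assert row["effect"] == pytest.approx(
                1.0 + 0.5 * row["w"] - 0.25 * row["z"], abs=1e-12
            )

    def test_grid_percentiles_of_centered_moderator(self, default_dataset):
        _, table, _ = default_dataset
        grid = ProbeGrid.from_table(table, "humidity_max", None)
        col = table.column("humidity_max")
        expect = np.percentile(col - col.mean(), [16, 50, 84])
        np.testing.assert_allclose(grid.w_values, expect, atol=1e-12)
        assert grid.z_values == (0.0,)

    def test_nonfinite_probe_values_rejected(self):
        with pytest.raises(ValueError):
            ProbeGrid(w_values=(np.nan,))
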