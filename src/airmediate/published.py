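"""Published coefficient tables for the worked examples.

Point estimates from the two-moderator (structure 6) fits of a daily
Xi'an influenza-like-illness study (1 January 2014 – 15 November 2016,
n = 1050 days): the air-quality index as mediator between meteorology
and daily ILI case counts, all variables mean-centered.  Two role
assignments were reported:

* ``"temp_min"``      — X = minimum temperature (°C), W = maximum
  humidity (%), Z = pressure;
* ``"humidity_max"``  — X = maximum humidity, W = minimum temperature,
  Z = pressure.

These coefficient-only results let the effect-assembly machinery be
demonstrated (and checked) against the study's printed conditional
effect formulas without access to the restricted raw data.
"""

from __future__ import annotations

from .datamodel import VariableRoles
from .mediation import FitResult, ModelSpec

__all__ = ["xian_ili_fit", "XIAN_N_DAYS", "XIAN_MEAN_CASES_TOTAL", "XIAN_MEAN_CASES_UNDER5"]

#: days in the study window
XIAN_N_DAYS = 1050
#: printed mean daily ILI cases, all ages and ages 0–4
XIAN_MEAN_CASES_TOTAL = 73.93
XIAN_MEAN_CASES_UNDER5 = 40.53

_TABLES = {
    "temp_min": {
        "roles": VariableRoles(
            x="temp_min", m="aqi", y="ili_cases", w="humidity_max", z="pressure"
        ),
        "m": {
            "const": 7.8476, "x": -3.9840, "w": -0.2457, "z": -1.6632,
            "x:w": -0.0970, "x:z": 0.0808,
        },
        "y": {
            "const": -4.0010, "x": -1.5822, "w": -0.2347, "z": 0.1332,
            "x:w": 0.0029, "x:z": -0.0550, "m": 0.0049,
        },
        "r2_m": 0.2917,
        "r2_y": 0.3846,
    },
    "humidity_max": {
        "roles": VariableRoles(
            x="humidity_max", m="aqi", y="ili_cases", w="temp_min", z="pressure"
        ),
        "m": {
            "const": 2.1286, "x": -0.0925, "w": -4.0545, "z": -1.8915,
            "x:w": -0.1057, "x:z": -0.0124,
        },
        "y": {
            "const": 0.0813, "x": -0.3267, "w": -1.6121, "z": 0.2318,
            "x:w": -0.0087, "x:z": -0.0116, "m": -0.0087,
        },
        "r2_m": 0.2779,
        "r2_y": 0.3656,
    },
}


def xian_ili_fit(antecedent: str = "temp_min") -> FitResult:
    """Coefficients-only FitResult for one published role assignment.

    Parameters
    ----------
    antecedent
        ``"temp_min"`` or ``"humidity_max"`` — which meteorological
        driver plays the focal antecedent X.
    """
    try:
        entry = _TABLES[antecedent]
    except KeyError:
        raise KeyError(
            f"antecedent must be one of {sorted(_TABLES)}, got {antecedent!r}"
        ) from None
    spec = ModelSpec(structure=6, roles=entry["roles"])
    return FitResult.from_coefficients(
        spec,
        entry["m"],
        entry["y"],
        n=XIAN_N_DAYS,
        r2_m=entry["r2_m"],
        r2_y=entry["r2_y"],
    )
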