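# airmediate

Moderated mediation analysis for environmental-epidemiology time series.

## The problem

Does weather drive respiratory infections directly, or partly *through*
air pollution?  Daily counts of influenza-like illness (ILI) peak in
winter, exactly when temperature bottoms out and pollution indices such
as the AQI peak — so a meteorological driver X may push the daily case
count Y along two pathways: a direct one, and an indirect one through a
pollutant mediator M.  Either pathway may in turn be *moderated* by
other meteorological variables W and Z (humidity, pressure).

`airmediate` is a library for epidemiologists and biostatisticians who
want to fit, compare and probe these conditional-process models on daily
series — and to validate the whole machinery on synthetic data with
known ground truth, since surveillance counts of this kind are usually
restricted.

## The models

Six candidate structures, each a pair of OLS equations on mean-centered
variables (products formed after centering).  The fully moderated
structure (6) is

```
M = i_M + a1·X + a2·W + a3·Z + a4·XW + a5·XZ + ε_M
Y = i_Y + c1'·X + c2'·W + c3'·Z + c4'·XW + c5'·XZ + b·M + ε_Y
```

with structures 1–5 obtained by dropping moderation terms (1 is simple
mediation: `M = i_M + a·X + ε_M`, `Y = i_Y + c'·X + b·M + ε_Y`).  From a
fit the package assembles

- the **conditional direct effect** `c1' + c4'·W + c5'·Z`,
- the **conditional indirect effect** `(a1 + a4·W + a5·Z)·b`,
- the **index of moderated mediation** `a4·b` (or `a5·b`) — the slope of
  the indirect effect in a moderator,
- the **total effect** in simple mediation, with the exact same-sample
  identity `total = c' + a·b`.

Direct effects get analytic t intervals; indirect effects and the index
get percentile-bootstrap intervals (rows resampled with replacement,
both equations refit per replicate).  Structures are compared by R² of
each equation, ranked by the outcome equation among models with
significant F-tests.  Conditional effects are probed at the 16th, 50th
and 84th percentiles of each moderator.

## Worked example

A published two-moderator fit of daily Xi'an ILI counts (X = minimum
temperature, W = maximum humidity, Z = pressure, M = AQI; n = 1050
days) ships with the package as a coefficients-only `FitResult`:

```python
from airmediate import direct_effect_function, indirect_effect_function, xian_ili_fit

pub = xian_ili_fit("temp_min")
d = direct_effect_function(pub)
i = indirect_effect_function(pub)
print(f"direct:   {d.intercept:+.4f} {d.w_slope:+.4f}·W {d.z_slope:+.4f}·Z")
print(f"indirect: {i.intercept:+.4f} {i.w_slope:+.4f}·W {i.z_slope:+.4f}·Z")
```

prints

```
direct:   -1.5822 +0.0029·W -0.0550·Z
indirect: -0.0195 -0.0005·W +0.0004·Z
```

i.e. at average humidity and pressure, a 1 °C rise in minimum
temperature is associated with 1.5822 fewer daily ILI cases directly
and a further 0.0195 fewer through the air-quality channel.

On synthetic data the same machinery runs end to end with known truth
(`examples/bootstrap_inference.py`; true indirect effect −0.60):

```
      w       z  estimate      ll      ul  significant
-0.2334 -0.0240   -0.5864 -0.7403 -0.4489         True
...
Index of moderated mediation (slope of the indirect effect):
  w: -0.01630  [-0.02366, -0.01016]  significant=True
  z: +0.00926  [+0.00336, +0.01548]  significant=True
```

Each script in `examples/` demonstrates one capability: simulating a
dataset, correlation screening, fitting and effect assembly, bootstrap
inference, model selection, Monte-Carlo parameter recovery, and the
full pipeline (which writes CSV artifacts plus a reproducibility
manifest).

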