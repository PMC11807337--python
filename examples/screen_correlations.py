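"""Pearson screening: which variables move together, and how strongly.

Correlation magnitudes are labelled weak (<0.36), moderate or strong
(≥0.68); stars flag two-sided significance at 0.05 (*) and 0.01 (**).
"""

from airmediate import GeneratorConfig, generate, pearson_matrix

table, _ = generate(GeneratorConfig(seed=1))
matrix = pearson_matrix(table)

print(matrix.to_long().round(3).to_string(index=False))
# Expect: temp_min vs pressure strongly negative (seasonal antiphase),
# temp_min vs aqi negative (cold, stagnant winter air pollutes), and
# ili_cases negatively correlated with temperature.
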