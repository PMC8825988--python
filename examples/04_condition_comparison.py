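"""Mixed-model comparison of flight conditions on a feature table.

Simulates a balanced single1 / group / single2 design for nine bats with
a known +3 kHz group-flight increase in tFM bandwidth, fits the linear
mixed model (bat as random intercept) and reports Wald tests and
Tukey-Kramer-adjusted pairwise contrasts.
"""

import numpy as np

from sonarjam import simulate_feature_table, compare_conditions

rng = np.random.default_rng(42)
table = simulate_feature_table(rng, n_bats=9, group_effect=3.0,
                               sigma_bat=0.5, sigma_res=1.0)
print(table.groupby("condition")["tfm_bandwidth"].mean().round(2))

res = compare_conditions(table, "tfm_bandwidth", include_space=False)
print("\nWald chi-square tests:")
print(res.fixed_tests.to_string(index=False))
print("\nTukey-Kramer pairwise contrasts:")
print(res.contrasts[["pair", "estimate", "se", "t", "p_tukey"]]
      .to_string(index=False))
# Both group-vs-single contrasts recover the injected ~3 kHz shift and
# are significant after adjustment; single1 vs single2 is not.
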