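"""The headline demonstration: observation bias and the data-stream null.

Simulates a population in which females truly have stronger social bonds,
then deletes 20% of female observations (inconspicuous females are harder to
record).  The raw sex difference disappears from the observed network, so a
naive regression and a node-permutation test both miss it; the data-stream
(checkerboard) permutation — which preserves how often each individual was
observed — recovers it.
"""

import numpy as np

from socialnull import (
    GroupScenarioSpec,
    NullChainSpec,
    ols_fit,
    run_null_chain,
    simple_ratio_index,
    simulate_observed_group_data,
    weighted_degree,
)
from socialnull.inference import strength_slope_statistic

spec = GroupScenarioSpec(seed=1)
gbi_true, gbi_obs, nodes = simulate_observed_group_data(spec)
female = nodes.get("sex") == "F"

for label, gbi in (("true", gbi_true), ("observed (20% female loss)", gbi_obs)):
    s = weighted_degree(simple_ratio_index(gbi))
    print(
        f"{label:28s} mean strength  F={s[female].mean():.3f}  "
        f"M={s[~female].mean():.3f}"
    )

strengths = weighted_degree(simple_ratio_index(gbi_obs))
naive = ols_fit(strengths, nodes, "sex")
print(
    f"\nnaive OLS on observed data:  slope(sexM) = "
    f"{naive.coefficients['sex']:+.3f},  parametric P = {naive.p_values['sex']:.3f}"
)

statistic = strength_slope_statistic(attribute="sex")
node = run_null_chain(
    gbi_obs, "node", NullChainSpec(1000, seed=2), statistic, nodes=nodes
)
ds = run_null_chain(
    gbi_obs,
    "datastream",
    NullChainSpec(1000, swaps_per_step=10, burn_in=1000, seed=3),
    statistic,
    nodes=nodes,
)
print(f"node permutation:            P = {node.p_two_tailed:.3f}")
print(
    f"data-stream permutation:     P = {ds.p_two_tailed:.3f}  "
    f"(observed {ds.observed_statistic:+.3f} vs null "
    f"{np.mean(ds.null_statistics):+.3f} +/- {np.std(ds.null_statistics):.3f})"
)
print(
    "\nThe true data show females ~15% stronger; the bias hides this from the"
    "\nnaive and node tests (P >> 0.05), while the data-stream null - centred"
    "\nwell above the observed slope because it knows females were recorded"
    "\nless often - exposes it (P < 0.01)."
)
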