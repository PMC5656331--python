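"""Pre-network permutation of focal-follow data.

Focal samples (one focal individual plus its recorded associates) are recast
as groups, and the null model swaps single associates between samples with
different focals — preserving every individual's total number of appearances
and every sample's associate count.
"""

import numpy as np

from socialnull import (
    GroupScenarioSpec,
    NullChainSpec,
    focal_to_gbi,
    run_null_chain,
    simple_ratio_index,
    simulate_observed_focal_data,
    weighted_degree,
)
from socialnull.inference import strength_slope_statistic

spec = GroupScenarioSpec(seed=2)
focals_true, focals_obs, nodes = simulate_observed_focal_data(spec)
female = nodes.get("sex") == "F"

s = weighted_degree(simple_ratio_index(focal_to_gbi(focals_obs)))
print(
    f"observed focal data: {len(focals_obs)} samples, mean strength "
    f"F={s[female].mean():.3f} M={s[~female].mean():.3f}"
)

statistic = strength_slope_statistic(attribute="sex")
res = run_null_chain(
    focals_obs,
    "focal",
    NullChainSpec(1000, swaps_per_step=10, burn_in=1000, seed=5),
    statistic,
    nodes=nodes,
)
print(
    f"focal-swap null:  observed slope {res.observed_statistic:+.3f}, "
    f"null {np.mean(res.null_statistics):+.3f} +/- "
    f"{np.std(res.null_statistics):.3f},  P = {res.p_two_tailed:.3f}"
)
print(
    "\nAs in the group-data demo, the null (which conditions on observation"
    "\nfrequencies) sits above the observed slope: female bonds are stronger"
    "\nthan the biased sampling makes them look."
)
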