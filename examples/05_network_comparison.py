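"""Comparing two networks with simultaneous randomisation.

Is the difference in a network metric between two populations larger than
chance?  The observed statistic is metric(A) - metric(B); at each chain step
one checkerboard swap is applied within EACH population's raw data and the
difference recorded, so the null respects both datasets' sampling structure.
"""

import numpy as np

from socialnull import (
    GroupScenarioSpec,
    NullChainSpec,
    compare_networks,
    simulate_group_data,
)

# population A: females concentrate on social events; population B: no effect
gbi_a, _ = simulate_group_data(GroupScenarioSpec(seed=21))
gbi_b, _ = simulate_group_data(
    GroupScenarioSpec(seed=22, female_sociality_effect=0.0)
)

for metric in ("cv_edge_weights", "mean_strength"):
    res = compare_networks(
        gbi_a,
        gbi_b,
        metric,
        method="datastream",
        chain=NullChainSpec(500, swaps_per_step=10, burn_in=500, seed=23),
    )
    print(
        f"{metric:16s} A-B observed {res.observed_statistic:+.4f}, null "
        f"{np.mean(res.null_statistics):+.4f} +/- "
        f"{np.std(res.null_statistics):.4f},  P = {res.p_two_tailed:.3f}"
    )
print(
    "\nThe social-event structure in population A makes its edge weights more"
    "\nvariable than B's (positive CV difference); margin-preserving swaps"
    "\nerode that structure, so the null differences sit mostly below the"
    "\nobserved one (small-ish P).  Mean strength shows no difference beyond"
    "\nwhat the two sampling designs already imply."
)
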