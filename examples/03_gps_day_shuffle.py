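"""Nulls for autocorrelated movement data: day-shuffle vs identity swap.

Grid-world tracks: males move at random, females are 5x more likely to step
into a neighbouring cell that held another individual, and 20% of female
points go unrecorded.  The day-shuffle null permutes each individual's day
labels within that individual (space use and sampling kept, timing broken);
the track-identity swap reassigns whole daily tracks between individuals and
behaves like a node permutation — with the known consequences.
"""

import numpy as np

from socialnull import (
    GpsScenarioSpec,
    NullChainSpec,
    run_null_chain,
    simulate_gps_data,
)
from socialnull.inference import strength_slope_statistic

spec = GpsScenarioSpec(seed=6)
traj, nodes = simulate_gps_data(spec)
obs = traj.observed_mask()
female = nodes.get("sex") == "F"
print(
    f"{spec.n_individuals} individuals, {spec.n_days} days x "
    f"{spec.steps_per_day} steps on a {spec.grid_width}x{spec.grid_height} grid; "
    f"female points recorded: {obs[female].mean():.0%}"
)

statistic = strength_slope_statistic(attribute="sex")
day = run_null_chain(
    traj, "day-shuffle", NullChainSpec(1000, seed=7), statistic, nodes=nodes
)
ident = run_null_chain(
    traj, "identity-swap", NullChainSpec(1000, seed=8), statistic, nodes=nodes
)
print(
    f"day-shuffle:    observed {day.observed_statistic:+.4f} vs null "
    f"{np.mean(day.null_statistics):+.4f},  P = {day.p_two_tailed:.3f}"
)
print(
    f"identity-swap:  observed {ident.observed_statistic:+.4f} vs null "
    f"{np.mean(ident.null_statistics):+.4f},  P = {ident.p_two_tailed:.3f}"
)
print(
    "\nThe day-shuffle null detects the female social attraction (small P)"
    "\nbecause it conditions on each animal's space use and sampling; the"
    "\nidentity swap, blind to per-individual sampling, typically does not."
)
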