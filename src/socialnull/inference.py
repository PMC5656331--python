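"""Test statistics, permutation p-values and dyadic (QAP/MRQAP) regression.

The recommended node-level test statistic is the OLS slope of a node value
(e.g. weighted degree) on a node attribute (e.g. sex): the slope describes
the data, whereas t or Z statistics measure departure from the parametric
null and are poor permutation statistics.  Significance always comes from
comparing the observed slope with the slopes recomputed on permuted data.

Dyadic hypotheses (is the association network predicted by dyad-level
matrices such as sex similarity or relatedness?) use the quadratic
assignment procedure: OLS over unordered dyads, with the null slope
distribution generated by simultaneous row/column permutations of the
dependent matrix (QAP), by Dekker-style double-semi-partialing permutations
of each predictor's residual matrix (MRQAP-DSP), or by refitting the model
on null networks supplied by *any* permutation engine — which is how a
pre-network data-stream null plugs into dyadic regression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    FocalSampleSet,
    GroupByIndividualMatrix,
    NodeTable,
    PermutationResult,
    TrajectorySet,
    WeightedNetwork,
    _pvalue_triple,
)
from .network_core import (
    DyadCategoryMatrix,
    focal_to_gbi,
    network_metric,
    simple_ratio_index,
    trajectories_to_gbi,
    weighted_degree,
)
from .null_models import (
    NullChainSpec,
    SwapRestriction,
    _apply_checkerboard_swap,
    find_checkerboard,
)

__all__ = [
    "RegressionFit",
    "MrqapResult",
    "node_statistic_slope",
    "ols_fit",
    "permutation_pvalues",
    "stabilisation_series",
    "strength_slope_statistic",
    "network_metric_statistic",
    "qap_regression",
    "mrqap_dsp",
    "mrqap_custom_null",
    "datastream_null_networks",
    "compare_networks",
]


# ---------------------------------------------------------------------------
# node-level statistics


def _encode_predictor(values: np.ndarray) -> np.ndarray:
    """Numeric copy of a predictor; binary categories coded 0/1.

    The reference level (coded 0) is the alphabetically first, so for sexes
    M/F the slope is the effect of being male relative to female.
    """
    values = np.asarray(values)
    if values.dtype.kind in "ifu":
        return values.astype(float)
    levels = sorted(set(map(str, values.tolist())))
    if len(levels) != 2:
        raise ValueError(
            f"categorical predictor must be binary, got levels {levels}"
        )
    return np.asarray([1.0 if str(v) == levels[1] else 0.0 for v in values])


def node_statistic_slope(
    node_values: np.ndarray, nodes: NodeTable, predictor: str
) -> float:
    """OLS slope of per-individual values on a node attribute.

    Closed-form simple regression (with intercept); the slope equals the
    between-group mean difference for a binary predictor.
    """
    y = np.asarray(node_values, dtype=float)
    x = _encode_predictor(nodes.get(predictor))
    if y.shape != x.shape:
        raise ValueError("node_values and predictor must have equal length")
    if y.size < 3:
        raise ValueError("need at least 3 individuals")
    vx = x - x.mean()
    denom = vx @ vx
    if denom == 0:
        raise ValueError(f"predictor {predictor!r} is constant")
    return float(vx @ (y - y.mean()) / denom)


def ols_fit(node_values: np.ndarray, nodes: NodeTable, predictor: str) -> "RegressionFit":
    """Parametric OLS fit (statsmodels) of node values on one attribute.

    This is the "naive" analysis: its p-value assumes independent
    observations, which network data violate — use it for comparison with
    permutation p-values, not for inference.
    """
    import statsmodels.api as sm

    y = np.asarray(node_values, dtype=float)
    x = _encode_predictor(nodes.get(predictor))
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionFit(
        coefficients={"intercept": float(model.params[0]), predictor: float(model.params[1])},
        response_name="node_values",
        predictor_names=[predictor],
        std_errors={predictor: float(model.bse[1])},
        p_values={predictor: float(model.pvalues[1])},
    )


@dataclass
class RegressionFit:
    """An OLS fit: named coefficients plus (optional) parametric diagnostics."""

    coefficients: dict[str, float]
    response_name: str
    predictor_names: list[str]
    std_errors: dict[str, float] | None = None
    p_values: dict[str, float] | None = None


# ---------------------------------------------------------------------------
# permutation p-values and diagnostics


def permutation_pvalues(observed: float, null_statistics) -> tuple[float, float, float]:
    """(p_upper, p_lower, p_two_tailed) from an observed statistic and null series.

    p_upper counts null values >= observed, p_lower those <= observed (ties
    fall in both tails, which is conservative), and the two-tailed value is
    twice the smaller proportion, clamped at 1.
    """
    return _pvalue_triple(float(observed), np.asarray(null_statistics, dtype=float))


def stabilisation_series(result: PermutationResult) -> pd.DataFrame:
    """Running diagnostics of a null series against permutation number.

    Columns: ``permutation`` (1-based), ``null_statistic``, ``running_mean``
    of the null statistics so far, and ``running_p_two_tailed`` computed on
    the first k null values.  Plotting the statistic (or running p) against
    permutation number shows whether a serial chain has stabilised; the final
    row reproduces the full-series p-value.
    """
    nulls = np.asarray(result.null_statistics, dtype=float)
    n = nulls.size
    finite = np.isfinite(nulls)
    obs = result.observed_statistic
    cum_n = np.cumsum(finite)
    cum_sum = np.cumsum(np.where(finite, nulls, 0.0))
    upper = np.cumsum(np.where(finite & (nulls >= obs), 1, 0))
    lower = np.cumsum(np.where(finite & (nulls <= obs), 1, 0))
    with np.errstate(invalid="ignore", divide="ignore"):
        running_mean = np.where(cum_n > 0, cum_sum / np.maximum(cum_n, 1), np.nan)
        p_up = upper / np.maximum(cum_n, 1)
        p_lo = lower / np.maximum(cum_n, 1)
    running_p = np.minimum(1.0, 2.0 * np.minimum(p_up, p_lo))
    running_p[cum_n == 0] = np.nan
    return pd.DataFrame(
        {
            "permutation": np.arange(1, n + 1),
            "null_statistic": nulls,
            "running_mean": running_mean,
            "running_p_two_tailed": running_p,
        }
    )


# ---------------------------------------------------------------------------
# statistic factories for run_null_chain


def strength_slope_statistic(
    attribute: str = "sex",
    weight: str = "sri",
    cooccurrence_radius: int = 0,
) -> Callable:
    """Statistic: OLS slope of weighted degree (strength) on a node attribute.

    Accepts any observation container: a GBI is used directly, focal samples
    and trajectories are first reduced to a GBI, a WeightedNetwork is used
    as-is.  ``weight`` selects the edge weight ("sri" or raw "counts").
    """
    from .network_core import cooccurrence_counts

    build = simple_ratio_index if weight == "sri" else cooccurrence_counts

    def statistic(data, nodes: NodeTable) -> float:
        if nodes is None:
            raise ValueError("strength_slope_statistic requires a NodeTable")
        net = _as_network(data, build, cooccurrence_radius)
        strengths = _aligned_strengths(net, nodes)
        return node_statistic_slope(strengths, nodes, attribute)

    statistic.__name__ = f"strength_slope[{attribute}]"
    return statistic


def network_metric_statistic(metric: str, weight: str = "sri") -> Callable:
    """Statistic: a network-level scalar (mean degree, density, CV of edge weights...)."""
    from .network_core import cooccurrence_counts

    build = simple_ratio_index if weight == "sri" else cooccurrence_counts

    def statistic(data, nodes=None) -> float:
        return network_metric(_as_network(data, build, 0), metric)

    statistic.__name__ = f"network_metric[{metric}]"
    return statistic


def _as_network(data, build, cooccurrence_radius) -> WeightedNetwork:
    if isinstance(data, WeightedNetwork):
        return data
    if isinstance(data, GroupByIndividualMatrix):
        return build(data)
    if isinstance(data, FocalSampleSet):
        return build(focal_to_gbi(data))
    if isinstance(data, TrajectorySet):
        return build(trajectories_to_gbi(data, cooccurrence_radius))
    raise TypeError(f"cannot build a network from {type(data).__name__}")


def _aligned_strengths(net: WeightedNetwork, nodes: NodeTable) -> np.ndarray:
    """Strengths ordered to match the NodeTable; ids must correspond."""
    strengths = weighted_degree(net)
    if net.individual_ids == nodes.individual_ids:
        return strengths
    idx = {ind: k for k, ind in enumerate(net.individual_ids)}
    try:
        order = [idx[i] for i in nodes.individual_ids]
    except KeyError as e:
        raise ValueError(f"node table id {e} not present in the network") from None
    return strengths[order]


# ---------------------------------------------------------------------------
# QAP / MRQAP


@dataclass
class MrqapResult:
    """Dyadic-regression result: OLS coefficients with permutation p-values."""

    coefficients: dict[str, float]
    p_values: dict[str, float]
    n_permutations: int
    method: str
    null_coefficients: dict[str, np.ndarray] | None = None


def _dyad_vector(matrix, n: int) -> np.ndarray:
    if isinstance(matrix, WeightedNetwork):
        m = matrix.adjacency
    elif isinstance(matrix, DyadCategoryMatrix):
        m = matrix.values.astype(float)
    else:
        m = np.asarray(matrix, dtype=float)
    if m.shape != (n, n):
        raise ValueError("all matrices must share the same node set")
    iu = np.triu_indices(n, k=1)
    return m[iu].astype(float)


def _predictor_names(predictors) -> list[str]:
    names = []
    for k, p in enumerate(predictors):
        if isinstance(p, DyadCategoryMatrix):
            names.append("sex_category" if 1 in p.coding.values() else f"x{k + 1}")
        else:
            names.append(f"x{k + 1}")
    # de-duplicate
    seen: dict[str, int] = {}
    out = []
    for nm in names:
        if nm in seen:
            seen[nm] += 1
            out.append(f"{nm}_{seen[nm]}")
        else:
            seen[nm] = 0
            out.append(nm)
    return out


def _design(dep: WeightedNetwork, predictors) -> tuple[np.ndarray, np.ndarray, list[str]]:
    n = dep.n_nodes
    y = _dyad_vector(dep, n)
    cols = [np.ones_like(y)] + [_dyad_vector(p, n) for p in predictors]
    x = np.column_stack(cols)
    for k, c in enumerate(cols[1:], start=1):
        if np.ptp(c) == 0:
            raise ValueError(f"predictor {k} is constant across dyads (rank deficient)")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("rank-deficient dyadic design matrix")
    return y, x, _predictor_names(predictors)


def _ols(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return beta


def _permute_matrix(m: np.ndarray, perm: np.ndarray) -> np.ndarray:
    return m[np.ix_(perm, perm)]


def qap_regression(
    dep: WeightedNetwork,
    predictors: Sequence,
    n_perm: int = 1000,
    seed: int = 0,
) -> MrqapResult:
    """QAP dyadic regression: node permutations of the dependent network.

    OLS over each unordered dyad once (the networks are symmetric, so the
    upper triangle holds every observation).  The null distribution of each
    slope comes from simultaneous row/column permutations of the dependent
    matrix, which preserve its dyadic structure while breaking its alignment
    with the predictors.
    """
    rng = np.random.default_rng(seed)
    y, x, names = _design(dep, predictors)
    n = dep.n_nodes
    iu = np.triu_indices(n, k=1)
    pinv = np.linalg.pinv(x)
    beta_obs = pinv @ y  # same operator as the null fits, so ties are exact
    null_betas = np.empty((n_perm, x.shape[1]))
    adj = dep.adjacency
    for r in range(n_perm):
        perm = rng.permutation(n)
        yp = _permute_matrix(adj, perm)[iu]
        null_betas[r] = pinv @ yp
    return _mrqap_result(beta_obs, null_betas, names, n_perm, "qap-y")


def mrqap_dsp(
    dep: WeightedNetwork,
    predictors: Sequence,
    n_perm: int = 1000,
    seed: int = 0,
) -> MrqapResult:
    """MRQAP with double semi-partialing (Dekker-style) predictor permutations.

    For each predictor X_i: residualise X_i on the remaining predictors by
    dyadic OLS, node-permute the residual matrix, substitute it into the
    model and refit; the permuted-residual coefficients form the null for
    beta_i.  Estimation is unchanged (coefficients are the plain OLS
    coefficients); only the permutation scheme differs from QAP, giving
    better behaved tests when predictors are correlated.  With a single
    predictor it reduces statistically to QAP on the dependent network.
    """
    rng = np.random.default_rng(seed)
    y, x, names = _design(dep, predictors)
    beta_obs = _ols(x, y)
    n = dep.n_nodes
    iu = np.triu_indices(n, k=1)
    n_pred = len(predictors)
    null_betas = np.full((n_perm, x.shape[1]), np.nan)
    for i in range(n_pred):
        others = [c for c in range(1, n_pred + 1) if c != i + 1]
        x_others = x[:, [0] + others]
        xi = x[:, i + 1]
        gamma = _ols(x_others, xi)
        resid = xi - x_others @ gamma
        e_mat = np.zeros((n, n))
        e_mat[iu] = resid
        e_mat = e_mat + e_mat.T
        for r in range(n_perm):
            perm = rng.permutation(n)
            ep = _permute_matrix(e_mat, perm)[iu]
            design = np.column_stack([x_others, ep])
            b = _ols(design, y)
            null_betas[r, i + 1] = b[-1]
    return _mrqap_result(beta_obs, null_betas, names, n_perm, "dsp")


def mrqap_custom_null(
    dep_observed: WeightedNetwork,
    predictors: Sequence,
    null_dep_networks: Sequence[WeightedNetwork],
) -> MrqapResult:
    """Dyadic regression with a caller-supplied null-network ensemble.

    Observed coefficients come from OLS on the observed network; the null
    coefficient distribution from refitting the identical model on each
    supplied null network (e.g. networks recorded along a data-stream
    permutation chain).  This is how a pre-network null plugs into MRQAP.
    """
    y, x, names = _design(dep_observed, predictors)
    n = dep_observed.n_nodes
    pinv = np.linalg.pinv(x)
    beta_obs = pinv @ y  # same operator as the null fits, so ties are exact
    null_betas = np.empty((len(null_dep_networks), x.shape[1]))
    for r, net in enumerate(null_dep_networks):
        if net.n_nodes != n or net.individual_ids != dep_observed.individual_ids:
            raise ValueError("null networks must share the observed network's nodes")
        null_betas[r] = pinv @ _dyad_vector(net, n)
    return _mrqap_result(
        beta_obs, null_betas, names, len(null_dep_networks), "custom-null"
    )


def _mrqap_result(beta_obs, null_betas, names, n_perm, method) -> MrqapResult:
    coefficients = {"intercept": float(beta_obs[0])}
    p_values = {}
    null_store = {}
    for k, nm in enumerate(names, start=1):
        coefficients[nm] = float(beta_obs[k])
        _, _, p2 = _pvalue_triple(float(beta_obs[k]), null_betas[:, k])
        p_values[nm] = p2
        null_store[nm] = null_betas[:, k].copy()
    return MrqapResult(
        coefficients=coefficients,
        p_values=p_values,
        n_permutations=n_perm,
        method=method,
        null_coefficients=null_store,
    )


def datastream_null_networks(
    gbi: GroupByIndividualMatrix,
    n_networks: int,
    swaps_per_network: int = 10,
    burn_in: int = 0,
    seed: int = 0,
    restriction: SwapRestriction | None = None,
    nodes: NodeTable | None = None,
    weight: str = "sri",
) -> list[WeightedNetwork]:
    """Record association networks along a data-stream permutation chain.

    Useful as the null ensemble for `mrqap_custom_null` or for network-level
    comparisons.  The chain applies checkerboard swaps cumulatively,
    recording one network every ``swaps_per_network`` swaps after
    ``burn_in``.
    """
    from .network_core import cooccurrence_counts

    build = simple_ratio_index if weight == "sri" else cooccurrence_counts
    rng = np.random.default_rng(seed)
    restriction = restriction or SwapRestriction()
    restriction.validate_for_gbi(gbi, nodes)
    working = gbi.copy()

    def step():
        found = find_checkerboard(working, restriction, rng, nodes)
        if found is not None:
            _apply_checkerboard_swap(working.membership, *found)

    for _ in range(burn_in):
        step()
    out = []
    for _ in range(n_networks):
        for _ in range(swaps_per_network):
            step()
        out.append(build(working))
    return out


# ---------------------------------------------------------------------------
# two-network comparison


def compare_networks(
    data_a,
    data_b,
    metric,
    method: str = "datastream",
    chain: NullChainSpec | None = None,
    restriction: SwapRestriction | None = None,
    nodes_a: NodeTable | None = None,
    nodes_b: NodeTable | None = None,
    weight: str = "sri",
) -> PermutationResult:
    """Permutation test of a metric difference between two networks.

    The observed statistic is metric(A) - metric(B).  Under the
    ``datastream`` (or ``focal``) method both datasets are randomised
    *simultaneously* — one swap applied within each at every chain step —
    and the difference recorded, so the null captures differences that could
    arise from each dataset's own sampling structure.  ``metric`` is a
    network-metric name or a callable on WeightedNetwork.
    """
    from .network_core import cooccurrence_counts

    chain = chain or NullChainSpec()
    restriction = restriction or SwapRestriction()
    build = simple_ratio_index if weight == "sri" else cooccurrence_counts
    if callable(metric):
        mfun = metric
        mname = getattr(metric, "__name__", "metric")
    else:
        mfun = lambda net: network_metric(net, metric)  # noqa: E731
        mname = metric

    def net_of(data):
        return _as_network(data, build, 0)

    observed = mfun(net_of(data_a)) - mfun(net_of(data_b))
    rng = np.random.default_rng(chain.seed)
    nulls = np.empty(chain.n_permutations)
    n_failed = 0

    if method == "datastream":
        for d, nm in ((data_a, "A"), (data_b, "B")):
            if not isinstance(d, GroupByIndividualMatrix):
                raise TypeError(
                    f"datastream comparison requires GBI data for network {nm}"
                )
        wa, wb = data_a.copy(), data_b.copy()

        def step() -> int:
            failed = 0
            for w, nd in ((wa, nodes_a), (wb, nodes_b)):
                found = find_checkerboard(w, restriction, rng, nd)
                if found is None:
                    failed += 1
                else:
                    _apply_checkerboard_swap(w.membership, *found)
            return failed

        for _ in range(chain.burn_in):
            n_failed += step()
        for r in range(chain.n_permutations):
            for _ in range(chain.swaps_per_step):
                n_failed += step()
            nulls[r] = mfun(build(wa)) - mfun(build(wb))
    elif method == "focal":
        from .null_models import _FocalWorkspace

        for d, nm in ((data_a, "A"), (data_b, "B")):
            if not isinstance(d, FocalSampleSet):
                raise TypeError(
                    f"focal comparison requires FocalSampleSet data for network {nm}"
                )
        wsa, wsb = _FocalWorkspace(data_a), _FocalWorkspace(data_b)

        def step() -> int:
            failed = 0
            for ws, nd in ((wsa, nodes_a), (wsb, nodes_b)):
                if not ws.try_swap(restriction, rng, nd, 10_000):
                    failed += 1
            return failed

        for _ in range(chain.burn_in):
            n_failed += step()
        for r in range(chain.n_permutations):
            for _ in range(chain.swaps_per_step):
                n_failed += step()
            nulls[r] = mfun(build(focal_to_gbi(wsa.to_focal_set()))) - mfun(
                build(focal_to_gbi(wsb.to_focal_set()))
            )
    elif method == "edge":
        from .null_models import edge_permutation

        na, nb = net_of(data_a), net_of(data_b)
        for r in range(chain.n_permutations):
            nulls[r] = mfun(edge_permutation(na, rng)) - mfun(edge_permutation(nb, rng))
    else:
        raise ValueError(
            "compare_networks supports methods 'datastream', 'focal' and 'edge'"
        )

    return PermutationResult.from_series(
        observed,
        nulls,
        seed=chain.seed,
        method=f"compare-{method}",
        statistic_name=f"difference[{mname}]",
        n_failed_swaps=n_failed,
    )
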