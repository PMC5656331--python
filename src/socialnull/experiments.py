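"""End-to-end experiment runner: scenario -> null model(s) -> report bundle.

A single YAML/dict config describes a simulated scenario (or input files),
one or more null models and a chain specification; `run_experiment` writes a
deterministic report bundle — observed statistic, per-method null series
CSV, p-values, stabilisation table, and the full config with its seed for
provenance.  CSV/JSON are the canonical outputs; plots are optional
artifacts so downstream checks never parse images.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .inference import (
    ols_fit,
    stabilisation_series,
    strength_slope_statistic,
    network_metric_statistic,
)
from .network_core import simple_ratio_index, weighted_degree, focal_to_gbi, trajectories_to_gbi
from .null_models import (
    INDEPENDENT_METHODS,
    SERIAL_METHODS,
    NullChainSpec,
    SwapRestriction,
    run_null_chain,
)
from .synthetic_data import (
    GpsScenarioSpec,
    GroupScenarioSpec,
    simulate_gps_data,
    simulate_observed_focal_data,
    simulate_observed_group_data,
)

__all__ = ["run_experiment", "ConfigurationError", "load_config"]

_FLOAT_FMT = "%.12g"


class ConfigurationError(ValueError):
    """Raised for invalid or internally inconsistent experiment configs."""


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _build_scenario(cfg: dict, seed: int):
    kind = cfg.get("type")
    params = {k: v for k, v in cfg.items() if k != "type"}
    params.setdefault("seed", seed)
    if kind == "group":
        spec = GroupScenarioSpec(**params)
        _, gbi_obs, nodes = simulate_observed_group_data(spec)
        return gbi_obs, nodes, spec.as_dict()
    if kind == "focal":
        spec = GroupScenarioSpec(**params)
        _, focals_obs, nodes = simulate_observed_focal_data(spec)
        return focals_obs, nodes, spec.as_dict()
    if kind == "gps":
        spec = GpsScenarioSpec(**params)
        traj, nodes = simulate_gps_data(spec)
        return traj, nodes, spec.as_dict()
    raise ConfigurationError(f"unknown scenario type {cfg.get('type')!r}")


_METHOD_DATA = {
    "datastream": "gbi",
    "focal": "focal",
    "day-shuffle": "trajectories",
    "identity-swap": "trajectories",
}


def _check_compatibility(method: str, data) -> None:
    from .data_model import FocalSampleSet, GroupByIndividualMatrix, TrajectorySet

    wanted = _METHOD_DATA.get(method)
    kind = {
        GroupByIndividualMatrix: "gbi",
        FocalSampleSet: "focal",
        TrajectorySet: "trajectories",
    }.get(type(data))
    if wanted is not None and wanted != kind:
        raise ConfigurationError(
            f"null method {method!r} is incompatible with {kind!r} data "
            f"(requires {wanted!r}); convert the data explicitly first"
        )


def _make_statistic(cfg: dict):
    kind = cfg.get("type", "strength_slope")
    if kind == "strength_slope":
        return (
            strength_slope_statistic(attribute=cfg.get("attribute", "sex")),
            f"strength_slope[{cfg.get('attribute', 'sex')}]",
        )
    if kind == "network_metric":
        return (
            network_metric_statistic(cfg["metric"]),
            f"network_metric[{cfg['metric']}]",
        )
    raise ConfigurationError(f"unknown statistic type {kind!r}")


def run_experiment(config: dict | str | Path, out_dir) -> dict:
    """Run one experiment config and write its report bundle to ``out_dir``.

    Returns the summary dict (also written as ``summary.json``).  Re-running
    the same config yields byte-identical outputs: all randomness flows from
    the config seed and no timestamps are recorded.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    seed = int(config.get("seed", 0))
    chain_cfg = dict(config.get("chain", {}))
    chain_cfg.setdefault("seed", seed)
    try:
        chain = NullChainSpec(**chain_cfg)
    except (TypeError, ValueError) as e:
        raise ConfigurationError(f"invalid chain spec: {e}") from e

    data, nodes, scenario_params = _build_scenario(dict(config["scenario"]), seed)
    statistic, stat_name = _make_statistic(dict(config.get("statistic", {})))
    restriction = SwapRestriction(**config.get("restriction", {}))

    methods = config.get("nulls", ["datastream"])
    if isinstance(methods, str):
        methods = [methods]
    if not methods:
        raise ConfigurationError("config requests no null methods")

    summary: dict = {
        "config": {**config, "scenario": scenario_params, "seed": seed},
        "statistic": stat_name,
        "methods": {},
    }
    observed = None
    for method in methods:
        if method not in SERIAL_METHODS | INDEPENDENT_METHODS:
            raise ConfigurationError(f"unknown null method {method!r}")
        _check_compatibility(method, data)
        result = run_null_chain(
            data,
            method,
            chain,
            statistic,
            restriction=restriction,
            nodes=nodes,
            statistic_name=stat_name,
        )
        observed = result.observed_statistic
        pd.DataFrame(
            {
                "permutation": np.arange(1, result.n_permutations + 1),
                "null_statistic": result.null_statistics,
            }
        ).to_csv(out_dir / f"null_series_{method}.csv", index=False, float_format=_FLOAT_FMT)
        stabilisation_series(result).to_csv(
            out_dir / f"stabilisation_{method}.csv", index=False, float_format=_FLOAT_FMT
        )
        summary["methods"][method] = result.summary()

    # the parametric comparison the permutation tests are contrasted against
    stat_cfg = dict(config.get("statistic", {}))
    if stat_cfg.get("type", "strength_slope") == "strength_slope":
        from .data_model import FocalSampleSet, GroupByIndividualMatrix, TrajectorySet

        if isinstance(data, GroupByIndividualMatrix):
            gbi = data
        elif isinstance(data, FocalSampleSet):
            gbi = focal_to_gbi(data)
        else:
            gbi = trajectories_to_gbi(data)
        strengths = weighted_degree(simple_ratio_index(gbi))
        fit = ols_fit(strengths, nodes, stat_cfg.get("attribute", "sex"))
        summary["naive_ols"] = {
            "coefficients": fit.coefficients,
            "p_values": fit.p_values,
        }

    summary["observed_statistic"] = observed
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    with open(out_dir / "config.json", "w") as fh:
        json.dump(summary["config"], fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return summary


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
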