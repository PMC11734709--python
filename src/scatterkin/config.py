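"""Structured (YAML) run configuration.

One YAML document drives the whole pipeline: a ``scenario`` block for the
synthetic generator, a ``network`` block for the kinetic scheme, and a
``fit`` block for the global analysis.  All blocks are optional; omitted
entries fall back to the nominal study conditions.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .globalfit import FitConfig
from .kinetics import (
    DT_RATES,
    InstrumentResponse,
    RateSet,
    ReactionNetwork,
    default_delay_grid,
    default_dt_network,
)
from .synthetic import ScenarioConfig

__all__ = ["load_config", "save_config", "scenario_from_dict", "network_from_dict",
           "fit_config_from_dict"]


def network_from_dict(d: dict | None) -> ReactionNetwork:
    d = d or {}
    return default_dt_network(
        edge_assignment=d.get("edge_assignment"),
        merge_hot_group=bool(d.get("merge_hot_group", False)),
        fit_dt_star_pattern=bool(d.get("fit_dt_star_pattern", False)),
    )


def _rates_from_dict(d: dict | None) -> RateSet:
    if not d:
        return DT_RATES
    return RateSet(**{k: float(v) for k, v in d.items()})


def scenario_from_dict(d: dict | None, network: ReactionNetwork | None = None) -> ScenarioConfig:
    d = d or {}
    qspec = d.get("q", {})
    q = np.linspace(float(qspec.get("min", 0.5)), float(qspec.get("max", 4.5)),
                    int(qspec.get("n", 60)))
    tspec = d.get("delays", {})
    t = default_delay_grid(
        n_linear=int(tspec.get("n_linear", 40)), n_log=int(tspec.get("n_log", 40)),
        t_min=float(tspec.get("t_min", -500.0)),
        t_switch=float(tspec.get("t_switch", 1000.0)),
        t_max=float(tspec.get("t_max", 3.0e6)),
    )
    irf = d.get("irf", {})
    return ScenarioConfig(
        network=network if network is not None else default_dt_network(),
        rates=_rates_from_dict(d.get("rates")),
        gamma=float(d.get("gamma", 0.045)),
        irf=InstrumentResponse(float(irf.get("fwhm", 238.0)), float(irf.get("t0", 0.0))),
        q=q, t=t,
        noise=float(d.get("noise", 0.1)),
        hot_amplitude=float(d.get("hot_amplitude", 0.05)),
        hot_frames=int(d.get("hot_frames", 100)),
        seed=d.get("seed"),
    )


def fit_config_from_dict(d: dict | None) -> FitConfig:
    d = d or {}
    cfg = FitConfig(
        n_restarts=int(d.get("n_restarts", 20)),
        seed=d.get("seed"),
        fit_t0=bool(d.get("fit_t0", False)),
        fit_irf=bool(d.get("fit_irf", False)),
        prior_strength=float(d.get("prior_strength", 10.0)),
    )
    if "bounds" in d:
        cfg.bounds.update({k: tuple(map(float, v)) for k, v in d["bounds"].items()})
    return cfg


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError(f"config root must be a mapping, got {type(doc).__name__}")
    return doc


def save_config(path: str | Path, doc: dict) -> None:
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
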