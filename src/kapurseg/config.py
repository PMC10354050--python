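"""Run configuration: flat YAML key-value files -> typed parameter objects.

Keys mirror the published parameter names (beta, W, p, P_gj, n_agents,
max_iters) plus pipeline knobs (optimizer, M, top_k, ADF and bias-field
settings, seed, repeats).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .gto import GTOParams
from .preprocess import ADFParams
from .rbl import RBLParams
from .segment import PipelineConfig


@dataclass
class RunConfig:
    """Batch-experiment configuration (one segmentation repeat protocol)."""

    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    seed: int = 0
    repeats: int = 10

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


_GTO_KEYS = {"n_agents": "n_agents", "max_iters": "max_iters",
             "p": "p", "beta": "beta", "W": "W"}
_RBL_KEYS = {"phi0": "phi0", "sigma": "sigma", "P_gj": "p_gj"}
_ADF_KEYS = {"adf_iters": "n_iters", "kappa": "kappa", "lam": "lam"}


def config_from_dict(data: dict) -> RunConfig:
    data = dict(data or {})
    gto = GTOParams(**{dst: data.pop(src) for src, dst in _GTO_KEYS.items()
                       if src in data})
    rbl = RBLParams(**{dst: data.pop(src) for src, dst in _RBL_KEYS.items()
                       if src in data})
    adf = ADFParams(**{dst: data.pop(src) for src, dst in _ADF_KEYS.items()
                       if src in data})
    pipeline = PipelineConfig(
        optimizer=data.pop("optimizer", "gtorbl"),
        n_thresholds=int(data.pop("M", 4)),
        top_k=int(data.pop("top_k", 1)),
        gto_params=gto, rbl_params=rbl, adf_params=adf,
        iih_window=int(data.pop("iih_window", 127)),
        iih_sigma=float(data.pop("iih_sigma", 224.0)),
    )
    cfg = RunConfig(pipeline=pipeline,
                    seed=int(data.pop("seed", 0)),
                    repeats=int(data.pop("repeats", 10)))
    if data:
        raise ValueError(f"unknown config keys: {sorted(data)}")
    return cfg


def load_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return RunConfig()
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})
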