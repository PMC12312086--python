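"""YAML configuration loading for the CLI.

The config file is a nested mapping with optional ``generator``,
``pipeline`` and ``experiment`` sections whose keys mirror the dataclass
fields. User-facing band numbers are 1-based (band 2 = 492 nm) and are
converted to 0-based indices here, at the interface layer.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import yaml

from .bands import band_index
from .experiments import ExperimentConfig, PipelineSettings
from .preprocess import MaskThresholds
from .synth import GeneratorConfig


def _coerce_generator(d: dict) -> GeneratorConfig:
    gen = GeneratorConfig()
    for k, v in d.items():
        if not hasattr(gen, k):
            raise ValueError(f"unknown generator setting {k!r}")
        if k == "start_date" and isinstance(v, str):
            v = _dt.date.fromisoformat(v)
        if k in ("bleaching_window", "gain_range", "offset_range",
                 "noise_sd_range", "glint_amplitude_range"):
            v = tuple(v)
        setattr(gen, k, v)
    return gen


def _coerce_pipeline(d: dict) -> PipelineSettings:
    pipe = PipelineSettings()
    d = dict(d)
    if "band" in d:
        d["band"] = band_index(int(d["band"]))
    if "mask_thresholds" in d:
        d["mask_thresholds"] = MaskThresholds(**d["mask_thresholds"])
    for k, v in d.items():
        if not hasattr(pipe, k):
            raise ValueError(f"unknown pipeline setting {k!r}")
        setattr(pipe, k, v)
    return pipe


def load_config(path: str | Path) -> ExperimentConfig:
    """Parse a YAML config into an :class:`ExperimentConfig`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    exp = raw.get("experiment", {})
    return ExperimentConfig(
        scenario=exp.get("scenario", raw.get("scenario", "horseshoe")),
        generator=_coerce_generator(raw.get("generator", {})),
        pipeline=_coerce_pipeline(raw.get("pipeline", {})),
        n_seeds=int(exp.get("n_seeds", raw.get("n_seeds", 1))),
        out_dir=str(exp.get("out_dir", raw.get("out_dir", "results"))),
    )
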