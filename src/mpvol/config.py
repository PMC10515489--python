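"""YAML run configuration.

A config file can override the image scale, thresholding, model
parameters (including per-group Tanoiri height rules) and the output
directory, e.g.::

    scale_px_mm: 40
    threshold: otsu
    min_area_px: 20
    seed: 1
    models:
      k_c: 0.1
      k_i: 0.4
      fiber_void_fraction: 0.4
      clamp_cf: false
      tanoiri_groups:
        fragments: {axis: minor, slope: 0.55, intercept: 0.0}
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .volume_models import ModelParams, TanoiriGroup

__all__ = ["load_config", "params_from_config"]


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return {}
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config root must be a mapping")
    return cfg


def params_from_config(cfg: dict) -> ModelParams:
    """Model parameters from a loaded config (missing keys keep defaults)."""
    m = cfg.get("models", {})
    kwargs = {}
    for key in ("k_c", "k_i", "fiber_void_fraction", "clamp_cf"):
        if key in m:
            kwargs[key] = m[key]
    if "tanoiri_groups" in m:
        kwargs["tanoiri_groups"] = {
            name: TanoiriGroup(axis=g.get("axis", "minor"),
                               slope=float(g["slope"]),
                               intercept=float(g.get("intercept", 0.0)))
            for name, g in m["tanoiri_groups"].items()
        }
    return ModelParams(**kwargs)
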