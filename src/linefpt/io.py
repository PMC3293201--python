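"""Structured-text configuration for campaign runs (YAML)."""
from __future__ import annotations

from dataclasses import asdict

import yaml

from .experiment import DesignSpec
from .movestats import MovementParams

__all__ = ["load_design", "save_design"]


def save_design(spec: DesignSpec, path) -> None:
    payload = asdict(spec)
    payload["params"] = asdict(spec.params)
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_design(path) -> DesignSpec:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    pdata = payload.pop("params")
    pdata.pop("ci", None)
    params = MovementParams(**pdata)
    for key in ("seismic_densities", "prey_densities", "models"):
        if key in payload:
            payload[key] = tuple(payload[key])
    return DesignSpec(params=params, **payload)
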