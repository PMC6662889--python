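"""Named sequence-parameter presets shipped with the package."""

from __future__ import annotations

from importlib import resources
from typing import Dict

import yaml

from .trajectory import Scheme, SequenceParams

__all__ = ["available_presets", "get_preset", "load_params"]


def _raw() -> Dict[str, dict]:
    text = resources.files("epikit").joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)


def available_presets() -> list[str]:
    return sorted(_raw())


def get_preset(name: str) -> SequenceParams:
    """Return the named preset ("epi64" or "epik96") as SequenceParams."""
    raw = _raw()
    if name not in raw:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(raw))}"
        )
    return load_params(raw[name])


def load_params(d: dict) -> SequenceParams:
    d = dict(d)
    d["scheme"] = Scheme(d.get("scheme", "EPI"))
    return SequenceParams(**d)
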