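"""Versioned reference parameterizations, shipped as JSON.

Presets are tuned once against the qualitative anchors of the biology they
emulate (bistability window, irreversibility onset, induction delays, dose
threshold) and then frozen; all analyses and tests load them from here.
"""

from __future__ import annotations

import json
from importlib import resources

from ..params import KineticParameters

#: dose (ug) -> stimulus (a.u.) scale of the dermal-injection preset
DOSE_SCALE_KEY = "dose_scale"


def _load(name: str) -> dict:
    with resources.files(__package__).joinpath(f"{name}.json").open() as fh:
        return json.load(fh)


def load_params(name: str) -> KineticParameters:
    """Load a packaged preset: ``dox_reference``, ``mrc5``, ``imr90`` or
    ``dermal_injection``."""
    data = _load(name)
    return KineticParameters.from_dict(data["parameters"])


def load_meta(name: str) -> dict:
    """Preset metadata (mode, dose scale, provenance notes)."""
    data = _load(name)
    return {k: v for k, v in data.items() if k != "parameters"}


def available() -> list[str]:
    return sorted(
        p.name[:-5]
        for p in resources.files(__package__).iterdir()
        if p.name.endswith(".json")
    )
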