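"""Shipped population presets (JSON data files)."""

from __future__ import annotations

import json
from importlib import resources

from ..config import PopulationSpec


def load_population_presets() -> dict:
    """Raw presets dict as shipped (means/sds per population)."""
    with resources.files(__package__).joinpath("populations.json").open() as fh:
        return json.load(fh)


def preset_spec(name: str, n_cells: int) -> PopulationSpec:
    """Build a PopulationSpec for a shipped preset population."""
    presets = load_population_presets()["populations"]
    if name not in presets:
        raise KeyError(f"unknown preset population {name!r}; have {sorted(presets)}")
    p = presets[name]
    return PopulationSpec(name=name, n_cells=n_cells,
                          mean=dict(p["mean"]), sd=dict(p.get("sd", {})))
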