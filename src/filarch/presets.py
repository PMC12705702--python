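"""Named lattice presets and derivation of new ones from deposited models.

The only preset shipped with the package is the reported IFI16 pyrin-domain
lattice (see :data:`filarch.synthetic.IFI16_PRESET`). Presets for comparator
filaments (ASC-like, AIM2-like, …) are *derived*: computed from a deposited
coordinate file via :func:`derive_preset` and cached locally with a
provenance stamp, so they are never hand-entered.
"""

from __future__ import annotations

import json
from pathlib import Path

from .helical import HelicalParams, estimate_params
from .io import order_protomers, read_structure
from .synthetic import IFI16_PRESET, LatticePreset

__all__ = ["IFI16_PRESET", "derive_preset", "load_cached_preset", "save_preset"]

DEFAULT_CACHE = Path("derived_presets.json")


def derive_preset(coordinate_file: str | Path, name: str,
                  format: str | None = None,
                  cache_path: str | Path | None = DEFAULT_CACHE) -> LatticePreset:
    """Estimate a lattice preset from a deposited filament model.

    Reads the file, orders the chains along the 1-start helix, estimates
    twist/rise/cn, and (unless ``cache_path`` is None) records the result
    with a ``derived`` provenance stamp naming the source file.
    """
    chains = read_structure(coordinate_file, format=format)
    assembly = order_protomers(chains)
    params = estimate_params(assembly)
    preset = LatticePreset(name=name, params=params, provenance="derived")
    if cache_path is not None:
        save_preset(preset, cache_path, source=str(coordinate_file))
    return preset


def save_preset(preset: LatticePreset, cache_path: str | Path,
                source: str = "") -> None:
    path = Path(cache_path)
    data = json.loads(path.read_text()) if path.exists() else {}
    data[preset.name] = {
        "twist_deg": preset.params.twist_deg,
        "rise_A": preset.params.rise_A,
        "cn": preset.params.cn,
        "n_start": preset.params.n_start,
        "provenance": preset.provenance,
        "source": source,
    }
    path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")


def load_cached_preset(name: str,
                       cache_path: str | Path = DEFAULT_CACHE) -> LatticePreset:
    data = json.loads(Path(cache_path).read_text())
    if name not in data:
        raise KeyError(f"no cached preset {name!r} in {cache_path}")
    d = data[name]
    return LatticePreset(
        name=name,
        params=HelicalParams(twist_deg=d["twist_deg"], rise_A=d["rise_A"],
                             cn=d["cn"], n_start=d["n_start"]),
        provenance=d.get("provenance", "derived"))
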