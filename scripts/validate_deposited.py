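#!/usr/bin/env python
"""Measure the deposited pyrin-domain filament models (requires network).

Downloads the published cryo-EM coordinate files from the PDB archive,
rebuilds each filament frame, and reports: helical parameters, base-layer
polygon counts, rim diameters, interior shell sizes, monomer core RMSDs and
the cross-threading score orderings. Also caches derived lattice presets for
the comparator filaments.

Usage:
    python scripts/validate_deposited.py --dest structures --out deposited.json
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

from filarch.deposited import (
    adapter_swap_total,
    core_rmsd,
    deposited_monomer,
    homo_threading_total,
    interior_honeycomb,
    load_deposited_filament,
)
from filarch.helical import estimate_params
from filarch.lattice import base_layer_count, rim_diameters
from filarch.presets import save_preset
from filarch.synthetic import LatticePreset

ACCESSIONS = {
    "ifi16": "9muf",
    "asc": "3j63",
    "aim2": "7k3r",
    "nlrp3": "7pzd",
    "nlrp6": "6ncv",
}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--dest", type=Path, default=Path("structures"))
    ap.add_argument("--out", type=Path, default=Path("deposited.json"))
    ap.add_argument("--preset-cache", type=Path, default=Path("derived_presets.json"))
    args = ap.parse_args()

    report: dict = {}
    filaments = {}
    for name, acc in ACCESSIONS.items():
        fil = load_deposited_filament(acc, args.dest)
        filaments[name] = fil
        entry: dict = {"accession": acc, "n_chains": len(fil)}
        try:
            params = estimate_params(fil)
            entry["helical_params"] = {
                "twist_deg": round(params.twist_deg, 2),
                "rise_A": round(params.rise_A, 2),
                "cn": params.cn,
                "n_start": params.n_start,
            }
            save_preset(LatticePreset(f"{name}_derived", params, "derived"),
                        args.preset_cache, source=acc)
        except Exception as exc:  # deposited subsets may be too short
            entry["helical_params"] = {"error": str(exc)}
        try:
            entry["base_layer_count"] = base_layer_count(fil)
        except ValueError as exc:
            entry["base_layer_count"] = None
            entry["base_layer_note"] = str(exc)
        outer, inner = rim_diameters(fil)
        entry["rim_diameters_A"] = {"outer": round(outer), "inner": round(inner)}
        try:
            entry["interior_shell_size"] = len(interior_honeycomb(fil).shell)
        except Exception as exc:
            entry["interior_shell_size"] = None
            entry["shell_note"] = str(exc)
        report[name] = entry

    monomers = {n: deposited_monomer(a, args.dest) for n, a in ACCESSIONS.items()}
    report["monomer_core_rmsd_A"] = {
        "ifi16_vs_asc": round(core_rmsd(monomers["ifi16"], monomers["asc"]), 2),
        "aim2_vs_asc": round(core_rmsd(monomers["aim2"], monomers["asc"]), 2),
    }

    report["cross_threading_totals"] = {
        "ifi16_in_own_lattice": homo_threading_total(
            monomers["ifi16"], filaments["ifi16"]).total,
        "ifi16_in_aim2_lattice": homo_threading_total(
            monomers["ifi16"], filaments["aim2"]).total,
        "asc_in_receptor_shells": {
            rec: adapter_swap_total(monomers["asc"], filaments[rec]).total
            for rec in ("nlrp3", "nlrp6", "aim2", "ifi16")
        },
    }

    args.out.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    print(json.dumps(report, indent=2, sort_keys=True))


if __name__ == "__main__":
    main()
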