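# filarch

Helical-lattice architecture analysis for death-fold (PYD/CARD) protein
filaments.

Pyrin domains (PYDs) and caspase-recruitment domains (CARDs) are ~90-residue
six-helix bundles that polymerize into helical filaments during innate-immune
signaling. A filament is described by a screw operator — an azimuthal twist
Δφ (degrees per subunit) and an axial rise Δz (Å per subunit) along the
1-start helix, optionally with an axial point group Cn — and each subunit
touches its neighbors through three conserved asymmetric interface classes
(Type 1, 2, 3, each with an `a` and a `b` surface). Whether two homologous
domains can co-assemble is largely a question of lattice architecture:
a monomer rigidly threaded into the honeycomb neighborhood of a foreign
filament either fits its shell or collides with it.

`filarch` implements that analysis end to end:

- **structure I/O** (`filarch.io`): mmCIF/PDB reading and writing through
  gemmi, decomposition into protomers, cylindrical axis fitting and 1-start
  re-indexing of deposited chains;
- **screw algebra** (`filarch.helical`): build filaments from
  (twist, rise, Cn), decompose rigid transforms into screw form, and
  estimate parameters from an assembly via Kabsch superposition of
  consecutive subunits (median-aggregated, with Cn and strand-count
  detection);
- **lattice analysis** (`filarch.lattice`): heavy-atom contact graphs,
  honeycomb neighborhoods with Type 1/2/3 interface labels, base-layer
  polygon counts, outer/inner rim diameters, residue-to-interface
  annotation;
- **compatibility** (`filarch.compat`): rigid threading of a monomer onto a
  template center, a transparent clash/contact score per interface with
  exact top/bottom half-sums, center-subunit swapping, honeycomb overlays
  and core-trimmed monomer RMSDs;
- **synthetic fixtures** (`filarch.synthetic`): coarse-grained six-helix
  protomers on idealized lattices with known ground truth, so the entire
  pipeline is testable offline;
- **CLI** (`filarch`): `analyze`, `thread`, `swap-center`, `compare`,
  `fixture`, `fetch`.

The steric score is `w_clash · (pairs < 2.6 Å) − w_contact · (non-clashing
pairs < 4.5 Å)`; lower is more favorable. Only its sign and orderings are
meaningful — it is a transparent stand-in for physics-based interface
energies, not a reimplementation of them.

## Worked example

Generate a 24-subunit coarse-grained filament on the IFI16 pyrin-domain
lattice (twist 134.6°, rise 5.6 Å, C1) and analyze it:

```sh
$ filarch fixture --n 24 --out fixture.pdb
$ filarch analyze fixture.pdb --protein toy6 --out report
{
  "helical_params": {
    "cn": 1, "handedness": "right", "n_start": 3,
    "rise_A": 5.6, "twist_deg": 134.6
  },
  "honeycomb": {
    "center_index": 12, "offsets": [-3, -2, -1, 1, 2, 3], "shell_size": 6
  },
  "n_protomers": 24,
  "rim_diameters_A": {"inner": 3, "outer": 55}, ...
}
```

The estimator recovers the generating twist and rise exactly; the lattice is
read as a three-start helix (`n_start: 3`), and an interior subunit touches
six neighbors at offsets ±1, ±2, ±3 — the canonical PYD honeycomb shell.
Rim diameters are toy-scale (the coarse protomer is smaller than a real
PYD). Threading the protomer back into its own honeycomb is clash-free
and maximally favorable, split exactly between the two axial halves:

```sh
$ filarch thread fixture.pdb fixture.pdb --identity --out out
...
"half_sums": {"bottom": -17.0, "top": -17.0}, "total": -34.0
```

On deposited models the same commands measure the real quantities (base
pentagon/hexagon counts, 85/22 Å vs 94/25 Å rims, cross-threading
orderings); see `scripts/validate_deposited.py`, which needs network access
to the PDB archive.

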