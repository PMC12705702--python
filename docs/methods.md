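# Methods

## Model

A helical filament is an ordered set of protomers indexed along the 1-start
helix: protomer k+1 is protomer k transformed by a screw operator — rotation
by the twist Δφ about the filament axis composed with translation by the
rise Δz along it. An axial point group Cn (n > 1) additionally replicates
each level by rotations of 360/n. Death-fold filaments add a second layer of
structure: each interior subunit contacts six neighbors through the three
conserved asymmetric interface classes (Type 1: the h1/h2 face against the
h3/h4 face; Type 2: the h4–h5 corner against the h5–h6 loop; Type 3: the
short helix 3 against the h1–h2 loop). The "honeycomb" is the center-plus-
shell view of those six contacts, split into a top and a bottom axial half.

## Conventions

- **Axis and handedness.** The filament axis is fit to protomer centroids:
  principal-component initialization refined by cylindrical least squares
  (minimizing the variance of centroid radial distances about the line),
  restarted from all three principal directions and keeping the best fit —
  the centroid cloud of a short filament is nearly isotropic and a single
  initialization can converge to a skew local minimum. The axis direction
  is chosen so the rise from index k to k+1 is positive; positive twist is
  then a right-handed screw. Twist is reported in (−180°, 180°].
- **Screw decomposition.** Rotation angle/axis from the rotation matrix;
  rise is the translation component along the axis; the axis point solves
  (I − R)p = t⊥ in the plane normal to the axis. A rotation angle below
  tolerance raises an error: a pure translation has no unique screw axis.
- **Cn ambiguity.** With a Cn point group the level-to-level twist is only
  defined modulo 360/n (the lattices are literally identical); the estimator
  reports the smallest-magnitude representative, aligning all consecutive
  measurements to the first to avoid sign-flapping at the half-period.
- **Strand count.** `n_start` is descriptive, not an independent parameter.
  With Cn symmetry it equals n. Otherwise the lattice is read as d strands
  for the subunit offset d — within axial contact range, one protomer height
  plus the contact cutoff — that minimizes the residual azimuth
  |d·Δφ mod 360°|: subunits k and k+d then stack most nearly on top of one
  another. For Δφ = 134.6°, Δz = 5.6 Å this reads 3, the three-start
  description of the IFI16 pyrin-domain lattice.
- **Parameter estimation.** Consecutive subunits (one representative per
  level under Cn) are superposed by Kabsch over matched Cα atoms (falling
  back to heavy atoms for coarse-grained protomers); each transform is screw-
  decomposed and the median twist/rise is reported. Median, not mean:
  end-of-filament irregularities should not bias the estimate. A twist
  spread above 5° (or rise spread above 1 Å) across consecutive pairs raises
  a non-helical error rather than returning a meaningless median.

## Interface typing

The paperless part of interface classification is the assignment rule, which
is a declared design choice: for each shell contact, atom-level contacts are
attributed to the six surface groups of the center subunit (h1+h2 → 1a,
h3+h4 → 1b, h4–h5 corner → 2a, h5–h6 loop → 2b, h3 → 3a, h1–h2 loop → 3b,
with short loops widened by two flanking residues, and missing loop segments
synthesized from the gaps between annotated helices). The argmax group sets
both the type and the side the center presents. Because the Type-3a surface
(h3) is a subset of the Type-1b face (h3+h4), near-ties within a 10%
tolerance are resolved toward the more specific (smaller) group; a contact
that lands exclusively on h3 is Type 3, one spread across h3+h4 is Type 1b.
Ambiguity is flagged — never raised — when a group of a different type, not
in a subset relation with the winner, scores within the tolerance. A within-
type side tie falls back to the axial convention: the center presents its
'a' surface toward the +axis half. Segment ranges come from a packaged,
editable JSON table keyed by protein name; no external secondary-structure
program is invoked, because deposited models are cited by author residue
numbering and helix index.

## Lattice measurements

- **Contact graph.** Edge between protomers with ≥1 heavy-atom pair within
  the 4.5 Å contact cutoff (the standard interface-contact convention);
  k-d-tree neighbor search, validated against an exhaustive O(N²) oracle in
  the tests.
- **Base-layer count.** Protomers whose centroids lie within one protomer
  axial extent of the terminal centroid form the candidate slab; the
  reported value is the size of the minimal subset whose azimuthal arcs
  cover 360° (exact greedy circular arc cover, validated against brute-force
  subset enumeration). Hexameric bases read 6, the skewed-pentagon base of
  the IFI16 lattice reads 5.
- **Rim diameters.** Caliper convention: outer = 2 × maximum heavy-atom
  radial distance over interior subunits, inner = 2 × minimum. No probe
  radius is subtracted from the inner channel — the value is a plain caliper
  reading, chosen because it reproduces the printed diameters of the
  deposited models without assuming an unstated probe model. Interior
  subunits exclude one protomer extent at each end so frayed termini cannot
  bias either number.

## Cross-threading score

Threading is rigid: the monomer is superposed onto the template center over
mapped Cα atoms and nothing is remodeled or repacked. Each shell interface
scores `w_clash · n_clash − w_contact · n_contact`, where clashes are heavy-
atom pairs below 2.6 Å, contacts are non-clashing pairs below 4.5 Å, and the
default weights are 10 and 1. Keeping the score deterministic and purely
steric is the main divergence from energy-function protocols; in exchange,
only signs and orderings of the score are ever asserted (self-lattice beats
cross-lattice, clash counts grow with lattice mismatch), never magnitudes.
Residue correspondences between homologs come from Needleman–Wunsch global
alignment (BLOSUM62, gap open 10 / extend 1) or a user-supplied mapping;
threading requires the mapping to cover ≥60% of the template-center
residues. Core-trimmed monomer RMSD discards pairs with residuals above 2σ
iteratively (≤5 rounds, stopping when the retained set is stable or would
drop below 30 pairs).

## Synthetic fixtures

The generator emulates a death-fold-sized protomer as six antiparallel
pseudo-helix strips (one Cα-like pseudo-atom per residue, 88 residues) on
the surface of a convex ellipsoid of extents 26 × 20 × 16 Å, placed at a
14.5 Å centroid radius from the filament axis. Placing atoms on a convex
envelope is deliberate: copies of the protomer on the lattice then touch
without interpenetrating, so the native assembly is contact-rich but
clash-free at the 2.6 Å threshold, as packed domains are. The ellipsoid and
radius are calibrated — and asserted in the tests — so that an interior
subunit of the 134.6°/5.6 Å lattice touches exactly six neighbors at offsets
±1, ±2, ±3: the canonical honeycomb. Optional i.i.d. isotropic Gaussian
coordinate noise (the simplest perturbation that exercises estimator
robustness) is seeded and fully deterministic.

What the toy does **not** reproduce: side-chain chemistry (so interface
typing on toy lattices exercises the mechanics of the rule, not the real
type assignments), the tall interdigitating protomer shape of real PYDs
(so the toy IFI16-lattice base does not close azimuthally within one
protomer height and base counts are exercised on Cn ring lattices instead),
and absolute dimensions (toy rim diameters are smaller than the deposited
filaments'). Passing fixture tests therefore validate the algorithms and
their invariants, not any claim about a particular protein; deposited-model
numbers come from the accession-gated path (`scripts/validate_deposited.py`).

## Problem sizes and determinism

Fixture filaments use 24–40 subunits (large enough for interior honeycombs
and three slab thicknesses of base layer); the estimation grid spans twists
20–170°, rises 3–20 Å and Cn 1–3 at 12 subunits; noise-robustness checks use
20 replicate seeds at σ = 0.3 Å. Every random draw is seeded; identical
configuration and inputs yield byte-identical JSON reports.

## Known limitations

- Derived lattice presets for comparator filaments (ASC-like, AIM2-like)
  are computed from deposited models and cached with a provenance stamp;
  they are intentionally absent until `derive_preset` has run on a fetched
  file — they are never hand-entered.
- The inner-rim caliper convention reads the narrowest heavy-atom channel;
  a solvent-excluded-surface definition would give systematically larger
  cavities.
- Interface typing requires a segment table; on proteins whose helix
  boundaries deviate strongly from the packaged template the labels follow
  the table, not the structure.
- The steric score saturates at extreme lattice mismatch (once shells
  disengage, clash counts can plateau or dip); monotonicity is asserted only
  over moderate twist offsets.
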