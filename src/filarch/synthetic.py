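"""Coarse-grained protomers and idealized filament fixtures.

Death-fold domains (PYDs, CARDs) are compact six-helix bundles roughly
30 x 25 x 20 Å in extent. The generator here emulates one as a bundle of
pseudo-atom "helices" (one pseudo-atom per residue, Cα-like spacing), places
it at a configurable radius from the filament axis, and replicates it on a
helical lattice with known twist, rise and point-group order — so every
analysis stage can be exercised, with ground truth, without any downloaded
model. Optional isotropic Gaussian coordinate noise perturbs atoms i.i.d.

All fixtures are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .helical import HelicalParams, build_filament
from .structures import AtomSite, FilamentAssembly, ProtomerStructure

__all__ = [
    "ToyProtomerSpec",
    "LatticePreset",
    "IFI16_PRESET",
    "make_toy_protomer",
    "make_filament_fixture",
]

# Cycled through to give toy protomers a non-degenerate sequence, so that
# sequence-alignment-based residue mappings behave as they would on proteins.
_SEQ_CYCLE = "ADEFGHIKLMNPQRSTVWY"

_AA3 = {
    "A": "ALA", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY", "H": "HIS",
    "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN", "P": "PRO",
    "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL", "W": "TRP",
    "Y": "TYR",
}


@dataclass(frozen=True)
class ToyProtomerSpec:
    """Parameters of the coarse-grained six-helix bundle.

    The bundle is built as helix strips on the surface of a convex ellipsoid
    whose full extents are ``bundle_dimensions`` (radial, tangential, axial
    in the filament frame; the bundle sits on the +x side of the axis). Placing every pseudo-atom on a convex envelope
    keeps inter-subunit gaps controlled by the lattice geometry, so copies of
    the protomer touch without interpenetrating — the way packed domains do.
    ``centroid_radius`` is where the bundle centroid sits relative to the
    filament axis. The defaults are calibrated so that an interior subunit of
    the pyrin-domain lattice preset (twist 134.6°, rise 5.6 Å) touches
    exactly six neighbors (offsets ±1, ±2, ±3) at the standard 4.5 Å
    heavy-atom contact cutoff with native minimum distances above the 2.6 Å
    clash threshold — the canonical honeycomb shell, clash-free at rest.
    """

    n_pseudo_helices: int = 6
    pseudo_atoms_per_helix: int = 13
    bundle_dimensions: tuple[float, float, float] = (26.0, 20.0, 16.0)
    centroid_radius: float = 14.5
    jitter_A: float = 0.10
    wiggle_rad: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.bundle_dimensions):
            raise ValueError("bundle dimensions must be positive")
        if self.n_pseudo_helices < 2 or self.pseudo_atoms_per_helix < 2:
            raise ValueError("need >= 2 helices of >= 2 pseudo-atoms")


@dataclass(frozen=True)
class LatticePreset:
    """A named helical lattice with provenance.

    ``provenance`` records where the parameters came from: ``"reported"``
    (refined symmetry printed for a deposited structure), ``"derived"``
    (estimated from a model by this package; see
    :func:`filarch.presets.derive_preset`) or ``"user"``.
    """

    name: str
    params: HelicalParams
    provenance: str = "user"


#: Pyrin-domain filament lattice of IFI16: a three-start 1-start helix with
#: 134.6° rotation and 5.6 Å rise per subunit and no axial point group.
IFI16_PRESET = LatticePreset(
    name="IFI16_PYD",
    params=HelicalParams(twist_deg=134.6, rise_A=5.6, cn=1, n_start=3),
    provenance="reported",
)


def _ellipsoid_point(a: float, b: float, c: float,
                     theta: float, phi: float) -> np.ndarray:
    return np.array([a * np.sin(phi) * np.cos(theta),
                     b * np.sin(phi) * np.sin(theta),
                     c * np.cos(phi)])


def make_toy_protomer(spec: ToyProtomerSpec = ToyProtomerSpec()) -> ProtomerStructure:
    """Build a coarse-grained six-helix-bundle protomer.

    Pseudo-helices are antiparallel meridian strips on the surface of the
    bundle ellipsoid, each sweeping pole to pole with a small azimuthal
    wiggle (so the strip has finite width and the surface is well sampled);
    consecutive helices are bridged by two loop pseudo-atoms near the poles.
    One pseudo-atom per residue, labeled ``CA``/carbon, with ``ss_segments``
    (h1…h6 and the inter-helix loops) assigned from the construction. A
    small seeded jitter makes the bundle irregular without changing its
    envelope. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    a, b, c = (d / 2 for d in spec.bundle_dimensions)
    n_h = spec.n_pseudo_helices
    n_per = spec.pseudo_atoms_per_helix

    atoms: list[AtomSite] = []
    seq: list[str] = []
    ss: dict[str, tuple[int, int]] = {}
    resnum = 0

    def add_atom(pos: np.ndarray) -> None:
        nonlocal resnum
        resnum += 1
        aa = _SEQ_CYCLE[(resnum - 1) % len(_SEQ_CYCLE)]
        seq.append(aa)
        atoms.append(AtomSite(
            element="C", name="CA", residue_number=resnum,
            residue_name=_AA3[aa], chain_id="A",
            position=pos + rng.normal(0.0, spec.jitter_A, 3)))

    phis = np.linspace(0.32, np.pi - 0.32, n_per)  # avoid exact poles
    for h in range(1, n_h + 1):
        theta0 = 2 * np.pi * (h - 1) / n_h
        start = resnum + 1
        direction = 1 if h % 2 else -1  # antiparallel bundle
        phase = rng.uniform(0, 2 * np.pi)
        for j, phi in enumerate(phis[::direction]):
            theta = theta0 + spec.wiggle_rad * np.cos(phase + 2 * np.pi * j / 3.6)
            add_atom(_ellipsoid_point(a, b, c, theta, phi))
        ss[f"h{h}"] = (start, resnum)
        if h < n_h:
            phi_end = phis[-1] if direction == 1 else phis[0]
            theta1, theta2 = theta0, 2 * np.pi * h / n_h
            for frac in (1 / 3, 2 / 3):
                add_atom(_ellipsoid_point(a, b, c,
                                          theta1 + frac * (theta2 - theta1), phi_end))
            ss[f"loop_h{h}h{h + 1}"] = (resnum - 1, resnum)

    protomer = ProtomerStructure(atoms=atoms, label="toy", sequence="".join(seq),
                                 ss_segments=ss)
    # Place the bundle centroid at the lattice radius on the +x axis.
    shift = np.array([spec.centroid_radius, 0.0, 0.0]) - protomer.centroid
    return protomer.transformed(np.eye(3), shift)


@dataclass(frozen=True)
class FixtureGroundTruth:
    """What the generator actually used, for recovery tests."""

    params: HelicalParams
    axis_origin: np.ndarray
    axis_direction: np.ndarray
    noise_sigma: float
    seed: int
    protomer: ProtomerStructure = field(repr=False, default=None)


def make_filament_fixture(preset: LatticePreset,
                          spec: ToyProtomerSpec = ToyProtomerSpec(),
                          n: int = 24,
                          noise_sigma: float = 0.0,
                          seed: int = 0,
                          ) -> tuple[FilamentAssembly, FixtureGroundTruth]:
    """Build an idealized filament of toy protomers plus its ground truth.

    The filament is generated on the z axis by :func:`build_filament`; if
    ``noise_sigma > 0``, i.i.d. isotropic Gaussian noise is added to every
    atom. Returns the (possibly noisy) assembly and a ground-truth record
    with the generating parameters, axis and seed.
    """
    if n < 6:
        raise ValueError(f"need n >= 6 subunits for a meaningful fixture, got {n}")
    protomer = make_toy_protomer(spec)
    filament = build_filament(protomer, preset.params, n)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        noisy = []
        for p in filament.protomers:
            delta = rng.normal(0.0, noise_sigma, (len(p.atoms), 3))
            atoms = [AtomSite(a.element, a.name, a.residue_number, a.residue_name,
                              a.chain_id, a.position + d)
                     for a, d in zip(p.atoms, delta)]
            noisy.append(ProtomerStructure(atoms=atoms, label=p.label,
                                           sequence=p.sequence,
                                           ss_segments=dict(p.ss_segments)))
        filament = FilamentAssembly(protomers=noisy,
                                    axis_origin=filament.axis_origin,
                                    axis_direction=filament.axis_direction,
                                    params=filament.params)
    truth = FixtureGroundTruth(params=preset.params,
                               axis_origin=filament.axis_origin,
                               axis_direction=filament.axis_direction,
                               noise_sigma=noise_sigma, seed=seed,
                               protomer=protomer)
    return filament, truth
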