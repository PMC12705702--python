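"""Core in-memory containers for protomers and filament assemblies.

A *protomer* is one subunit of a helical filament: a labeled set of atomic
(or pseudo-atomic) coordinates with residue metadata and an optional
secondary-structure segmentation (``h1`` … ``h6`` plus inter-helix loops for
a death-fold domain). A *filament assembly* is an ordered list of protomers
indexed along the 1-start helix, together with the filament axis that serves
as the reference frame for all geometric measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AtomSite",
    "ProtomerStructure",
    "FilamentAssembly",
    "CompositionError",
    "DegenerateGeometryError",
]

#: Elements treated as hydrogen for the heavy-atom flag.
_HYDROGEN = {"H", "D", "T"}


class CompositionError(ValueError):
    """Chains that should be copies of one protomer differ in residue content."""


class DegenerateGeometryError(ValueError):
    """Geometry does not define the requested quantity (e.g. collinear centroids)."""


@dataclass(frozen=True)
class AtomSite:
    """One atom record.

    Parameters
    ----------
    element:
        Chemical element symbol (upper case, e.g. ``"C"``).
    name:
        Atom label within the residue (e.g. ``"CA"``).
    residue_number:
        Author residue numbering; authoritative for all residue references.
    residue_name:
        Three-letter residue code.
    chain_id:
        Chain identifier in the source file.
    position:
        Cartesian coordinates in Å.
    """

    element: str
    name: str
    residue_number: int
    residue_name: str
    chain_id: str
    position: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom position must be a finite 3-vector, got {pos!r}")
        object.__setattr__(self, "position", pos)

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in _HYDROGEN


@dataclass
class ProtomerStructure:
    """One filament subunit with coordinates and residue metadata.

    ``ss_segments`` maps segment names (``h1`` … ``h6``, ``loop_h1h2``,
    ``loop_h5h6``, …) to inclusive author-residue-number ranges. Segments are
    the basis of interface typing, so coarse-grained protomers carry them too.
    """

    atoms: list[AtomSite]
    label: str = ""
    sequence: str = ""
    ss_segments: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not any(a.is_heavy for a in self.atoms):
            raise ValueError(f"protomer {self.label!r} has no heavy atoms")
        span = self.residue_span
        for name, (lo, hi) in self.ss_segments.items():
            if lo > hi or lo < span[0] or hi > span[1]:
                raise ValueError(
                    f"segment {name!r} range {lo}-{hi} outside residue span {span}"
                )

    # -- coordinate views -------------------------------------------------

    def coords(self, heavy_only: bool = True) -> np.ndarray:
        sel = [a for a in self.atoms if (a.is_heavy or not heavy_only)]
        return np.array([a.position for a in sel], dtype=float)

    def heavy_atoms(self) -> list[AtomSite]:
        return [a for a in self.atoms if a.is_heavy]

    def ca_coords(self) -> dict[int, np.ndarray]:
        """Residue number -> Cα position. Falls back to one heavy atom per
        residue (the first) for coarse-grained protomers without ``CA`` labels."""
        out: dict[int, np.ndarray] = {}
        for a in self.atoms:
            if a.name == "CA" and a.is_heavy:
                out[a.residue_number] = a.position
        if not out:
            for a in self.heavy_atoms():
                out.setdefault(a.residue_number, a.position)
        return out

    @property
    def centroid(self) -> np.ndarray:
        return self.coords(heavy_only=True).mean(axis=0)

    @property
    def residue_numbers(self) -> list[int]:
        seen: dict[int, None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_number, None)
        return list(seen)

    @property
    def residue_span(self) -> tuple[int, int]:
        nums = [a.residue_number for a in self.atoms]
        return (min(nums), max(nums))

    def residue_composition(self) -> tuple[tuple[int, str], ...]:
        seen: dict[tuple[int, str], None] = {}
        for a in self.atoms:
            seen.setdefault((a.residue_number, a.residue_name), None)
        return tuple(seen)

    # -- transforms -------------------------------------------------------

    def transformed(self, rotation: np.ndarray, translation: np.ndarray,
                    label: str | None = None) -> "ProtomerStructure":
        """Return a rigid-body transformed copy (positions -> R p + t)."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        atoms = [replace(a, position=R @ a.position + t) for a in self.atoms]
        return ProtomerStructure(
            atoms=atoms,
            label=self.label if label is None else label,
            sequence=self.sequence,
            ss_segments=dict(self.ss_segments),
        )

    def segment_residues(self, names: Iterable[str]) -> set[int]:
        out: set[int] = set()
        for n in names:
            if n in self.ss_segments:
                lo, hi = self.ss_segments[n]
                out.update(range(lo, hi + 1))
        return out


@dataclass
class FilamentAssembly:
    """Ordered protomers along the 1-start helix plus the filament axis frame.

    ``protomers[k]`` is the subunit at 1-start index ``index_offset + k``.
    ``axis_direction`` is the unit vector along which the per-subunit rise is
    positive; positive twist means a right-handed screw about it.
    """

    protomers: list[ProtomerStructure]
    axis_origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axis_direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    params: "object | None" = None  # HelicalParams when known
    index_offset: int = 0

    def __post_init__(self) -> None:
        # A meaningful filament has >= 2 subunits, but a 1-subunit assembly
        # is allowed as the degenerate output of building with n = 1.
        if len(self.protomers) < 1:
            raise ValueError("a filament needs at least 1 protomer")
        comp0 = self.protomers[0].residue_composition()
        for p in self.protomers[1:]:
            if p.residue_composition() != comp0:
                raise CompositionError(
                    f"protomer {p.label!r} residue composition differs from "
                    f"{self.protomers[0].label!r}"
                )
        self.axis_origin = np.asarray(self.axis_origin, float)
        d = np.asarray(self.axis_direction, float)
        nrm = np.linalg.norm(d)
        if nrm < 1e-12:
            raise DegenerateGeometryError("axis direction has zero length")
        self.axis_direction = d / nrm

    def __len__(self) -> int:
        return len(self.protomers)

    def __getitem__(self, k: int) -> ProtomerStructure:
        return self.protomers[k]

    # -- axis-frame helpers ----------------------------------------------

    def axial_coord(self, point: np.ndarray) -> float:
        return float(np.dot(np.asarray(point, float) - self.axis_origin,
                            self.axis_direction))

    def radial_distance(self, point: np.ndarray) -> float:
        v = np.asarray(point, float) - self.axis_origin
        v_par = np.dot(v, self.axis_direction) * self.axis_direction
        return float(np.linalg.norm(v - v_par))

    def azimuth(self, point: np.ndarray) -> float:
        """Azimuth in radians in a fixed frame perpendicular to the axis."""
        e1, e2 = _perpendicular_frame(self.axis_direction)
        v = np.asarray(point, float) - self.axis_origin
        return float(np.arctan2(np.dot(v, e2), np.dot(v, e1)))

    def centroids(self) -> np.ndarray:
        return np.array([p.centroid for p in self.protomers])

    def axial_coords(self) -> np.ndarray:
        return np.array([self.axial_coord(c) for c in self.centroids()])

    def protomer_axial_extent(self) -> float:
        """Median (over protomers) span of heavy-atom axial coordinates."""
        spans = []
        for p in self.protomers:
            z = (p.coords() - self.axis_origin) @ self.axis_direction
            spans.append(z.max() - z.min())
        return float(np.median(spans))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "FilamentAssembly":
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        return FilamentAssembly(
            protomers=[p.transformed(R, t) for p in self.protomers],
            axis_origin=R @ self.axis_origin + t,
            axis_direction=R @ self.axis_direction,
            params=self.params,
            index_offset=self.index_offset,
        )


def _perpendicular_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal pair perpendicular to ``axis``."""
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    seed = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(seed, a)) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    e1 = seed - np.dot(seed, a) * a
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a, e1)
    return e1, e2
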