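"""Coordinate file I/O and filament-frame construction.

Reads mmCIF (PDBx) and PDB v3.3 files through gemmi, splits them into one
:class:`~filarch.structures.ProtomerStructure` per polymer chain, and orders
chains along the 1-start helix after fitting the filament axis to the
protomer centroids.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import gemmi
import numpy as np
from scipy.optimize import least_squares

from .structures import (
    AtomSite,
    CompositionError,
    DegenerateGeometryError,
    FilamentAssembly,
    ProtomerStructure,
)

__all__ = [
    "FormatError",
    "EmptyInputError",
    "read_structure",
    "write_pdb",
    "order_protomers",
    "fit_axis",
    "load_ss_segments",
]


class FormatError(ValueError):
    """File did not parse under the named coordinate-file standard."""


class EmptyInputError(ValueError):
    """File contained no polymer chains."""


_ONE_LETTER = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V", "MSE": "M",
}


def read_structure(path: str | Path, format: str | None = None,
                   ss_segments: dict[str, tuple[int, int]] | None = None
                   ) -> list[ProtomerStructure]:
    """Read a coordinate file into one protomer per polymer chain.

    Hydrogens are retained (flagged via ``AtomSite.is_heavy``); alternate
    locations are resolved to the highest-occupancy conformer; author residue
    numbering is kept, with insertion-code ordering preserved by gemmi's
    sequential residue traversal. ``format`` is inferred from the suffix when
    not given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or ("mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb")).lower()
    try:
        if fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        elif fmt == "pdb":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
        else:
            raise ValueError(f"unknown format {fmt!r}; use 'mmcif' or 'pdb'")
    except (RuntimeError, ValueError) as exc:
        if isinstance(exc, ValueError) and "unknown format" in str(exc):
            raise
        raise FormatError(f"could not parse {path} as {fmt}: {exc}") from exc
    st.setup_entities()
    st.remove_alternative_conformations()  # keeps highest occupancy
    model = st[0]
    protomers: list[ProtomerStructure] = []
    for chain in model:
        poly = chain.get_polymer()
        if len(poly) == 0:
            continue
        atoms: list[AtomSite] = []
        seq_parts: list[str] = []
        for res in poly:
            seq_parts.append(_ONE_LETTER.get(res.name.upper(), "X"))
            for at in res:
                atoms.append(AtomSite(
                    element=at.element.name.upper(),
                    name=at.name,
                    residue_number=res.seqid.num,
                    residue_name=res.name,
                    chain_id=chain.name,
                    position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                ))
        if not atoms:
            continue
        protomers.append(ProtomerStructure(
            atoms=atoms, label=chain.name, sequence="".join(seq_parts),
            ss_segments=dict(ss_segments or {})))
    if not protomers:
        raise EmptyInputError(f"{path} contains no polymer chains")
    return protomers


def write_pdb(protomers: list[ProtomerStructure] | FilamentAssembly,
              path: str | Path) -> Path:
    """Write protomers as chains of a PDB v3.3 file (coordinates to 0.001 Å)."""
    if isinstance(protomers, FilamentAssembly):
        protomers = protomers.protomers
    st = gemmi.Structure()
    st.name = "filarch"
    model = gemmi.Model("1")
    chain_ids = _chain_id_stream()
    for p in protomers:
        chain = gemmi.Chain(next(chain_ids))
        cur_num, res = None, None
        for a in p.atoms:
            if a.residue_number != cur_num:
                res = gemmi.Residue()
                res.name = a.residue_name
                res.seqid = gemmi.SeqId(a.residue_number, " ")
                chain.add_residue(res)
                cur_num = a.residue_number
            at = gemmi.Atom()
            at.name = a.name
            at.element = gemmi.Element(a.element)
            at.pos = gemmi.Position(*a.position)
            at.occ = 1.0
            chain[len(chain) - 1].add_atom(at)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    path = Path(path)
    st.write_pdb(str(path))
    return path


def _chain_id_stream():
    import string
    for c in string.ascii_uppercase + string.ascii_lowercase + string.digits:
        yield c
    i = 0
    while True:  # two-character ids for very long filaments (mmCIF only)
        yield f"A{i}"
        i += 1


# ---------------------------------------------------------------------------
# Filament axis and 1-start ordering
# ---------------------------------------------------------------------------

def fit_axis(centroids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fit the filament axis to protomer centroids.

    Initial direction from the principal axis of the centroid cloud, refined
    by cylindrical least squares (minimizing the variance of the radial
    distances of centroids about the line). Returns ``(origin, direction)``
    with the origin at the centroid mean.
    """
    C = np.asarray(centroids, float)
    if len(C) < 3:
        raise ValueError("need >= 3 centroids to fit an axis")
    mean = C.mean(axis=0)
    X = C - mean
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    if np.ptp(X @ vt[0]) < 1e-6:
        raise DegenerateGeometryError("centroids have no extent along any axis")

    def residuals(p):
        # p = (theta, phi, ox, oy): direction spherical angles, offset in the
        # plane perpendicular to the current direction.
        th, ph, ox, oy = p
        d = np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])
        e1, e2 = _perp_pair(d)
        o = mean + ox * e1 + oy * e2
        v = C - o
        r = np.linalg.norm(v - np.outer(v @ d, d), axis=1)
        return r - r.mean()

    # The centroid cloud of a short filament is nearly isotropic, so the
    # principal axis is an unreliable initializer on its own: refine from
    # every principal direction and keep the best cylindrical fit.
    best = None
    for d0 in vt:
        th0 = float(np.arccos(np.clip(d0[2], -1, 1)))
        ph0 = float(np.arctan2(d0[1], d0[0]))
        sol = least_squares(residuals, x0=[th0, ph0, 0.0, 0.0], method="lm")
        if best is None or sol.cost < best.cost:
            best = sol
    th, ph, ox, oy = best.x
    d = np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])
    e1, e2 = _perp_pair(d)
    origin = mean + ox * e1 + oy * e2
    radial = np.linalg.norm((C - origin) - np.outer((C - origin) @ d, d), axis=1)
    if np.max(radial) < 1e-6:
        raise DegenerateGeometryError(
            "centroids are collinear: no helical arrangement")
    return origin, d


def _perp_pair(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    seed = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = seed - np.dot(seed, d) * d
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(d, e1)


def order_protomers(chains: list[ProtomerStructure]) -> FilamentAssembly:
    """Order chains along the 1-start helix and build the filament frame.

    The axis is fit to the chain centroids; chains are sorted by axial
    coordinate (ties within a co-level ring broken by azimuth) so that
    consecutive indices carry the smallest consistent screw displacement.
    The axis direction is chosen so the rise from index k to k+1 is positive.

    Raises
    ------
    CompositionError
        If chains differ in residue composition.
    DegenerateGeometryError
        If the centroids are collinear (no helical arrangement).
    """
    if len(chains) < 3:
        raise ValueError("need >= 3 chains to order a filament")
    comp0 = chains[0].residue_composition()
    for c in chains[1:]:
        if c.residue_composition() != comp0:
            raise CompositionError(
                f"chain {c.label!r} composition differs from {chains[0].label!r}")
    centroids = np.array([c.centroid for c in chains])
    origin, direction = fit_axis(centroids)
    z = (centroids - origin) @ direction
    # Group co-level chains (point-group rings) and sort within by azimuth.
    extent = np.median([np.ptp((c.coords() - origin) @ direction) for c in chains])
    tol = max(1e-6, 0.05 * float(extent))
    order = _axial_then_azimuth_order(z, centroids, origin, direction, tol)
    ordered = [chains[i] for i in order]
    return FilamentAssembly(protomers=ordered, axis_origin=origin,
                            axis_direction=direction)


def _azimuth(point: np.ndarray, origin: np.ndarray, direction: np.ndarray) -> float:
    e1, e2 = _perp_pair(direction)
    v = point - origin
    return float(np.arctan2(v @ e2, v @ e1))


def _axial_then_azimuth_order(z, centroids, origin, direction, tol):
    idx = list(np.argsort(z))
    groups: list[list[int]] = []
    for i in idx:
        if groups and z[i] - z[groups[-1][0]] <= tol:
            groups[-1].append(i)
        else:
            groups.append([i])
    out: list[int] = []
    for g in groups:
        out.extend(sorted(g, key=lambda i: _azimuth(centroids[i], origin, direction)))
    return out


# ---------------------------------------------------------------------------
# Secondary-structure segment tables
# ---------------------------------------------------------------------------

def load_ss_segments(protein: str, table_path: str | Path | None = None
                     ) -> dict[str, tuple[int, int]]:
    """Load an ss_segments table entry for ``protein``.

    Defaults come from the packaged JSON annotation table
    (``filarch/data/ss_segments.json``); pass ``table_path`` to use an edited
    copy. Entries map segment names (h1…h6, loop_h1h2, …) to inclusive
    author-residue ranges.
    """
    if table_path is not None:
        data = json.loads(Path(table_path).read_text())
    else:
        data = json.loads(
            resources.files("filarch.data").joinpath("ss_segments.json").read_text())
    if protein not in data:
        raise KeyError(
            f"no ss_segments entry for {protein!r}; available: {sorted(data)}")
    return {k: (int(v[0]), int(v[1])) for k, v in data[protein].items()}
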