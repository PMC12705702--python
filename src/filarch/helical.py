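"""Screw-axis mathematics for helical filaments.

A helical filament is generated from one protomer by repeated application of
a screw operator: rotation by the *twist* (degrees per subunit) about the
filament axis composed with translation by the *rise* (Å per subunit) along
it. This module builds filaments from parameters, decomposes rigid
transforms into screw form, and estimates helical parameters from an ordered
assembly by Kabsch superposition of consecutive subunits.

Sign conventions
----------------
The axis direction is chosen so that the rise from subunit k to k+1 is
positive; positive twist then means a right-handed screw about the axis
(the convention of helical cryo-EM reconstruction: rotation + rise per
subunit). Twist is reported in (-180°, 180°]. With an n-fold axial point
group (cn > 1) the level-to-level twist is only defined modulo 360/cn; the
representative of smallest magnitude is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .structures import (
    DegenerateGeometryError,
    FilamentAssembly,
    ProtomerStructure,
)

__all__ = [
    "HelicalParams",
    "RigidTransform",
    "UndefinedAxisError",
    "NonHelicalError",
    "screw_from_params",
    "screw_decompose",
    "build_filament",
    "estimate_params",
    "kabsch",
    "wrap_angle",
]


class UndefinedAxisError(ValueError):
    """A (near-)pure translation has no unique screw axis."""


class NonHelicalError(ValueError):
    """Consecutive-subunit transforms are too inconsistent to be one helix."""


def wrap_angle(deg: float) -> float:
    """Wrap an angle in degrees to (-180, 180]."""
    a = (float(deg) + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


@dataclass(frozen=True)
class HelicalParams:
    """Helical symmetry description.

    Parameters
    ----------
    twist_deg:
        Rotation per subunit along the 1-start helix, degrees. Positive =
        right-handed screw about the axis.
    rise_A:
        Axial translation per subunit, Å (> 0 by convention).
    cn:
        Axial point-group order (1 = no rotational symmetry).
    n_start:
        Descriptive strand count: the number of interleaved helical strands
        the lattice is naturally read as. Not an independent degree of
        freedom; derived from twist/rise and the protomer size.
    """

    twist_deg: float
    rise_A: float
    cn: int = 1
    n_start: int = 1

    def __post_init__(self) -> None:
        if not (self.rise_A > 0):
            raise ValueError(f"rise must be positive, got {self.rise_A}")
        if not (0 < abs(self.twist_deg) <= 360):
            raise ValueError(f"twist must satisfy 0 < |twist| <= 360, got {self.twist_deg}")
        if self.cn < 1:
            raise ValueError(f"cn must be >= 1, got {self.cn}")
        if self.n_start < 1:
            raise ValueError(f"n_start must be >= 1, got {self.n_start}")

    @property
    def handedness(self) -> str:
        return "right" if wrap_angle(self.twist_deg) >= 0 else "left"


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body transform p -> R p + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, float)
        t = np.asarray(self.translation, float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or np.linalg.det(R) < 0:
            raise ValueError("rotation must be orthonormal with determinant +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other (apply ``other`` first)."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def power(self, n: int) -> "RigidTransform":
        out = RigidTransform(np.eye(3), np.zeros(3))
        base = self
        if n < 0:
            base = self.inverse()
            n = -n
        for _ in range(n):
            out = base.compose(out)
        return out

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)


def _axis_rotation(angle_deg: float, direction: np.ndarray) -> np.ndarray:
    return Rotation.from_rotvec(np.deg2rad(angle_deg) * np.asarray(direction, float)).as_matrix()


def screw_from_params(params: HelicalParams,
                      axis_origin: np.ndarray = (0.0, 0.0, 0.0),
                      axis_direction: np.ndarray = (0.0, 0.0, 1.0)) -> RigidTransform:
    """Screw operator relating subunit k to k+1.

    Rotation by ``twist_deg`` about the line through ``axis_origin`` along
    ``axis_direction``, composed with translation ``rise_A`` along the axis.
    """
    o = np.asarray(axis_origin, float)
    d = np.asarray(axis_direction, float)
    nrm = np.linalg.norm(d)
    if nrm < 1e-12:
        raise DegenerateGeometryError("axis direction has zero length")
    d = d / nrm
    R = _axis_rotation(params.twist_deg, d)
    t = o - R @ o + params.rise_A * d
    return RigidTransform(R, t)


def screw_decompose(t: RigidTransform, angle_tol_deg: float = 1e-4
                    ) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Decompose a rigid transform into screw form.

    Returns ``(twist_deg, rise_A, axis_direction, axis_point)`` with the axis
    direction flipped if needed so the rise is non-negative (twist sign
    follows the flip). The axis point is the point on the screw axis closest
    to the origin.

    Raises
    ------
    UndefinedAxisError
        If the rotation angle is below ``angle_tol_deg`` (a pure translation
        has no unique screw axis).
    """
    rot = Rotation.from_matrix(t.rotation)
    rotvec = rot.as_rotvec()
    angle = float(np.rad2deg(np.linalg.norm(rotvec)))
    if angle < angle_tol_deg:
        raise UndefinedAxisError(
            f"rotation angle {angle:.2e}° below tolerance; screw axis undefined")
    axis = rotvec / np.linalg.norm(rotvec)
    rise = float(np.dot(t.translation, axis))
    twist = angle
    if rise < 0:
        axis = -axis
        rise = -rise
        twist = -twist
    twist = wrap_angle(twist)
    # Point on axis: solve (I - R) p = t_perp in the plane perpendicular to axis.
    t_perp = t.translation - np.dot(t.translation, axis) * axis
    A = np.eye(3) - t.rotation
    p, *_ = np.linalg.lstsq(A, t_perp, rcond=None)
    p = p - np.dot(p, axis) * axis  # closest point on the axis to the origin
    return twist, rise, axis, p


def build_filament(protomer: ProtomerStructure, params: HelicalParams,
                   n_subunits: int,
                   axis_origin: np.ndarray = (0.0, 0.0, 0.0),
                   axis_direction: np.ndarray = (0.0, 0.0, 1.0)) -> FilamentAssembly:
    """Generate a filament by repeated application of the screw operator.

    Subunit at level k (k = 0 … n_levels-1) is the protomer transformed by
    the k-th power of the screw; for ``cn > 1`` each level is additionally
    replicated by rotations of 360/cn about the axis, and ``n_subunits`` must
    be divisible by ``cn``. Protomers are ordered level-major, within a level
    by the point-group copy index.
    """
    if n_subunits < 1:
        raise ValueError(f"n_subunits must be >= 1, got {n_subunits}")
    if params.cn > 1 and n_subunits % params.cn:
        raise ValueError(
            f"n_subunits={n_subunits} not divisible by cn={params.cn}")
    o = np.asarray(axis_origin, float)
    d = np.asarray(axis_direction, float)
    d = d / np.linalg.norm(d)
    screw = screw_from_params(params, o, d)
    protomers: list[ProtomerStructure] = []
    n_levels = n_subunits // params.cn
    for k in range(n_levels):
        tk = screw.power(k)
        for c in range(params.cn):
            Rc = _axis_rotation(360.0 * c / params.cn, d)
            ring = RigidTransform(Rc, o - Rc @ o)
            tf = ring.compose(tk)
            protomers.append(protomer.transformed(
                tf.rotation, tf.translation,
                label=f"{protomer.label or 'sub'}_{k * params.cn + c}"))
    return FilamentAssembly(protomers=protomers, axis_origin=o,
                            axis_direction=d, params=params)


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of point set P onto Q.

    Returns the transform minimizing ``|R P + t - Q|`` and the RMSD after
    superposition. Uses the quaternion/SVD solver from scipy.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must be matched (n, 3) arrays")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    rot, rssd = Rotation.align_vectors(Q - cq, P - cp)
    R = rot.as_matrix()
    t = cq - R @ cp
    rmsd = float(rssd / math.sqrt(len(P)))
    return RigidTransform(R, t), rmsd


def _matched_coords(a: ProtomerStructure, b: ProtomerStructure) -> tuple[np.ndarray, np.ndarray]:
    """Cα (or fallback heavy-atom) coordinates over residues shared by a and b."""
    ca, cb = a.ca_coords(), b.ca_coords()
    shared = [r for r in ca if r in cb]
    if len(shared) < 3:
        raise ValueError("fewer than 3 matched residues for superposition")
    return (np.array([ca[r] for r in shared]), np.array([cb[r] for r in shared]))


def _group_levels(z: np.ndarray, tol: float) -> list[list[int]]:
    """Group indices by axial coordinate within ``tol`` (z is sorted order agnostic)."""
    order = np.argsort(z)
    groups: list[list[int]] = []
    for i in order:
        if groups and z[i] - z[groups[-1][0]] <= tol:
            groups[-1].append(int(i))
        else:
            groups.append([int(i)])
    return groups


def estimate_params(filament: FilamentAssembly,
                    spread_tol_deg: float = 5.0,
                    spread_tol_rise: float = 1.0) -> HelicalParams:
    """Estimate helical parameters from an ordered assembly.

    Consecutive levels are superposed by Kabsch over matched Cα (fallback:
    heavy) atoms; each transform is screw-decomposed and the median twist and
    rise are returned. An axial point group cn > 1 is detected from co-level
    rings (equal protomer counts per level with equally spaced azimuths); the
    strand count ``n_start`` is reported descriptively (see
    :func:`descriptive_n_start`).

    Raises
    ------
    NonHelicalError
        If the spread of consecutive twists (or rises) exceeds the tolerance.
    """
    if len(filament) < 3:
        raise ValueError("need >= 3 ordered protomers to estimate parameters")
    z = filament.axial_coords()
    # Detect co-level rings -> cn.
    extent = filament.protomer_axial_extent()
    levels = _group_levels(z, tol=max(1e-6, 0.05 * extent))
    sizes = {len(g) for g in levels}
    cn = 1
    if sizes == {min(sizes)} and min(sizes) > 1:
        m = min(sizes)
        if _rings_are_symmetric(filament, levels, m):
            cn = m
    # One representative per level, in axial order; strands within a ring are
    # related by the point group, so any consistent representative works.
    reps = [g[0] for g in levels] if cn > 1 else list(np.argsort(z))
    twists, rises, axes = [], [], []
    for a, b in zip(reps[:-1], reps[1:]):
        P, Q = _matched_coords(filament[a], filament[b])
        tf, _ = kabsch(P, Q)
        try:
            tw, ri, ax, _ = screw_decompose(tf)
        except UndefinedAxisError:
            continue
        if cn > 1:
            period = 360.0 / cn
            if twists:
                # align to the first pair's representative: ring copies are
                # equivalent modulo the period, so measured twists may differ
                # by multiples of it (and flap in sign at the half-period).
                tw = twists[0] + _min_mod_representative(tw - twists[0], period)
            else:
                tw = _min_mod_representative(tw, period)
        twists.append(tw)
        rises.append(ri)
        axes.append(ax)
    if not twists:
        raise NonHelicalError("no consecutive pair produced a screw transform")
    twists_arr, rises_arr = np.array(twists), np.array(rises)
    if (np.ptp(twists_arr) > spread_tol_deg) or (np.ptp(rises_arr) > spread_tol_rise):
        raise NonHelicalError(
            f"consecutive transforms inconsistent: twist spread "
            f"{np.ptp(twists_arr):.2f}°, rise spread {np.ptp(rises_arr):.2f} Å")
    twist = float(np.median(twists_arr))
    rise = float(np.median(rises_arr))
    n_start = descriptive_n_start(twist, rise, extent, cn)
    return HelicalParams(twist_deg=twist, rise_A=rise, cn=cn, n_start=n_start)


def _min_mod_representative(twist: float, period: float) -> float:
    """Smallest-magnitude representative of ``twist`` modulo ``period``."""
    t = twist % period
    if t > period / 2:
        t -= period
    return t


def _rings_are_symmetric(filament: FilamentAssembly, levels: list[list[int]],
                         m: int, tol_deg: float = 5.0) -> bool:
    """True if every co-level ring of size m has equally spaced azimuths."""
    for g in levels:
        az = sorted(np.rad2deg(filament.azimuth(filament[i].centroid)) for i in g)
        gaps = np.diff(az + [az[0] + 360.0])
        if np.any(np.abs(gaps - 360.0 / m) > tol_deg):
            return False
    return True


def descriptive_n_start(twist_deg: float, rise_A: float,
                        protomer_extent_A: float, cn: int = 1) -> int:
    """Strand count the lattice is naturally read as.

    With cn-fold symmetry, co-level neighbors sit at 360/cn, giving
    ``n_start = cn``-interleaved strands at minimum. Without exact co-level
    neighbors, the lattice is read as d strands where the subunit offset d
    (within axial contact range: one protomer height plus the contact
    cutoff) minimizes the residual azimuth ``|d·twist mod 360|``: subunits k
    and k+d then stack most nearly on top of one another. Reported
    descriptively; returns 1 when no offset beats the 1-start residual.
    """
    if cn > 1:
        return cn
    d_max = max(1, int((protomer_extent_A + 4.5) // rise_A))
    best_d, best_res = 1, abs(wrap_angle(twist_deg))
    for d in range(2, d_max + 1):
        res = abs(wrap_angle(d * twist_deg))
        if res < best_res:
            best_d, best_res = d, res
    return best_d
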