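"""Cross-threading compatibility of a monomer with a filament lattice.

The honeycomb of a filament — a center protomer plus the six shell contacts
— is a template into which a homologous monomer can be rigidly threaded:
superposed onto the center over a residue correspondence, with no backbone
remodeling or side-chain repacking. Each shell interface is then scored by a
transparent steric term,

    score = w_clash * (heavy-atom pairs closer than the clash threshold)
          - w_contact * (non-clashing heavy-atom pairs within the contact cutoff)

so lower is more favorable. The score is a stand-in for physics-based
interface energies: only its sign and the orderings it induces (self vs
cross-threaded, one template vs another) are meaningful, not its magnitude.
Top-half and bottom-half sums mirror the two axial growth directions of the
filament.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .helical import RigidTransform, kabsch
from .lattice import (
    CONTACT_CUTOFF_A,
    HoneycombNeighborhood,
    IncompleteShellError,
    InterfaceRecord,
)
from .structures import ProtomerStructure

__all__ = [
    "CLASH_THRESHOLD_A",
    "W_CLASH",
    "W_CONTACT",
    "CompatibilityReport",
    "InsufficientCorrespondenceError",
    "sequence_mapping",
    "identity_mapping",
    "thread_monomer",
    "score_shell",
    "swap_center_analysis",
    "compare_honeycombs",
    "align_monomers",
]

#: Heavy-atom distance below which a pair counts as a steric clash, Å.
CLASH_THRESHOLD_A = 2.6
#: Score weights: one clash costs w_clash; one favorable contact earns w_contact.
W_CLASH = 10.0
W_CONTACT = 1.0


class InsufficientCorrespondenceError(ValueError):
    """The residue mapping covers too little of the alignable core."""


# ---------------------------------------------------------------------------
# Residue correspondences
# ---------------------------------------------------------------------------

def identity_mapping(p: ProtomerStructure) -> list[tuple[int, int]]:
    """Self-correspondence: every residue mapped to itself."""
    return [(r, r) for r in p.residue_numbers]


def sequence_mapping(a: ProtomerStructure, b: ProtomerStructure
                     ) -> list[tuple[int, int]]:
    """Residue correspondence from a global sequence alignment.

    Needleman–Wunsch with BLOSUM62, gap open 10 / extend 1, between the
    protomer sequences; returns aligned (a_residue, b_residue) pairs in
    author numbering. Use a hand-curated mapping instead when the proteins
    are too diverged for a meaningful global alignment.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    if not a.sequence or not b.sequence:
        raise ValueError("both protomers need sequences for alignment")
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    aln = aligner.align(a.sequence, b.sequence)[0]
    res_a = a.residue_numbers
    res_b = b.residue_numbers
    pairs: list[tuple[int, int]] = []
    for (sa, ea), (sb, eb) in zip(aln.aligned[0], aln.aligned[1]):
        for i, j in zip(range(sa, ea), range(sb, eb)):
            pairs.append((res_a[i], res_b[j]))
    return pairs


def _mapped_ca(a: ProtomerStructure, b: ProtomerStructure,
               mapping: list[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    ca_a, ca_b = a.ca_coords(), b.ca_coords()
    kept = [(ra, rb) for ra, rb in mapping if ra in ca_a and rb in ca_b]
    P = np.array([ca_a[ra] for ra, _ in kept])
    Q = np.array([ca_b[rb] for _, rb in kept])
    return P, Q, kept


# ---------------------------------------------------------------------------
# Threading and scoring
# ---------------------------------------------------------------------------

def thread_monomer(monomer: ProtomerStructure,
                   template: HoneycombNeighborhood,
                   mapping: list[tuple[int, int]] | None = None,
                   min_coverage: float = 0.6) -> ProtomerStructure:
    """Rigidly place ``monomer`` onto the template's center subunit.

    The monomer is superposed over mapped Cα atoms (Kabsch); nothing else is
    changed — no remodeling, no repacking. ``mapping`` is a list of
    ``(monomer_residue, center_residue)`` pairs; by default a sequence
    alignment is computed. The mapping must cover at least ``min_coverage``
    of the template-center residues (the alignable core).
    """
    center = template.center
    if mapping is None:
        mapping = sequence_mapping(monomer, center)
    P, Q, kept = _mapped_ca(monomer, center, mapping)
    coverage = len(kept) / max(1, len(center.residue_numbers))
    if coverage < min_coverage:
        raise InsufficientCorrespondenceError(
            f"mapping covers {coverage:.0%} of center residues "
            f"(< {min_coverage:.0%})")
    tf, _ = kabsch(P, Q)
    return monomer.transformed(tf.rotation, tf.translation,
                               label=f"{monomer.label}@{center.label}")


@dataclass
class CompatibilityReport:
    """Per-interface steric scores for a monomer threaded into a honeycomb.

    ``per_interface`` maps ``"<type>|<half>"`` (e.g. ``"3a:3b|top"``) to a
    dict with ``clash_count``, ``contact_count`` and ``score``. Half sums
    partition the total exactly.
    """

    threaded_monomer: str
    template: str
    per_interface: dict[str, dict] = field(default_factory=dict)
    half_sums: dict[str, float] = field(default_factory=dict)
    total: float = 0.0
    clash_threshold: float = CLASH_THRESHOLD_A
    contact_cutoff: float = CONTACT_CUTOFF_A
    w_clash: float = W_CLASH
    w_contact: float = W_CONTACT

    @property
    def total_clashes(self) -> int:
        return sum(v["clash_count"] for v in self.per_interface.values())

    def clashes_by_type(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for key, v in self.per_interface.items():
            t = key.split("|")[0]
            out[t] = out.get(t, 0) + v["clash_count"]
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "threaded_monomer": self.threaded_monomer,
            "template": self.template,
            "per_interface": self.per_interface,
            "half_sums": self.half_sums,
            "total": self.total,
            "parameters": {
                "clash_threshold_A": self.clash_threshold,
                "contact_cutoff_A": self.contact_cutoff,
                "w_clash": self.w_clash,
                "w_contact": self.w_contact,
            },
        }
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(interface=k, **v) for k, v in sorted(self.per_interface.items())]
        return pd.DataFrame(rows)


def _steric_counts(a_coords: np.ndarray, b_coords: np.ndarray,
                   clash: float, cutoff: float) -> tuple[int, int]:
    """(clash pairs, non-clashing contact pairs) between two heavy-atom sets."""
    tree = cKDTree(b_coords)
    ta = cKDTree(a_coords)
    n_within = ta.count_neighbors(tree, cutoff)
    n_clash = ta.count_neighbors(tree, clash)
    return int(n_clash), int(n_within - n_clash)


def score_shell(threaded: ProtomerStructure,
                template: HoneycombNeighborhood,
                shell_source: str = "template",
                mapping: list[tuple[int, int]] | None = None,
                clash_threshold: float = CLASH_THRESHOLD_A,
                contact_cutoff: float = CONTACT_CUTOFF_A,
                w_clash: float = W_CLASH,
                w_contact: float = W_CONTACT) -> CompatibilityReport:
    """Score a positioned monomer against every shell interface.

    ``shell_source`` selects what the monomer is scored against:
    ``"template"`` keeps the template's own shell protomers (center-subunit
    replacement, the receptor-shell experiment); ``"threaded"`` replaces each
    shell protomer by the monomer threaded onto it (a homo-filament modeled
    on a foreign lattice). For ``"threaded"`` a mapping is required unless
    the sequences align.
    """
    if not template.shell:
        raise IncompleteShellError("template has an empty shell")
    per: dict[str, dict] = {}
    half_sums = {"top": 0.0, "bottom": 0.0}
    thr_coords = np.array([a.position for a in threaded.heavy_atoms()])
    for rec in sorted(template.shell, key=lambda r: r.partner_offset):
        partner = rec.partner
        if shell_source == "threaded":
            partner = _thread_onto(threaded, rec, template, mapping)
        elif shell_source != "template":
            raise ValueError("shell_source must be 'template' or 'threaded'")
        p_coords = np.array([a.position for a in partner.heavy_atoms()])
        n_clash, n_contact = _steric_counts(thr_coords, p_coords,
                                            clash_threshold, contact_cutoff)
        score = w_clash * n_clash - w_contact * n_contact
        key = rec.key if rec.type_label else f"offset{rec.partner_offset:+d}|{rec.half}"
        if key in per:  # duplicate labels (degenerate typing): keep both records
            key = f"{key}@{rec.partner_offset:+d}"
        per[key] = {
            "partner_offset": rec.partner_offset,
            "clash_count": n_clash,
            "contact_count": n_contact,
            "score": score,
        }
        half_sums[rec.half] += score
    return CompatibilityReport(
        threaded_monomer=threaded.label, template=template.center.label or "template",
        per_interface=per, half_sums=half_sums,
        total=half_sums["top"] + half_sums["bottom"],
        clash_threshold=clash_threshold, contact_cutoff=contact_cutoff,
        w_clash=w_clash, w_contact=w_contact)


def _thread_onto(monomer: ProtomerStructure, rec: InterfaceRecord,
                 template: HoneycombNeighborhood,
                 mapping: list[tuple[int, int]] | None) -> ProtomerStructure:
    """Thread the (already center-positioned) monomer onto a shell position."""
    if mapping is None:
        mapping = sequence_mapping(monomer, rec.partner)
    P, Q, kept = _mapped_ca(monomer, rec.partner, mapping)
    if len(kept) < 3:
        raise InsufficientCorrespondenceError(
            f"cannot thread onto shell position {rec.partner_offset:+d}")
    tf, _ = kabsch(P, Q)
    return monomer.transformed(tf.rotation, tf.translation)


def swap_center_analysis(adapter: ProtomerStructure,
                         receptor_honeycomb: HoneycombNeighborhood,
                         mapping: list[tuple[int, int]] | None = None,
                         **score_kwargs) -> CompatibilityReport:
    """Replace the honeycomb's center subunit by a homologous adapter.

    Composition of :func:`thread_monomer` and :func:`score_shell` with the
    template's own shell — the downstream-adapter-in-upstream-receptor-shell
    experiment. Lower totals mean the adapter fits that receptor's lattice
    better.
    """
    threaded = thread_monomer(adapter, receptor_honeycomb, mapping)
    return score_shell(threaded, receptor_honeycomb, shell_source="template",
                       **score_kwargs)


# ---------------------------------------------------------------------------
# Honeycomb and monomer comparisons
# ---------------------------------------------------------------------------

def compare_honeycombs(a: HoneycombNeighborhood, b: HoneycombNeighborhood,
                       mapping: list[tuple[int, int]] | None = None
                       ) -> pd.DataFrame:
    """Overlay two honeycombs at their centers and tabulate shell deviations.

    ``b`` is superposed onto ``a`` over the centers' mapped Cα atoms; shell
    positions are then matched by interface label when both shells are
    typed, else by partner offset. Returns one row per matched position with
    the centroid displacement (Å) and relative orientation difference
    (degrees); unmatched positions get NaN displacements rather than an
    error.
    """
    if mapping is None:
        mapping = sequence_mapping(b.center, a.center)
    P, Q, kept = _mapped_ca(b.center, a.center, mapping)
    if len(kept) < 3:
        raise InsufficientCorrespondenceError("centers share too few residues")
    tf, center_rmsd = kabsch(P, Q)

    # Match by interface label only when labels are unique within each
    # shell; degenerate or untyped shells fall back to lattice offsets.
    def keys_of(shell):
        return [r.key for r in shell]

    by_label = (all(r.type_label for r in a.shell + b.shell)
                and len(set(keys_of(a.shell))) == len(a.shell)
                and len(set(keys_of(b.shell))) == len(b.shell))

    def match_key(rec: InterfaceRecord) -> str:
        return rec.key if by_label else f"offset{rec.partner_offset:+d}"

    b_by_key = {match_key(r): r for r in b.shell}
    rows = []
    for ra in sorted(a.shell, key=lambda r: r.partner_offset):
        key = match_key(ra)
        rb = b_by_key.pop(key, None)
        if rb is None:
            rows.append(dict(position=key, offset_a=ra.partner_offset,
                             offset_b=None, centroid_displacement_A=np.nan,
                             orientation_diff_deg=np.nan))
            continue
        pb = rb.partner.transformed(tf.rotation, tf.translation)
        disp = float(np.linalg.norm(pb.centroid - ra.partner.centroid))
        ori = _orientation_difference(ra.partner, pb, mapping)
        rows.append(dict(position=key, offset_a=ra.partner_offset,
                         offset_b=rb.partner_offset,
                         centroid_displacement_A=disp,
                         orientation_diff_deg=ori))
    for key, rb in b_by_key.items():
        rows.append(dict(position=key, offset_a=None, offset_b=rb.partner_offset,
                         centroid_displacement_A=np.nan,
                         orientation_diff_deg=np.nan))
    df = pd.DataFrame(rows)
    df.attrs["center_rmsd_A"] = center_rmsd
    return df


def _orientation_difference(pa: ProtomerStructure, pb: ProtomerStructure,
                            mapping: list[tuple[int, int]]) -> float:
    """Angle (deg) of the rotation relating two placed copies of homologs."""
    # mapping is b-residue -> a-residue; orientation uses the same pairs.
    P, Q, kept = _mapped_ca(pb, pa, mapping)
    if len(kept) < 3:
        return float("nan")
    tf, _ = kabsch(P, Q)
    from scipy.spatial.transform import Rotation
    ang = Rotation.from_matrix(tf.rotation).magnitude()
    return float(np.rad2deg(ang))


def align_monomers(a: ProtomerStructure, b: ProtomerStructure,
                   mapping: list[tuple[int, int]] | None = None,
                   trim: bool = False,
                   min_pairs: int = 30,
                   sigma_factor: float = 2.0,
                   max_rounds: int = 5
                   ) -> tuple[float, RigidTransform, float]:
    """Kabsch superposition of monomer ``a`` onto ``b`` over mapped Cα.

    With ``trim``, pairs whose residual exceeds ``sigma_factor`` standard
    deviations are discarded iteratively (at most ``max_rounds`` rounds,
    stopping when the retained set is stable or would drop below
    ``min_pairs``) — a core superposition that ignores diverged loops.
    Returns ``(rmsd, transform, retained_fraction)``.
    """
    if mapping is None:
        mapping = sequence_mapping(a, b)
    P, Q, kept = _mapped_ca(a, b, mapping)
    if len(kept) < min_pairs:
        raise InsufficientCorrespondenceError(
            f"only {len(kept)} mapped residue pairs (< {min_pairs})")
    keep = np.ones(len(P), dtype=bool)
    tf, rmsd = kabsch(P, Q)
    if trim:
        for _ in range(max_rounds):
            resid = np.linalg.norm(tf.apply(P[keep]) - Q[keep], axis=1)
            thresh = sigma_factor * np.sqrt(np.mean(resid ** 2))
            new_keep = keep.copy()
            new_keep[np.where(keep)[0][resid > thresh]] = False
            if new_keep.sum() < min_pairs or new_keep.sum() == keep.sum():
                break
            keep = new_keep
            tf, rmsd = kabsch(P[keep], Q[keep])
    return rmsd, tf, float(keep.sum() / len(P))
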