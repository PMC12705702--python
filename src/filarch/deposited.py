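"""Analysis pipeline for deposited filament models.

Convenience wrappers that fetch a PDB accession, rebuild the filament frame,
and run the lattice and cross-threading analyses exactly as they run on
synthetic fixtures. Everything here needs network access to the PDB archive
on first use; downloaded files are cached in ``dest_dir``.
"""

from __future__ import annotations

from pathlib import Path

from .compat import align_monomers, score_shell, sequence_mapping, thread_monomer
from .fetch import fetch_pdb
from .io import order_protomers, read_structure
from .lattice import CONTACT_CUTOFF_A, extract_honeycomb, IncompleteShellError
from .structures import FilamentAssembly, ProtomerStructure

__all__ = [
    "load_deposited_filament",
    "deposited_monomer",
    "interior_honeycomb",
    "core_rmsd",
    "homo_threading_total",
    "adapter_swap_total",
]


def load_deposited_filament(accession: str, dest_dir: str | Path = "structures",
                            ss_segments: dict | None = None) -> FilamentAssembly:
    """Fetch an accession and order its chains along the 1-start helix."""
    path = fetch_pdb(accession, dest_dir)
    chains = read_structure(path, ss_segments=ss_segments)
    return order_protomers(chains)


def deposited_monomer(accession: str, dest_dir: str | Path = "structures"
                      ) -> ProtomerStructure:
    """First polymer chain of a deposited model."""
    path = fetch_pdb(accession, dest_dir)
    return read_structure(path)[0]


def interior_honeycomb(filament: FilamentAssembly,
                       cutoff: float = CONTACT_CUTOFF_A):
    """Most central protomer with a complete shell."""
    mid = len(filament) // 2
    last_err: Exception | None = None
    for delta in range(len(filament) // 2 + 1):
        for c in (mid - delta, mid + delta):
            if 0 <= c < len(filament):
                try:
                    return extract_honeycomb(filament, c, cutoff,
                                             classify=bool(filament[c].ss_segments))
                except IncompleteShellError as err:
                    last_err = err
    raise last_err or IncompleteShellError("no interior protomer found")


def core_rmsd(a: ProtomerStructure, b: ProtomerStructure) -> float:
    """Core-trimmed Cα RMSD between two homologous monomers (Å)."""
    rmsd, _, _ = align_monomers(a, b, sequence_mapping(a, b), trim=True)
    return rmsd


def homo_threading_total(monomer: ProtomerStructure, template: FilamentAssembly,
                         cutoff: float = CONTACT_CUTOFF_A):
    """Model a homo-filament of ``monomer`` on a foreign template lattice.

    Threads the monomer onto the template's center and scores it against
    copies of itself threaded onto every shell position. Returns the
    compatibility report.
    """
    neigh = interior_honeycomb(template, cutoff)
    mapping = sequence_mapping(monomer, neigh.center)
    threaded = thread_monomer(monomer, neigh, mapping)
    return score_shell(threaded, neigh, "threaded", mapping)


def adapter_swap_total(adapter: ProtomerStructure, receptor: FilamentAssembly,
                       cutoff: float = CONTACT_CUTOFF_A):
    """Replace a receptor honeycomb's center with an adapter; score the shell."""
    neigh = interior_honeycomb(receptor, cutoff)
    mapping = sequence_mapping(adapter, neigh.center)
    threaded = thread_monomer(adapter, neigh, mapping)
    return score_shell(threaded, neigh, "template", mapping)
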