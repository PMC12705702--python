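"""Download deposited coordinate files from the PDB.

Used by the deposited-model validation path; the rest of the package is
fully functional offline on synthetic fixtures.
"""

from __future__ import annotations

import urllib.request
from pathlib import Path

__all__ = ["fetch_pdb", "RCSB_URL"]

RCSB_URL = "https://files.rcsb.org/download/{accession}.cif"


def fetch_pdb(accession: str, dest_dir: str | Path = ".",
              timeout: float = 30.0, overwrite: bool = False) -> Path:
    """Fetch the mmCIF coordinate file for a PDB accession.

    Returns the local path; reuses an existing file unless ``overwrite``.
    Raises ``urllib.error.URLError`` (or a subclass) when the archive is
    unreachable — callers decide whether that is fatal.
    """
    accession = accession.lower()
    if not (len(accession) == 4 and accession[0].isdigit()):
        raise ValueError(f"{accession!r} is not a PDB accession")
    dest = Path(dest_dir) / f"{accession}.cif"
    if dest.exists() and not overwrite:
        return dest
    dest.parent.mkdir(parents=True, exist_ok=True)
    url = RCSB_URL.format(accession=accession)
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        data = resp.read()
    dest.write_bytes(data)
    return dest
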