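"""Report assembly: tidy CSV/JSON outputs and the honeycomb SVG diagram."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .compat import CompatibilityReport
from .lattice import HoneycombNeighborhood

__all__ = ["honeycomb_frame", "write_json", "honeycomb_svg"]


def honeycomb_frame(neigh: HoneycombNeighborhood) -> pd.DataFrame:
    """One tidy row per shell interface."""
    rows = []
    for r in sorted(neigh.shell, key=lambda r: r.partner_offset):
        rows.append(dict(
            partner_offset=r.partner_offset,
            half=r.half,
            type_label=r.type_label,
            center_side=r.center_side,
            ambiguous=r.ambiguous,
            contact_count=r.contact_count,
            min_distance_A=round(r.min_distance, 3),
            n_residue_pairs=len(r.residue_pairs),
        ))
    return pd.DataFrame(rows)


def write_json(doc: dict, path: str | Path) -> None:
    """Deterministic JSON: sorted keys, fixed float formatting via round."""
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


# Fixed layout mirroring the honeycomb diagram: center plus six hexagon
# positions, top half above, bottom half below.
_POSITIONS = {
    "top": [(0.5, 0.22), (0.22, 0.36), (0.78, 0.36)],
    "bottom": [(0.22, 0.64), (0.78, 0.64), (0.5, 0.78)],
}


def honeycomb_svg(report: CompatibilityReport, path: str | Path | None = None,
                  width: int = 460, height: int = 420) -> str:
    """Render a compatibility report as a honeycomb diagram (SVG text).

    The center cell names the threaded monomer; each shell cell shows its
    interface label and score; half sums appear beside the two halves.
    """

    def cell(x, y, label, value=None, fill="#e8eef7"):
        r = 52
        pts = []
        for k in range(6):
            import math
            ang = math.pi / 180 * (60 * k - 30)
            pts.append(f"{x + r * math.cos(ang):.1f},{y + r * math.sin(ang):.1f}")
        svg = [f'<polygon points="{" ".join(pts)}" fill="{fill}" stroke="#333"/>']
        svg.append(f'<text x="{x}" y="{y - 6}" text-anchor="middle" '
                   f'font-size="12">{label}</text>')
        if value is not None:
            svg.append(f'<text x="{x}" y="{y + 12}" text-anchor="middle" '
                       f'font-size="12" font-weight="bold">{value:g}</text>')
        return svg

    parts = [f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
             f'height="{height}" font-family="sans-serif">']
    cx, cy = width / 2, height / 2
    parts += cell(cx, cy, report.threaded_monomer or "center", fill="#f7e8c8")
    by_half: dict[str, list] = {"top": [], "bottom": []}
    for key, v in sorted(report.per_interface.items()):
        by_half[key.split("|")[1]].append((key.split("|")[0], v["score"]))
    for half, slots in _POSITIONS.items():
        for (label, score), (fx, fy) in zip(by_half[half], slots):
            parts += cell(fx * width, fy * height, label, score)
        parts.append(
            f'<text x="{width - 8}" y="{int(fy * height)}" text-anchor="end" '
            f'font-size="13">{half} sum: {report.half_sums[half]:g}</text>')
    parts.append(f'<text x="8" y="16" font-size="13">{report.threaded_monomer} '
                 f'in {report.template} shell — total {report.total:g}</text>')
    parts.append("</svg>")
    text = "\n".join(parts)
    if path is not None:
        Path(path).write_text(text)
    return text
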