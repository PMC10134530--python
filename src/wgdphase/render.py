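"""Static SVG visualization of a pillar window.

The layout mirrors a genome-browser view of double-conserved synteny: one
column per pillar, and for every genome two horizontal tracks — subgenome 1
on top, subgenome 2 below.  Gene boxes are coloured by the pillar's decoded
category (fully duplicated, single-copy on the favoured or the disfavoured
subgenome, reciprocal loss, or a mixture), and the orthology confidence,
rounded to one decimal, is printed above each column.  Output is plain SVG
assembled as text, byte-identical across reruns of the same input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

from .datamodel import PillarSet
from .errors import ValidationError
from .hmm import (
    DUPLICATED,
    MIXED,
    RECIPROCAL_LOSS,
    SINGLE_SUB1,
    SINGLE_SUB2,
    PosteriorTable,
    classify_pillar,
)

# Category fill colours (approximate browser scheme: light pink = retained
# duplicates, dark pink = reciprocal loss, tan = mixed, blue = single-copy on
# the less fractionated subgenome 1, green = the more fractionated subgenome 2)
CATEGORY_COLORS: Dict[str, str] = {
    DUPLICATED: "#f4b6c2",
    RECIPROCAL_LOSS: "#d4668c",
    MIXED: "#d2b48c",
    SINGLE_SUB1: "#7da7d9",
    SINGLE_SUB2: "#7fbf7f",
}
ABSENT_COLOR = "#f0f0f0"

_BOX_W = 90
_BOX_H = 22
_COL_GAP = 8
_ROW_GAP = 4
_GENOME_GAP = 14
_MARGIN = 60
_HEADER = 30


@dataclass
class WindowSpec:
    """A window of pillars centred on one pillar."""

    center_pillar: int
    window_size: int = 11
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.window_size < 1 or self.window_size % 2 == 0:
            raise ValidationError("window_size must be a positive odd integer")
        if self.scale <= 0:
            raise ValidationError("scale must be positive")


def window_range(pillars: PillarSet, window: WindowSpec) -> Tuple[int, int]:
    """Half-open pillar range, clipped at list ends and block boundaries."""
    c = window.center_pillar
    if not 0 <= c < len(pillars):
        raise ValidationError(f"center pillar {c} out of range")
    half = window.window_size // 2
    lo, hi = c - half, c + half + 1
    block = pillars.pillars[c].block_id
    for start, end in pillars.block_bounds():
        if start <= c < end:
            lo, hi = max(lo, start), min(hi, end)
            break
    return max(lo, 0), min(hi, len(pillars))


def render_window(
    pillars: PillarSet,
    posterior: PosteriorTable,
    window: WindowSpec,
    out_path: str,
) -> str:
    """Write the window as an SVG file; returns the SVG text."""
    svg = render_window_svg(pillars, posterior, window)
    with open(out_path, "w") as fh:
        fh.write(svg)
    return svg


def render_window_svg(
    pillars: PillarSet, posterior: PosteriorTable, window: WindowSpec
) -> str:
    lo, hi = window_range(pillars, window)
    genomes = pillars.genomes
    n_cols = hi - lo
    n_rows = 2 * len(genomes)

    width = _MARGIN + n_cols * (_BOX_W + _COL_GAP) + _MARGIN
    height = (
        _HEADER
        + len(genomes) * (2 * _BOX_H + _ROW_GAP + _GENOME_GAP)
        + _MARGIN
    )
    parts: List[str] = []
    parts.append(
        f'<svg xmlns="http://www.w3.org/2000/svg" '
        f'width="{width * window.scale:.0f}" height="{height * window.scale:.0f}" '
        f'viewBox="0 0 {width} {height}">'
    )
    parts.append(
        '<style>text{font-family:monospace;font-size:10px}'
        ".conf{font-size:12px;text-anchor:middle}"
        ".gname{font-size:11px}</style>"
    )

    # genome row labels
    for gi, g in enumerate(genomes):
        y0 = _HEADER + gi * (2 * _BOX_H + _ROW_GAP + _GENOME_GAP)
        parts.append(
            f'<text class="gname" x="4" y="{y0 + _BOX_H + _ROW_GAP // 2 + 4}">'
            f"{_esc(g)}</text>"
        )

    for col, p_idx in enumerate(range(lo, hi)):
        pillar = pillars.pillars[p_idx]
        config = posterior.viterbi_config(p_idx)
        category = classify_pillar(pillar, config)
        color = CATEGORY_COLORS[category]
        conf = posterior.confidence[p_idx]
        x = _MARGIN + col * (_BOX_W + _COL_GAP)
        parts.append(
            f'<text class="conf" x="{x + _BOX_W // 2}" y="{_HEADER - 10}">'
            f"{conf:.1f}</text>"
        )
        for gi, g in enumerate(genomes):
            y0 = _HEADER + gi * (2 * _BOX_H + _ROW_GAP + _GENOME_GAP)
            for sub in (1, 2):
                track = config.track_of_subgenome(gi, sub)
                gid = pillar.slots.get(g, (None, None))[track]
                y = y0 if sub == 1 else y0 + _BOX_H + _ROW_GAP
                if gid is None:
                    parts.append(
                        f'<rect x="{x}" y="{y}" width="{_BOX_W}" '
                        f'height="{_BOX_H}" fill="{ABSENT_COLOR}" '
                        'stroke="none"/>'
                    )
                else:
                    parts.append(
                        f'<g><rect x="{x}" y="{y}" width="{_BOX_W}" '
                        f'height="{_BOX_H}" fill="{color}" stroke="#444"/>'
                        f"<title>{_esc(gid)} (pillar {p_idx}, subgenome {sub}, "
                        f"{category})</title>"
                        f'<text x="{x + 3}" y="{y + _BOX_H - 7}">'
                        f"{_esc(_clip(gid))}</text></g>"
                    )
    parts.append("</svg>")
    return "\n".join(parts) + "\n"


def _clip(gid: str, max_chars: int = 13) -> str:
    return gid if len(gid) <= max_chars else gid[: max_chars - 1] + "…"


def _esc(text: str) -> str:
    return (
        text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
    )
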