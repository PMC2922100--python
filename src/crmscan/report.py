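"""Plain-text track rendering of a detected regulatory module.

One track per species across the full region (-upstream .. +downstream
relative to the TSS), with a distance ruler on top, one glyph per member
binding site, and vertical bars demarcating the module window — followed by
an exact per-species listing of window coordinates and member sites.
"""

from __future__ import annotations

from typing import Mapping

from .discovery import ModuleWindow, RegulatoryModule

#: conventional single-character glyphs for the default families
FAMILY_GLYPHS = {
    "NEUR": "N",
    "HNF1": "1",
    "HNF6": "6",
    "BRNF": "B",
    "PDX1": "P",
    "LEFF": "L",
}
_FALLBACK_GLYPHS = "abcdefghijklmnopqrstuvwxyz"


def _glyph_map(families) -> dict[str, str]:
    glyphs = dict(FAMILY_GLYPHS)
    used = set(glyphs.values())
    fallback = iter(c for c in _FALLBACK_GLYPHS if c not in used)
    out = {}
    for fam in families:
        out[fam] = glyphs.get(fam) or next(fallback)
    return out


def _ruler(lo: int, hi: int, width: int) -> list[str]:
    span = hi - lo
    ticks = range(lo, hi + 1, 1000)
    line = [" "] * width
    marks = [" "] * width
    for t in ticks:
        col = round((t - lo) / span * (width - 1))
        marks[col] = "+"
        label = str(t)
        start = min(max(0, col - len(label) // 2), width - len(label))
        for i, ch in enumerate(label):
            line[start + i] = ch
    return ["".join(line), "".join(marks)]


def _place_glyph(track: list[str], col: int, glyph: str) -> None:
    # shift right to the next free column so every member site stays visible
    width = len(track)
    c = col
    while c < width and track[c] not in (".", "|"):
        c += 1
    if c >= width:
        c = col
        while c >= 0 and track[c] not in (".", "|"):
            c -= 1
    if 0 <= c < width:
        track[c] = glyph


def _track_line(window: ModuleWindow, lo: int, hi: int, width: int, glyphs) -> str:
    span = hi - lo
    track = ["."] * width

    def col(pos_rel_tss: int) -> int:
        return round((pos_rel_tss - lo) / span * (width - 1))

    for edge in (window.start_rel_tss, window.end_rel_tss):
        track[min(width - 1, max(0, col(edge)))] = "|"
    for h in window.members:
        _place_glyph(track, col(h.position_rel_tss), glyphs[h.family])
    return "".join(track)


def render_module_report(module: RegulatoryModule, width: int = 100) -> str:
    """Fig-style text rendering: ruler, per-species glyph tracks, exact
    member listings parseable back to the module JSON positions."""
    if not module.windows:
        raise ValueError("module has no windows to render")
    tss_offset = next(iter(module.windows.values())).tss_offset
    region_len = tss_offset + 500  # renderer assumes the default +500 downstream
    lo, hi = -tss_offset, region_len - tss_offset
    glyphs = _glyph_map(module.families)

    lines: list[str] = []
    lines.append(f"Regulatory module report: {module.gene_id or '(unnamed gene)'}")
    lines.append(
        f"families: {', '.join(sorted(module.families))}   "
        f"anchor: {module.anchor_family}   max span: {module.max_span} bp"
    )
    lines.append("legend: " + "  ".join(f"{g}={f}" for f, g in sorted(glyphs.items())))
    lines.append("")
    lines.extend(_ruler(lo, hi, width))
    for sp in sorted(module.windows):
        w = module.windows[sp]
        lines.append(_track_line(w, lo, hi, width, glyphs) + f"  {sp}")
    lines.append("")
    for sp in sorted(module.windows):
        w = module.windows[sp]
        members = " ".join(
            f"{h.family}@{h.position_rel_tss}({h.strand})" for h in w.members
        )
        lines.append(
            f"{sp}  window {w.start_rel_tss}..{w.end_rel_tss} rel TSS "
            f"(span {w.span} bp, distance {w.distance_from_tss} bp)  {members}"
        )
    return "\n".join(lines) + "\n"
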