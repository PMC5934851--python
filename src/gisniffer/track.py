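"""Scalable-vector-graphic track of a chromosome scan.

One linear panel per chromosome: called islands as pink blocks along the
coordinate axis and four statistic curves overlaid above it -- GC content
(black), the GRV/RV variance ratio (blue), the rank distance D to the
rolling reference pattern (red), and the strand pattern skew PS (green).
Each curve is drawn on its own vertical scale (GC on 0-1, D and PS on
0-100, the ratio on 0-max); the legend carries the conventional track
abbreviations (n0_4mer:D, n0_4mer:PS, n1_4mer:GRV/n1_4mer:RV).
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from typing import Optional, Sequence

from .detector import WindowStats

_SVG_NS = "http://www.w3.org/2000/svg"

WIDTH = 1000
HEIGHT = 320
MARGIN_LEFT = 60
MARGIN_RIGHT = 30
PLOT_TOP = 40
PLOT_HEIGHT = 200
AXIS_Y = PLOT_TOP + PLOT_HEIGHT + 20
ISLAND_Y = PLOT_TOP + PLOT_HEIGHT + 4
ISLAND_H = 12

CURVES = (
    # (attribute, colour, label, fixed (lo, hi) scale or None for 0..max)
    ("gc", "black", "GC", (0.0, 1.0)),
    ("grv_rv", "blue", "n1_4mer:GRV/n1_4mer:RV", None),
    ("d", "red", "n0_4mer:D", (0.0, 100.0)),
    ("ps", "green", "n0_4mer:PS", (0.0, 100.0)),
)


class TrackError(ValueError):
    pass


def _x_scale(x0: int, x1: int):
    span = max(1, x1 - x0)
    width = WIDTH - MARGIN_LEFT - MARGIN_RIGHT

    def to_px(pos: float) -> float:
        return MARGIN_LEFT + (pos - x0) / span * width

    return to_px


def render_track(
    stats: Sequence[WindowStats],
    islands: Sequence,
    out_path,
    title: Optional[str] = None,
) -> None:
    """Render the scan track to ``out_path`` as an SVG document."""
    if not stats:
        raise TrackError("cannot render a track from empty window statistics")
    x0 = stats[0].start
    x1 = max(w.end for w in stats)
    to_px = _x_scale(x0, x1)

    ET.register_namespace("", _SVG_NS)
    svg = ET.Element(
        f"{{{_SVG_NS}}}svg",
        {
            "width": str(WIDTH),
            "height": str(HEIGHT),
            "viewBox": f"0 0 {WIDTH} {HEIGHT}",
        },
    )
    if title:
        t = ET.SubElement(svg, f"{{{_SVG_NS}}}text", {"x": str(MARGIN_LEFT), "y": "18"})
        t.text = title

    # axis with bp tick labels
    ET.SubElement(
        svg, f"{{{_SVG_NS}}}line",
        {"x1": str(MARGIN_LEFT), "y1": str(AXIS_Y),
         "x2": str(WIDTH - MARGIN_RIGHT), "y2": str(AXIS_Y), "stroke": "black"},
    )
    for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
        pos = x0 + frac * (x1 - x0)
        label = ET.SubElement(
            svg, f"{{{_SVG_NS}}}text",
            {"x": f"{to_px(pos):.2f}", "y": str(AXIS_Y + 16),
             "font-size": "10", "text-anchor": "middle"},
        )
        label.text = f"{int(pos):,} bp"

    # island blocks
    for isl in islands:
        ET.SubElement(
            svg, f"{{{_SVG_NS}}}rect",
            {"x": f"{to_px(isl.start):.2f}", "y": str(ISLAND_Y),
             "width": f"{max(1.0, to_px(isl.end) - to_px(isl.start)):.2f}",
             "height": str(ISLAND_H), "fill": "pink", "stroke": "deeppink",
             "class": "island"},
        )

    # statistic curves, one polyline each
    for attr, colour, label, fixed in CURVES:
        values = [getattr(w, attr) for w in stats]
        lo, hi = fixed if fixed else (0.0, max(values) or 1.0)
        span = hi - lo or 1.0
        pts = []
        for w, v in zip(stats, values):
            centre = (w.start + w.end) / 2
            y = PLOT_TOP + PLOT_HEIGHT * (1.0 - (v - lo) / span)
            y = min(max(y, PLOT_TOP - 10), PLOT_TOP + PLOT_HEIGHT + 10)
            pts.append(f"{to_px(centre):.2f},{y:.2f}")
        ET.SubElement(
            svg, f"{{{_SVG_NS}}}polyline",
            {"points": " ".join(pts), "fill": "none", "stroke": colour,
             "stroke-width": "1", "class": f"curve-{attr}"},
        )

    # legend
    for i, (attr, colour, label, _fixed) in enumerate(CURVES):
        y = 14 + 12 * i
        ET.SubElement(
            svg, f"{{{_SVG_NS}}}line",
            {"x1": str(WIDTH - 250), "y1": str(y - 4), "x2": str(WIDTH - 230),
             "y2": str(y - 4), "stroke": colour, "stroke-width": "2"},
        )
        t = ET.SubElement(
            svg, f"{{{_SVG_NS}}}text",
            {"x": str(WIDTH - 225), "y": str(y), "font-size": "10"},
        )
        t.text = label

    ET.ElementTree(svg).write(out_path, xml_declaration=True, encoding="unicode")
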