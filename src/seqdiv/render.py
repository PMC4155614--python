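"""SVG serialization of a DiagramLayout, plus PNG/PDF export.

The SVG is the source of truth: it is emitted directly (timestamp-free,
fixed number formatting) so identical inputs produce byte-identical
documents.  PNG and PDF are produced by rasterizing the emitted SVG
subset — paths, lines, text — through matplotlib's Agg and PDF backends.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

from matplotlib.backends.backend_agg import FigureCanvasAgg  # noqa: F401  (backend registration)
from matplotlib.figure import Figure
from matplotlib.patches import PathPatch
from matplotlib.path import Path as MplPath
from matplotlib.transforms import IdentityTransform  # noqa: F401

from .errors import NothingToDrawError
from .layout import DiagramLayout
from .scheme import AlphabetScheme, DiagramConfig

#: CSS reference pixel density: SVG user units are interpreted at 96 px/inch.
_PX_PER_INCH = 96.0


def _fmt(v: float) -> str:
    """Fixed-precision coordinate formatting keeps the SVG byte-deterministic."""
    s = f"{v:.2f}"
    return "0.00" if s == "-0.00" else s


def _esc(text: str) -> str:
    return (
        text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
        .replace('"', "&quot;")
    )


def render_svg(
    layout: DiagramLayout, scheme: AlphabetScheme, config: DiagramConfig
) -> str:
    """Serialize a layout to an SVG 1.1 document string.

    One ``<path class="ribbon">`` element is written per ribbon, stroked in
    its sample's semi-transparent color so overlapping samples composite
    optically (red over blue reads as purple).  Residue rows and group
    labels annotate the y-axis, 1-based position labels the x-axis; masked
    positions keep their axis tick but carry no ribbons (the layout already
    suppressed them).
    """
    if not layout.ribbons:
        raise NothingToDrawError("nothing to draw: no ribbons survive")
    x0, y0, x1, y1 = layout.extents
    w, h = x1 - x0, y1 - y0
    font = _esc(config.font_family)
    fs = config.font_size
    geo = config.geometry

    out: list[str] = []
    out.append('<?xml version="1.0" encoding="UTF-8"?>')
    out.append(
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_fmt(w)}" height="{_fmt(h)}" '
        f'viewBox="0 0 {_fmt(w)} {_fmt(h)}">'
    )
    out.append("<desc>Sequence Diversity Diagram</desc>")

    out.append('<g class="ribbons" fill="none" stroke-linecap="butt">')
    for r in layout.ribbons:
        (px0, py0), (cx1, cy1), (cx2, cy2), (px1, py1) = r.path
        d = (
            f"M {_fmt(px0)} {_fmt(py0)} "
            f"C {_fmt(cx1)} {_fmt(cy1)} {_fmt(cx2)} {_fmt(cy2)} "
            f"{_fmt(px1)} {_fmt(py1)}"
        )
        out.append(
            f'<path class="ribbon" d="{d}" stroke="{r.color}" '
            f'stroke-opacity="{r.alpha:.3f}" stroke-width="{_fmt(r.weight)}"/>'
        )
    out.append("</g>")

    # y axis: residue rows and functional-group labels
    label_x = geo.margin_left - 10.0
    out.append(
        f'<g class="row-labels" font-family="{font}" font-size="{_fmt(fs)}" '
        f'text-anchor="end" fill="#333333">'
    )
    for sym, y in layout.row_labels:
        out.append(
            f'<text x="{_fmt(label_x)}" y="{_fmt(y + fs * 0.35)}">{_esc(sym)}</text>'
        )
    out.append("</g>")
    group_x = geo.margin_left - 36.0
    out.append(
        f'<g class="group-labels" font-family="{font}" '
        f'font-size="{_fmt(fs * 0.9)}" text-anchor="end" fill="#777777">'
    )
    for glabel, gy in layout.group_labels:
        out.append(
            f'<text x="{_fmt(group_x)}" y="{_fmt(gy + fs * 0.3)}">{_esc(glabel)}</text>'
        )
    out.append("</g>")

    # x axis: 1-based position labels with ticks (masked columns keep both)
    axis_y = y1 - geo.margin_bottom + 14.0
    out.append(
        f'<g class="position-labels" font-family="{font}" '
        f'font-size="{_fmt(fs * 0.9)}" text-anchor="middle" fill="#333333">'
    )
    for i in sorted(layout.position_labels):
        x = geo.margin_left + i * geo.column_spacing
        out.append(
            f'<line x1="{_fmt(x)}" y1="{_fmt(axis_y - 11.0)}" '
            f'x2="{_fmt(x)}" y2="{_fmt(axis_y - 7.0)}" '
            f'stroke="#999999" stroke-width="1.00"/>'
        )
        out.append(
            f'<text x="{_fmt(x)}" y="{_fmt(axis_y + fs * 0.4)}">'
            f"{_esc(layout.position_labels[i])}</text>"
        )
    out.append("</g>")

    # sample legend, top-left
    out.append(
        f'<g class="legend" font-family="{font}" font-size="{_fmt(fs)}" '
        f'text-anchor="start" fill="#333333">'
    )
    lx = geo.margin_left
    ly = 16.0
    for k, (label, hex6, alpha) in enumerate(layout.legend):
        yk = ly + k * (fs + 4.0)
        out.append(
            f'<line x1="{_fmt(lx)}" y1="{_fmt(yk - fs * 0.3)}" '
            f'x2="{_fmt(lx + 24.0)}" y2="{_fmt(yk - fs * 0.3)}" '
            f'stroke="{hex6}" stroke-opacity="{alpha:.3f}" stroke-width="6.00"/>'
        )
        out.append(
            f'<text x="{_fmt(lx + 30.0)}" y="{_fmt(yk)}">{_esc(label)}</text>'
        )
    out.append("</g>")

    out.append("</svg>")
    return "\n".join(out) + "\n"


def _strip_ns(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _parse_cubic(d: str):
    tok = d.replace(",", " ").split()
    assert tok[0] == "M" and tok[3] == "C", f"unsupported path data {d!r}"
    nums = [float(t) for t in tok[1:3] + tok[4:10]]
    return [(nums[0], nums[1]), (nums[2], nums[3]), (nums[4], nums[5]),
            (nums[6], nums[7])]


def export(
    svg: str,
    format: str,
    path: str | Path,
    dpi: float = 96.0,
) -> Path:
    """Convert an SVG document produced by :func:`render_svg` to PNG or PDF.

    The emitted SVG subset (cubic-Bezier paths, lines, text) is replayed
    onto a matplotlib figure in the same coordinate system; raster pixel
    dimensions are the SVG extents scaled by ``dpi`` / 96.
    """
    if format not in ("png", "pdf"):
        raise ValueError(f"unknown export format {format!r}")
    root = ET.fromstring(svg)
    w = float(root.get("width"))
    h = float(root.get("height"))

    fig = Figure(figsize=(w / _PX_PER_INCH, h / _PX_PER_INCH))
    ax = fig.add_axes((0.0, 0.0, 1.0, 1.0))
    ax.set_xlim(0, w)
    ax.set_ylim(h, 0)  # SVG y grows downward
    ax.axis("off")

    def px_to_pt(v: float) -> float:
        return v * 72.0 / _PX_PER_INCH

    for group in root:
        if _strip_ns(group.tag) != "g":
            continue
        g_font = group.get("font-family", "sans-serif")
        g_fs = float(group.get("font-size", "11"))
        g_anchor = group.get("text-anchor", "start")
        g_fill = group.get("fill", "#000000")
        ha = {"start": "left", "middle": "center", "end": "right"}[g_anchor]
        for el in group:
            tag = _strip_ns(el.tag)
            if tag == "path":
                pts = _parse_cubic(el.get("d"))
                mpath = MplPath(
                    pts,
                    [MplPath.MOVETO, MplPath.CURVE4, MplPath.CURVE4,
                     MplPath.CURVE4],
                )
                ax.add_patch(
                    PathPatch(
                        mpath,
                        fill=False,
                        edgecolor=el.get("stroke", "#000000"),
                        alpha=float(el.get("stroke-opacity", "1")),
                        linewidth=px_to_pt(float(el.get("stroke-width", "1"))),
                        capstyle="butt",
                    )
                )
            elif tag == "line":
                ax.plot(
                    [float(el.get("x1")), float(el.get("x2"))],
                    [float(el.get("y1")), float(el.get("y2"))],
                    color=el.get("stroke", "#000000"),
                    alpha=float(el.get("stroke-opacity", "1")),
                    linewidth=px_to_pt(float(el.get("stroke-width", "1"))),
                    solid_capstyle="butt",
                )
            elif tag == "text":
                ax.text(
                    float(el.get("x")),
                    float(el.get("y")),
                    el.text or "",
                    fontsize=px_to_pt(g_fs),
                    fontfamily=g_font,
                    color=g_fill,
                    ha=ha,
                    va="baseline",
                )

    path = Path(path)
    fig.savefig(str(path), format=format, dpi=dpi)
    return path


def render_to_file(
    layout: DiagramLayout,
    scheme: AlphabetScheme,
    config: DiagramConfig,
    out_path: str | Path,
    *,
    format: str | None = None,
    dpi: float = 96.0,
) -> Path:
    """Render a layout to SVG, PNG or PDF (format inferred from the suffix
    when not given)."""
    out_path = Path(out_path)
    fmt = format or (out_path.suffix.lstrip(".").lower() or "svg")
    svg = render_svg(layout, scheme, config)
    if fmt == "svg":
        out_path.write_text(svg)
        return out_path
    return export(svg, fmt, out_path, dpi=dpi)
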