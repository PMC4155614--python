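"""Geometry: mapping filtered transition tables onto the position x residue
grid and computing ribbon curves.

The grid is fixed: x is the alignment column, y the residue row in the
scheme's total order, with an extra vertical gap between functional groups.
Ribbons are cubic Bezier S-curves with horizontal tangents at both ends
(the Sankey convention) and a constant stroke width proportional to the
pair frequency, which avoids the line-width illusion of tapered bands.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import NothingToDrawError
from .freqs import TransitionTable
from .scheme import AlphabetScheme, DiagramConfig


@dataclass(frozen=True)
class Ribbon:
    """One drawn transition: group identity, endpoints and stroke weight."""

    group_label: str
    color: str          # "#rrggbb"
    alpha: float
    i: int              # left column (0-based)
    a: str
    b: str
    freq: float
    weight: float       # stroke width in figure units
    path: tuple         # ((x0,y0), (cx1,cy1), (cx2,cy2), (x1,y1))


@dataclass(frozen=True)
class DiagramLayout:
    """Resolved coordinates, ready for the renderer."""

    node_xy: dict                   # (column, row symbol) -> (x, y)
    ribbons: tuple                  # Ribbon, in draw order
    extents: tuple                  # (x0, y0, x1, y1)
    position_labels: dict           # column index -> 1-based label text
    row_labels: tuple               # (row symbol, y)
    group_labels: tuple             # (group label, y mid)
    legend: tuple                   # (sample label, color, alpha)
    n_columns: int


def compute_grid(
    scheme: AlphabetScheme, n_columns: int, config: DiagramConfig
) -> dict:
    """Deterministic node coordinates for every (column, row symbol).

    x advances by ``column_spacing`` per column; y follows the scheme's
    row order with ``row_spacing`` between rows and an additional
    ``group_gap`` across functional-group boundaries.
    """
    if n_columns < 2:
        raise ValueError("need at least two columns")
    geo = config.geometry
    ys = _row_ys(scheme, config)
    nodes = {}
    for i in range(n_columns):
        x = geo.margin_left + i * geo.column_spacing
        for sym, y in ys.items():
            nodes[(i, sym)] = (x, y)
    return nodes


def _row_ys(scheme: AlphabetScheme, config: DiagramConfig) -> dict:
    geo = config.geometry
    ys = {}
    y = geo.margin_top
    for g_idx, (_, residues) in enumerate(scheme.row_groups):
        if g_idx > 0:
            y += geo.group_gap
        for r_idx, sym in enumerate(residues):
            if g_idx > 0 and r_idx == 0 or r_idx > 0:
                y += geo.row_spacing
            ys[sym] = y
    return ys


def compute_ribbons(
    tables: list[TransitionTable],
    nodes: dict,
    scheme: AlphabetScheme,
    config: DiagramConfig,
    *,
    colors: dict | None = None,
) -> DiagramLayout:
    """Turn filtered transition tables into a fully resolved layout.

    One ribbon is emitted per surviving (group, i, a, b) entry whose
    columns are not masked; weight = ``max_ribbon_weight`` x pair_freq.
    Draw order is group-major (input order) then ascending weight, so the
    dominant paths of each sample are stroked last and stay visible.
    """
    geo = config.geometry
    colors = colors or {}
    masked = config.masked_positions  # 1-based
    ribbons: list[Ribbon] = []
    n_columns = tables[0].n_columns if tables else 0
    for g_idx, table in enumerate(tables):
        if table.n_columns != n_columns:
            raise ValueError("tables disagree on column count")
        hex6, alpha = colors.get(
            table.group_label, config.color_for(table.group_label, g_idx)
        )
        entries = []
        for (i, a, b), f in table.pair_freq.items():
            if (i + 1) in masked or (i + 2) in masked:
                continue
            try:
                x0, y0 = nodes[(i, a)]
                x1, y1 = nodes[(i + 1, b)]
            except KeyError as exc:
                raise KeyError(f"unmapped residue in table: {exc}") from exc
            xm = (x0 + x1) / 2.0
            entries.append(
                Ribbon(
                    group_label=table.group_label,
                    color=hex6,
                    alpha=alpha,
                    i=i,
                    a=a,
                    b=b,
                    freq=f,
                    weight=geo.max_ribbon_weight * f,
                    path=((x0, y0), (xm, y0), (xm, y1), (x1, y1)),
                )
            )
        entries.sort(key=lambda r: (r.weight, r.i, r.a, r.b))
        ribbons.extend(entries)

    ys = _row_ys(scheme, config)
    row_labels = tuple(ys.items())
    group_labels = tuple(
        (glabel, sum(ys[s] for s in residues) / len(residues))
        for glabel, residues in scheme.row_groups
    )
    width = geo.margin_left + (n_columns - 1) * geo.column_spacing + geo.margin_right
    height = max(ys.values()) + geo.margin_bottom
    legend = tuple(
        (
            t.group_label,
            *colors.get(t.group_label, config.color_for(t.group_label, k)),
        )
        for k, t in enumerate(tables)
    )
    return DiagramLayout(
        node_xy=dict(nodes),
        ribbons=tuple(ribbons),
        extents=(0.0, 0.0, width, height),
        position_labels={i: str(i + 1) for i in range(n_columns)},
        row_labels=row_labels,
        group_labels=group_labels,
        legend=legend,
        n_columns=n_columns,
    )


def build_layout(
    tables: list[TransitionTable],
    scheme: AlphabetScheme,
    config: DiagramConfig,
    *,
    colors: dict | None = None,
) -> DiagramLayout:
    """Convenience: grid + ribbons in one call."""
    if not tables:
        raise NothingToDrawError("nothing to draw: no transition tables")
    nodes = compute_grid(scheme, tables[0].n_columns, config)
    return compute_ribbons(tables, nodes, scheme, config, colors=colors)
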