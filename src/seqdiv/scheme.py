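"""Residue alphabets, functional groupings and diagram configuration.

The y-axis of a Sequence Diversity Diagram is an ordered list of residue
rows, partitioned into functional groups that are visually separated by
horizontal gaps.  The default protein scheme partitions the 20 standard
amino acids by side-chain structure and chemistry (aliphatic/hydrophobic,
aromatic, polar uncharged, positively charged, negatively charged, and the
special residues C, G, P); the nucleotide scheme splits purines from
pyrimidines.  Both are fully overridable through a YAML configuration
file, which also carries display parameters (colors, geometry, the
low-frequency filter threshold, position masking).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .errors import AmbiguousGroupingError, ConfigError

GAP = "-"
#: Row symbol used for declared ambiguity codes (X, B, Z ... / IUPAC nt codes).
OTHER = "?"

#: Standard physicochemical grouping of the 20 amino acids.
PROTEIN_GROUPS: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("aliphatic", ("A", "V", "L", "I", "M")),
    ("aromatic", ("F", "W", "Y")),
    ("polar", ("S", "T", "N", "Q")),
    ("positive", ("K", "R", "H")),
    ("negative", ("D", "E")),
    ("special", ("C", "G", "P")),
)

PROTEIN_AMBIGUITY = ("X", "B", "Z", "J")
NUCLEOTIDE_AMBIGUITY = ("N", "R", "Y", "S", "W", "K", "M", "B", "D", "H", "V")

#: Default sample palette: semi-transparent red then blue so that the overlap
#: of the first two samples composites to purple.
DEFAULT_PALETTE: tuple[tuple[str, float], ...] = (
    ("#d62728", 0.5),
    ("#1f77b4", 0.5),
    ("#2ca02c", 0.5),
    ("#9467bd", 0.5),
    ("#ff7f0e", 0.5),
    ("#8c564b", 0.5),
)


@dataclass(frozen=True)
class AlphabetScheme:
    """Ordered residue functional groups defining the y-axis.

    Every alphabet symbol belongs to exactly one group; concatenating the
    groups in declaration order yields the total top-to-bottom row order.
    Declared ambiguity symbols are mapped onto a dedicated "other" row, and
    the gap ``-`` gets its own bottom row unless ``gap_row_policy`` is
    ``"excluded"``.
    """

    groups: tuple[tuple[str, tuple[str, ...]], ...]
    gap_row_policy: str = "own_row"  # "own_row" | "excluded"
    ambiguity_symbols: frozenset = frozenset()
    kind: str = "protein"

    def __post_init__(self) -> None:
        if self.gap_row_policy not in ("own_row", "excluded"):
            raise ConfigError(f"bad gap_row_policy {self.gap_row_policy!r}")
        seen: dict[str, str] = {}
        for glabel, residues in self.groups:
            if not residues:
                raise ConfigError(f"group {glabel!r} is empty")
            for r in residues:
                if r in seen:
                    raise AmbiguousGroupingError(
                        f"ambiguous grouping: residue {r!r} in groups "
                        f"{seen[r]!r} and {glabel!r}"
                    )
                seen[r] = glabel
        overlap = self.ambiguity_symbols & set(seen)
        if overlap:
            raise AmbiguousGroupingError(
                f"ambiguous grouping: {sorted(overlap)} declared both as "
                "alphabet and ambiguity symbols"
            )

    @property
    def alphabet(self) -> tuple[str, ...]:
        """Alphabet symbols in total y-order (excluding other/gap rows)."""
        return tuple(r for _, residues in self.groups for r in residues)

    @property
    def accepted_symbols(self) -> frozenset:
        """All symbols a valid sequence may contain (gap excluded)."""
        return frozenset(self.alphabet) | self.ambiguity_symbols

    @property
    def row_groups(self) -> tuple[tuple[str, tuple[str, ...]], ...]:
        """Groups extended with the pseudo-rows actually drawn on the y-axis."""
        extra: list[tuple[str, tuple[str, ...]]] = []
        if self.ambiguity_symbols:
            extra.append(("other", (OTHER,)))
        if self.gap_row_policy == "own_row":
            extra.append(("gap", (GAP,)))
        return self.groups + tuple(extra)

    @property
    def rows(self) -> tuple[str, ...]:
        """All row symbols, top to bottom."""
        return tuple(r for _, residues in self.row_groups for r in residues)

    def canonical(self, ch: str) -> str:
        """Map an input character to the row symbol that represents it."""
        ch = ch.upper()
        if ch == GAP:
            return GAP
        if ch in self.ambiguity_symbols:
            return OTHER
        if ch in self.accepted_symbols:
            return ch
        raise KeyError(f"unmapped residue {ch!r}")


def default_protein_scheme(
    gap_row_policy: str = "own_row", *, ambiguity: tuple[str, ...] = PROTEIN_AMBIGUITY
) -> AlphabetScheme:
    """The stock 20-residue scheme grouped by side-chain chemistry."""
    return AlphabetScheme(
        groups=PROTEIN_GROUPS,
        gap_row_policy=gap_row_policy,
        ambiguity_symbols=frozenset(ambiguity),
        kind="protein",
    )


def default_nucleotide_scheme(
    gap_row_policy: str = "own_row",
    *,
    rna: bool | None = None,
    merge_tu: bool = False,
    ambiguity: tuple[str, ...] = NUCLEOTIDE_AMBIGUITY,
) -> AlphabetScheme:
    """Purine/pyrimidine grouping.

    ``rna=None`` (default) accepts both T and U as separate pyrimidine rows;
    ``rna=True`` keeps only U, ``rna=False`` only T.  ``merge_tu`` instead
    collapses U onto the T row (accepted on input, drawn as one row).
    """
    if merge_tu or rna is False:
        pyr: tuple[str, ...] = ("C", "T")
    elif rna is True:
        pyr = ("C", "U")
    else:
        pyr = ("C", "T", "U")
    groups = (("purine", ("A", "G")), ("pyrimidine", pyr))
    amb = frozenset(a for a in ambiguity if a not in ("A", "C", "G", "T", "U"))
    scheme = AlphabetScheme(
        groups=groups, gap_row_policy=gap_row_policy, ambiguity_symbols=amb,
        kind="nucleotide",
    )
    if merge_tu:
        scheme = replace(scheme, kind="nucleotide-tu")
    return scheme


@dataclass(frozen=True)
class Geometry:
    """Figure geometry in abstract units (the SVG maps 1 unit to 1 px)."""

    column_spacing: float = 48.0
    row_spacing: float = 16.0
    group_gap: float = 12.0
    max_ribbon_weight: float = 12.0
    margin_left: float = 88.0
    margin_right: float = 32.0
    margin_top: float = 40.0
    margin_bottom: float = 48.0

    def __post_init__(self) -> None:
        if self.group_gap <= 0:
            raise ConfigError("group_gap must be > 0")
        if self.max_ribbon_weight <= 0:
            raise ConfigError("max_ribbon_weight must be > 0")


@dataclass(frozen=True)
class DiagramConfig:
    """Everything about a diagram that is not the data itself."""

    filter_threshold: float = 0.01
    group_colors: tuple = ()  # ((label, (hex, alpha)), ...)
    geometry: Geometry = field(default_factory=Geometry)
    masked_positions: frozenset = frozenset()  # 1-based columns
    output_format: str = "svg"
    denominator_policy: str = "per_group"  # "per_group" | "combined"
    include_gap_pairs: bool = True
    dot_as_gap: bool = False
    font_family: str = "DejaVu Sans"
    font_size: float = 11.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.filter_threshold <= 1.0:
            raise ConfigError(
                f"filter threshold must be in [0, 1], got {self.filter_threshold}"
            )
        if self.output_format not in ("svg", "png", "pdf"):
            raise ConfigError(f"unknown output format {self.output_format!r}")
        if self.denominator_policy not in ("per_group", "combined"):
            raise ConfigError(
                f"unknown denominator policy {self.denominator_policy!r}"
            )

    def colors_dict(self) -> dict:
        return dict(self.group_colors)

    def color_for(self, label: str, index: int) -> tuple[str, float]:
        """Configured color for a group label, else the default palette."""
        d = self.colors_dict()
        if label in d:
            return d[label]
        return DEFAULT_PALETTE[index % len(DEFAULT_PALETTE)]


def parse_color(token: str, default_alpha: float = 0.5) -> tuple[str, float]:
    """Parse ``#rrggbb`` or ``#rrggbbaa`` into (hex6, alpha)."""
    t = token.strip()
    if not t.startswith("#") or len(t) not in (7, 9):
        raise ConfigError(f"bad color token {token!r} (expect #rrggbb[aa])")
    try:
        int(t[1:], 16)
    except ValueError as exc:
        raise ConfigError(f"bad color token {token!r}") from exc
    if len(t) == 9:
        return t[:7].lower(), round(int(t[7:9], 16) / 255.0, 4)
    return t.lower(), default_alpha


def format_color(color: tuple[str, float]) -> str:
    hex6, alpha = color
    return f"{hex6}{int(round(alpha * 255)):02x}"


_KNOWN_KEYS = {
    "alphabet", "groups", "ambiguity", "gap_row", "rna", "merge_tu",
    "colors", "geometry", "filter", "mask", "format", "font", "dot_as_gap",
}


def load_config(path: str | Path | None) -> tuple[AlphabetScheme, DiagramConfig]:
    """Load a YAML configuration file into a scheme and a diagram config.

    All keys are optional; an empty (or absent) file yields the default
    protein scheme with the 1% filter threshold.  Unknown keys warn but do
    not fail; structural errors (a residue in two groups, a threshold
    outside [0, 1]) raise :class:`ConfigError`.
    """
    if path is None:
        return default_protein_scheme(), DiagramConfig()
    raw = Path(path).read_text()
    try:
        data = yaml.safe_load(raw)
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML: {exc}") from exc
    if data is None:
        return default_protein_scheme(), DiagramConfig()
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")

    for key in data:
        if key not in _KNOWN_KEYS:
            warnings.warn(f"{path}: unknown config key {key!r} ignored", stacklevel=2)

    gap_row = data.get("gap_row", "own_row")
    kind = str(data.get("alphabet", "protein"))
    if "groups" in data:
        grp = data["groups"]
        if not isinstance(grp, dict):
            raise ConfigError("groups must map group label -> residue list")
        groups = tuple(
            (str(lbl), tuple(str(r).upper() for r in residues))
            for lbl, residues in grp.items()
        )
        amb = frozenset(str(a).upper() for a in data.get("ambiguity", ()))
        scheme = AlphabetScheme(
            groups=groups, gap_row_policy=gap_row, ambiguity_symbols=amb, kind=kind
        )
    elif kind == "nucleotide":
        scheme = default_nucleotide_scheme(
            gap_row, rna=data.get("rna"), merge_tu=bool(data.get("merge_tu", False))
        )
        if "ambiguity" in data:
            scheme = replace(
                scheme,
                ambiguity_symbols=frozenset(
                    str(a).upper() for a in data["ambiguity"]
                ),
            )
    else:
        amb = tuple(
            str(a).upper() for a in data.get("ambiguity", PROTEIN_AMBIGUITY)
        )
        scheme = default_protein_scheme(gap_row, ambiguity=amb)

    flt = data.get("filter", {}) or {}
    if not isinstance(flt, dict):
        raise ConfigError("filter must be a mapping")
    geo_raw = data.get("geometry", {}) or {}
    known_geo = {f for f in Geometry.__dataclass_fields__}
    bad_geo = set(geo_raw) - known_geo
    if bad_geo:
        warnings.warn(f"unknown geometry keys ignored: {sorted(bad_geo)}", stacklevel=2)
    geometry = Geometry(**{k: float(v) for k, v in geo_raw.items() if k in known_geo})

    colors_raw = data.get("colors", {}) or {}
    group_colors = []
    for lbl, tok in colors_raw.items():
        if isinstance(tok, dict):
            group_colors.append(
                (str(lbl), (str(tok["hex"]).lower(), float(tok.get("alpha", 0.5))))
            )
        else:
            group_colors.append((str(lbl), parse_color(str(tok))))
    group_colors = tuple(group_colors)

    mask = data.get("mask", ()) or ()
    masked = frozenset(int(p) for p in mask)
    if any(p < 1 for p in masked):
        raise ConfigError("masked positions are 1-based and must be >= 1")

    font = data.get("font", {}) or {}

    config = DiagramConfig(
        filter_threshold=float(flt.get("threshold", 0.01)),
        group_colors=group_colors,
        geometry=geometry,
        masked_positions=masked,
        output_format=str(data.get("format", "svg")),
        denominator_policy=str(flt.get("denominator", "per_group")),
        include_gap_pairs=bool(flt.get("include_gap_pairs", True)),
        dot_as_gap=bool(data.get("dot_as_gap", False)),
        font_family=str(font.get("family", "DejaVu Sans")),
        font_size=float(font.get("size", 11.0)),
    )
    return scheme, config


def write_config(
    scheme: AlphabetScheme, config: DiagramConfig, path: str | Path
) -> None:
    """Serialize a scheme + config pair so that :func:`load_config` round-trips."""
    data = {
        "alphabet": scheme.kind,
        "groups": {lbl: list(residues) for lbl, residues in scheme.groups},
        "ambiguity": sorted(scheme.ambiguity_symbols),
        "gap_row": scheme.gap_row_policy,
        "dot_as_gap": config.dot_as_gap,
        "colors": {
            lbl: {"hex": hex6, "alpha": alpha}
            for lbl, (hex6, alpha) in config.group_colors
        },
        "geometry": {
            k: getattr(config.geometry, k) for k in Geometry.__dataclass_fields__
        },
        "filter": {
            "threshold": config.filter_threshold,
            "denominator": config.denominator_policy,
            "include_gap_pairs": config.include_gap_pairs,
        },
        "mask": sorted(config.masked_positions),
        "format": config.output_format,
        "font": {"family": config.font_family, "size": config.font_size},
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
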