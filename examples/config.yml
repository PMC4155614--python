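# seqdiv configuration template.
# Every key is optional; omitted keys take the defaults shown here.

# Residue scheme: "protein" (default) or "nucleotide".
alphabet: protein

# Functional grouping of the y-axis, top to bottom.  Declaration order is
# the drawing order; every residue must appear in exactly one group.
# Omit this section to use the built-in grouping below.
groups:
  aliphatic: [A, V, L, I, M]
  aromatic: [F, W, Y]
  polar: [S, T, N, Q]
  positive: [K, R, H]
  negative: [D, E]
  special: [C, G, P]

# Ambiguity codes accepted on input and pooled onto one "other" row.
ambiguity: [X, B, Z, J]

# Gap handling: "own_row" draws gaps as a bottom row; "excluded" drops
# gap characters from the per-column counts.
gap_row: own_row

# Treat "." in input FASTA as a gap (default: "." is rejected).
dot_as_gap: false

# Per-sample ribbon colors, keyed by group label (file stem by default).
# Accepts "#rrggbb", "#rrggbbaa", or {hex, alpha}.  Unlisted samples take
# the built-in palette (semi-transparent red, then blue, ...).
colors:
  sample_a: "#d6272880"
  sample_b: "#1f77b480"

# Figure geometry in abstract units (rendered as SVG pixels).
geometry:
  column_spacing: 48      # x distance between alignment positions
  row_spacing: 16         # y distance between residue rows in one group
  group_gap: 12           # extra y gap between functional groups
  max_ribbon_weight: 12   # stroke width of a pair with frequency 1.0

filter:
  threshold: 0.01         # pairs with frequency strictly below are dropped
  denominator: per_group  # or "combined": pooled N of all samples
  include_gap_pairs: true # count pairs touching a gap (on the gap row)

# 1-based alignment positions whose ribbons are suppressed (axis labels
# are kept), e.g. [1, 2, 3] or leave empty.
mask: []

# Default output format when --out has no suffix: svg, png or pdf.
format: svg

font:
  family: DejaVu Sans
  size: 11
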