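# Methods

## The diagram model

A Sequence Diversity Diagram overlays one flow diagram per sample on a
fixed grid. The x-axis is the alignment column (stored 0-based, displayed
1-based); the y-axis is the scheme's total residue order: functional
groups in declaration order, residues in within-group order, then — when
present — a pooled "other" row for declared ambiguity codes and a bottom
gap row. Rows inside a group are `row_spacing` apart; an additional
`group_gap` separates groups, which is the visual cue for the functional
grouping.

For each sample with $N$ sequences, each junction $(i, i+1)$ and each
ordered residue pair $(a, b)$, the pair count is the number of sequences
carrying $a$ at $i$ and $b$ at $i+1$; the pair frequency divides by a
denominator that is the sample's own $N$ by default (`per_group`) or the
pooled size of all overlaid samples (`combined`). Per-group normalization
is the default because it keeps a small subfamily visible next to a large
one; the combined mode is a config key for when absolute prevalence is
the question. Unfiltered tables satisfy two identities used as test
invariants: pair counts at every junction sum to $N$, and their row/column
marginals equal the per-column residue counts.

Ribbons are cubic Bezier S-curves with horizontal tangents at both
endpoints (control points at the x-midpoint, each at its endpoint's y), so
a same-row transition is exactly horizontal and every ribbon attaches
flat to its rows. Stroke width is constant along the path and strictly
proportional to pair frequency (`max_ribbon_weight` x frequency); constant
width rather than a tapered band avoids the line-width illusion that makes
Parallel-Sets-style wedges hard to compare. Draw order is sample-major in
input order, then ascending weight within a sample, so each sample's
dominant paths are stroked last and stay visible. No crossing minimization
is attempted: the fixed grid *is* the encoding. Sample identity is
encoded by semi-transparent stroke color; overlap of two samples is left
to the viewer's alpha compositing (red over blue reads as purple), which
generalizes to three or more samples without computing blend colors.

## Filtering

Pairs with frequency strictly below the threshold (default 0.01) are
removed; a pair exactly at the threshold survives. The filter is applied
per sample independently, so a path common in one subfamily but rare
overall is retained — that is precisely the comparative signal the figure
exists to show. Filtering deliberately breaks the sum-to-$N$ invariant;
downstream code treats filtered tables as display selections, not
distributions.

## Entropy and information content

Per-column Shannon entropy $H=-\sum_a p_a \log_2 p_a$ (with
$0\log 0 := 0$) and information content
$R=\log_2 s - (H + e_n)$, $e_n=(s-1)/(2\ln 2\,N)$ applied only on
request, $R$ clamped at 0, are exposed for reporting and tabular export.
They do not scale the diagram: ribbons encode frequency, not bits, and
conflating the two would double-encode conservation.

## Configuration

A flat YAML file carries everything tunable: the grouping (any partition
of any alphabet — the nucleotide scheme is just purines/pyrimidines with
optional T/U merging), ambiguity codes, gap policy, colors with alpha,
geometry in abstract figure units (the SVG maps one unit to one CSS
pixel), the filter threshold and denominator policy, masked positions,
and fonts. Command-line flags override config values, which override
built-ins. Unknown keys warn rather than fail so configs stay forward
compatible; structural errors (a residue in two groups, a threshold
outside $[0,1]$) are hard errors. `write_config`/`load_config` round-trip
exactly, which is property-tested.

Gap policy default is a visible bottom gap row rather than dropping
gapped sequences: dropping would silently change $N$ and make frequencies
incomparable across columns. Pairs touching a gap flow through the gap
row by default for the same reason; `include_gap_pairs: false` excludes
them. Masking (1-based positions) suppresses every ribbon touching a
masked column but keeps its axis tick and label, so position numbering
stays readable.

## Rendering

SVG is emitted directly with fixed two-decimal coordinate formatting and
no timestamps, so identical inputs give byte-identical documents — the
determinism and ribbon-count assertions in the test suite are plain
string checks. One `<path class="ribbon">` per surviving pair. PNG and
PDF export replay the emitted SVG subset (cubic paths, lines, text)
through matplotlib's Agg and PDF backends in the same coordinate system;
raster pixel dimensions are the SVG extents scaled by `dpi`/96. Text
labels carry a font-family attribute but glyph metrics are never
measured, so layout does not depend on installed fonts.

## Synthetic data

The generator samples every column independently: the column's modal
residue with probability $p$, otherwise a uniform draw over the remaining
19 residues (uniform background is deliberately unstructured — it models
no chemistry). A configurable fraction of sequences follows a modal path
shifted by a fixed offset from a start column, background-filled where
the shifted index leaves the alignment. The committed demonstration
conditions are two 40-column samples of 500 sequences at $p = 0.85$, both
modal strings sharing Proline/Alanine at positions 5/6 and differing at
positions 24 and 30; sample B carries a 20% subgroup offset by +1 from
column 19 (`tests/data/`, regenerable with `seqdiv --synthetic` at seed
20140828).

What this emulates — and what it does not: real curated alignments have
phylogenetic correlation between sequences, structured minority residues,
and indel-driven gap columns; the generator has none of these. Passing
tests therefore demonstrate that the pipeline counts, filters, lays out
and renders correctly under controlled conservation and subgroup
structure, not that the defaults are tuned for any particular protein
family.

One statistical property of these conditions is worth recording: at
$p=0.85$ and $N=500$, a background pair has expected count
$\approx 3.4$ while the 1% filter keeps counts $\ge 5$, so roughly a
quarter of background pairs survive by sampling noise and both samples
retain several hundred thin ribbons. The subgroup signal is therefore
assessed at the *path* level: a chain of residues across a region
"survives" when every junction pair of the chain is present in the
filtered table (`chain_survives`, `surviving_chains`). Under the demo
conditions the +1-offset modal chain survives unbroken in sample B (every
link near $0.2\,p^2 \approx 0.14$) and is broken by the filter in sample
A, while the unshifted chain survives in both — the two-parallel-bands
picture the figure shows.

## Numerical choices and degenerate inputs

- Frequencies are plain double divisions; entropy validates that inputs
  sum to 1 within 1e-6 and are non-negative.
- `dominant_transition` breaks ties alphabetically on $(a,b)$ and sets a
  tie flag; an empty junction (possible after filtering) raises.
- Single-sequence and single-sample inputs are legal; alignments need at
  least 2 columns; overlays require identical column counts.
- Duplicate FASTA record ids warn but load; `.` is rejected unless
  `dot_as_gap` maps it to `-`; lowercase is normalized to uppercase.
- Seeds derive from a single integer; the acceptance script reduces its
  seed modulo $2^{31}-3$ before use.

## Command-line interface

`seqdiv` is a single command: positional FASTA files (one per sample),
with `--synthetic DIR` as a generator mode that writes the demo pair and
exits (kept as an option rather than a subcommand so the plain
`seqdiv a.fa b.fa -o out.svg` form stays primary). Errors map to a fixed
exit-code taxonomy: 3 missing file, 4 bad config, 5 incompatible
alignments, 6 malformed input (not aligned / unknown residue / empty), 7
nothing to draw.

## Known limitations

- No mutual information between non-adjacent positions; junctions are
  strictly $(i, i+1)$.
- No sequence weighting or redundancy down-weighting; every sequence
  counts once.
- No alignment computation and no Stockholm/Clustal readers; aligned
  FASTA only.
- The path-enumeration helper is exponential in pathological dense
  tables; it is intended for filtered tables over short regions.
- Static figures only; no interactive editing.
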