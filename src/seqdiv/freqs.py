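"""Column frequencies, adjacent-column transition frequencies, information
content and the low-frequency filter.

The central quantity of a Sequence Diversity Diagram is the transition
(pair) frequency: the fraction of sequences in a sample carrying residue
``a`` at column ``i`` and residue ``b`` at column ``i + 1``.  Ribbon
thickness is proportional to it.  Per-column Shannon entropy and
sequence-logo information content are computed for reporting; the diagram
itself encodes frequency, not bits.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, replace
from typing import Mapping, NamedTuple

import pandas as pd

from .msa_io import AlignmentGroup
from .scheme import GAP, AlphabetScheme


@dataclass(frozen=True)
class PositionFrequencyTable:
    """Per-column residue counts and relative frequencies for one group.

    ``counts[(i, a)]`` is the number of sequences with row symbol ``a`` at
    0-based column ``i``; every (column, row) combination is present, with
    count 0 for absent residues.  ``rel_freq`` divides by the group's
    ``n_sequences``, so with the gap row included each column sums to 1.
    """

    group_label: str
    n_sequences: int
    n_columns: int
    rows: tuple[str, ...]
    counts: dict
    rel_freq: dict

    def column_freqs(self, i: int) -> dict:
        """Row symbol -> relative frequency at column ``i`` (zeros included)."""
        return {a: self.rel_freq[(i, a)] for a in self.rows}

    def column_counts(self, i: int) -> dict:
        return {a: self.counts[(i, a)] for a in self.rows}

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per (position, residue) with count and freq."""
        recs = [
            {
                "group": self.group_label,
                "position": i + 1,
                "residue": a,
                "count": self.counts[(i, a)],
                "rel_freq": self.rel_freq[(i, a)],
            }
            for i in range(self.n_columns)
            for a in self.rows
        ]
        return pd.DataFrame.from_records(recs)


@dataclass(frozen=True)
class TransitionTable:
    """Ordered residue-pair counts for every adjacent column pair.

    ``pair_counts[(i, a, b)]`` counts sequences with row symbol ``a`` at
    column ``i`` and ``b`` at ``i + 1``; only observed pairs are stored.
    ``pair_freq`` divides by ``denominator``: the group's own size under the
    ``per_group`` policy, or the pooled size of all overlaid samples under
    ``combined``.  An unfiltered table satisfies, for every ``i``,
    ``sum_ab pair_counts = n_sequences`` and the marginal-consistency
    identities against :class:`PositionFrequencyTable`; filtering
    deliberately breaks them.
    """

    group_label: str
    n_sequences: int
    n_columns: int
    denominator: int
    denominator_policy: str
    pair_counts: dict
    pair_freq: dict
    filtered: bool = False

    def pairs_at(self, i: int) -> dict:
        """(a, b) -> frequency for the column pair (i, i+1)."""
        return {
            (a, b): f for (j, a, b), f in self.pair_freq.items() if j == i
        }

    def to_frame(self) -> pd.DataFrame:
        recs = [
            {
                "group": self.group_label,
                "position": i + 1,
                "residue_from": a,
                "residue_to": b,
                "count": self.pair_counts[(i, a, b)],
                "pair_freq": self.pair_freq[(i, a, b)],
            }
            for (i, a, b) in sorted(self.pair_counts)
        ]
        return pd.DataFrame.from_records(recs)


def position_frequencies(
    group: AlignmentGroup, scheme: AlphabetScheme
) -> PositionFrequencyTable:
    """Count row symbols per column and normalize by group size.

    Gap characters are counted on the gap row, or dropped entirely when the
    scheme's ``gap_row_policy`` is ``"excluded"`` (columns then sum to less
    than ``n_sequences``).
    """
    rows = scheme.rows
    drop_gap = scheme.gap_row_policy == "excluded"
    counts: dict = {(i, a): 0 for i in range(group.n_columns) for a in rows}
    for seq in group.sequences:
        for i, ch in enumerate(seq):
            sym = scheme.canonical(ch)
            if drop_gap and sym == GAP:
                continue
            counts[(i, sym)] += 1
    n = group.n_sequences
    rel = {key: c / n for key, c in counts.items()}
    return PositionFrequencyTable(
        group_label=group.label,
        n_sequences=n,
        n_columns=group.n_columns,
        rows=rows,
        counts=counts,
        rel_freq=rel,
    )


def transition_frequencies(
    group: AlignmentGroup,
    scheme: AlphabetScheme,
    *,
    denominator_policy: str = "per_group",
    combined_total: int | None = None,
    include_gap_pairs: bool = True,
) -> TransitionTable:
    """Count ordered residue pairs at every adjacent column pair.

    Each sequence contributes exactly one pair per junction ``(i, i+1)``.
    With ``include_gap_pairs=False`` pairs touching a gap are dropped
    (documented to break the sum-to-N invariant).  Under the ``combined``
    policy ``combined_total`` (the pooled number of sequences across all
    overlaid groups) is the frequency denominator.
    """
    if group.n_columns < 2:
        raise ValueError("need at least two columns for transitions")
    if denominator_policy == "per_group":
        denom = group.n_sequences
    elif denominator_policy == "combined":
        if combined_total is None or combined_total < group.n_sequences:
            raise ValueError("combined policy needs combined_total >= group size")
        denom = combined_total
    else:
        raise ValueError(f"unknown denominator policy {denominator_policy!r}")

    pair_counts: Counter = Counter()
    for seq in group.sequences:
        canon = [scheme.canonical(ch) for ch in seq]
        for i in range(len(canon) - 1):
            a, b = canon[i], canon[i + 1]
            if not include_gap_pairs and (a == GAP or b == GAP):
                continue
            pair_counts[(i, a, b)] += 1

    pair_counts = dict(pair_counts)
    pair_freq = {key: c / denom for key, c in pair_counts.items()}
    return TransitionTable(
        group_label=group.label,
        n_sequences=group.n_sequences,
        n_columns=group.n_columns,
        denominator=denom,
        denominator_policy=denominator_policy,
        pair_counts=pair_counts,
        pair_freq=pair_freq,
    )


def shannon_entropy(column_freqs: Mapping[str, float], *, tol: float = 1e-6) -> float:
    """Shannon entropy H = -sum p log2 p of one column, in bits.

    ``column_freqs`` must be a proper distribution (non-negative, summing
    to 1 within ``tol``); zero frequencies contribute nothing.
    """
    vals = list(column_freqs.values())
    if any(p < 0 for p in vals):
        raise ValueError("negative frequency")
    total = sum(vals)
    if abs(total - 1.0) > tol:
        raise ValueError(f"frequencies sum to {total}, not 1")
    return -sum(p * math.log2(p) for p in vals if p > 0)


def information_content(
    column_freqs: Mapping[str, float],
    alphabet_size: int,
    n_sequences: int | None = None,
    correction: bool = False,
) -> float:
    """Sequence-logo information content of one column, in bits.

    R = log2(s) - (H + e_n), where s is the alphabet size and e_n the
    small-sample correction (s - 1) / (2 ln2 n), applied only when
    ``correction`` is set; R is clamped at 0 from below.
    """
    if alphabet_size < 2:
        raise ValueError("alphabet_size must be >= 2")
    h = shannon_entropy(column_freqs)
    e_n = 0.0
    if correction:
        if not n_sequences or n_sequences < 1:
            raise ValueError("small-sample correction needs n_sequences >= 1")
        e_n = (alphabet_size - 1) / (2.0 * math.log(2.0) * n_sequences)
    return max(0.0, math.log2(alphabet_size) - h - e_n)


def filter_transitions(table: TransitionTable, threshold: float) -> TransitionTable:
    """Drop every pair whose frequency is strictly below ``threshold``.

    A pair exactly at the threshold survives ("less than" is strict).  The
    result keeps the surviving entries untouched but no longer sums to the
    number of sequences.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    keep = {key for key, f in table.pair_freq.items() if f >= threshold}
    return replace(
        table,
        pair_counts={k: table.pair_counts[k] for k in keep},
        pair_freq={k: table.pair_freq[k] for k in keep},
        filtered=True,
    )


class DominantTransition(NamedTuple):
    pair: tuple[str, str]
    count: int
    freq: float
    tie: bool


def dominant_transition(table: TransitionTable, i: int) -> DominantTransition:
    """Most frequent ordered pair at the column junction (i, i+1).

    Ties are broken by alphabetical order of (a, b) and reported through
    the ``tie`` flag.
    """
    pairs = table.pairs_at(i)
    if not pairs:
        raise ValueError(f"no transitions at column pair ({i}, {i + 1})")
    best_freq = max(pairs.values())
    candidates = sorted(p for p, f in pairs.items() if f == best_freq)
    a, b = candidates[0]
    return DominantTransition(
        pair=(a, b),
        count=table.pair_counts[(i, a, b)],
        freq=best_freq,
        tie=len(candidates) > 1,
    )


def surviving_chains(
    table: TransitionTable, start: int, end: int
) -> list[tuple[tuple[str, ...], float]]:
    """Complete residue chains through columns ``start..end`` (0-based,
    inclusive) whose every junction pair survives in ``table``.

    Returns ``(chain, bottleneck)`` pairs sorted by descending bottleneck
    frequency (the weakest link of the chain).  This is the path-level view
    of the diagram: a chain is one continuous ribbon trajectory the eye can
    follow across the region.
    """
    if not 0 <= start < end <= table.n_columns - 1:
        raise ValueError("need 0 <= start < end <= n_columns - 1")
    # chains[(residue at current column)] -> list of (prefix, bottleneck)
    chains: dict = {}
    for (i, a, b), f in table.pair_freq.items():
        if i == start:
            chains.setdefault(a, [])
    partial: dict = {
        a: [((a,), math.inf)] for a in chains
    }
    for j in range(start, end):
        nxt: dict = {}
        junction = {
            (a, b): f for (i, a, b), f in table.pair_freq.items() if i == j
        }
        for (a, b), f in junction.items():
            for prefix, bott in partial.get(a, ()):
                nxt.setdefault(b, []).append((prefix + (b,), min(bott, f)))
        partial = nxt
    out = [
        (chain, bott) for lst in partial.values() for chain, bott in lst
    ]
    out.sort(key=lambda t: (-t[1], t[0]))
    return out


def chain_survives(
    table: TransitionTable, residues: tuple[str, ...] | str, start: int
) -> bool:
    """True when every junction pair of the residue chain starting at
    0-based column ``start`` is present in ``table``.

    On a filtered table this asks whether the chain would be drawn as one
    unbroken ribbon trajectory across its region.
    """
    residues = tuple(residues)
    if len(residues) < 2:
        raise ValueError("a chain needs at least two residues")
    return all(
        (start + k, residues[k], residues[k + 1]) in table.pair_freq
        for k in range(len(residues) - 1)
    )


def write_tables(
    pos_tables, trans_tables, prefix: str, *, sep: str = "\t"
) -> tuple[str, str]:
    """Export position and transition tables as delimited text files.

    Writes ``<prefix>.positions.tsv`` and ``<prefix>.transitions.tsv`` with
    all groups concatenated; returns the two paths.
    """
    pos_path = f"{prefix}.positions.tsv"
    trans_path = f"{prefix}.transitions.tsv"
    pd.concat([t.to_frame() for t in pos_tables], ignore_index=True).to_csv(
        pos_path, sep=sep, index=False
    )
    pd.concat([t.to_frame() for t in trans_tables], ignore_index=True).to_csv(
        trans_path, sep=sep, index=False
    )
    return pos_path, trans_path
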