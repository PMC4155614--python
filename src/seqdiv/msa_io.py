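"""Reading, validation and writing of aligned FASTA files.

One FASTA file holds one sample (group) of pre-aligned sequences: every
record must have the same length, gaps are written as ``-``, and lowercase
residues are normalized to uppercase on input.  The reader never attempts
to align; inputs are expected to come from a curation pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    IncompatibleAlignmentsError,
    NoSequencesError,
    NotAlignedError,
    UnknownResidueError,
)

GAP = "-"


@dataclass(frozen=True)
class AlignmentGroup:
    """One sample's aligned sequences plus its display identity.

    Parameters
    ----------
    label
        Text identifier shown in the legend (defaults to the file stem).
    color
        Display color token, ``#rrggbb`` or ``#rrggbbaa`` hex.
    sequences
        Uppercased, equal-length residue strings in record order.
    ids
        FASTA record identifiers, parallel to ``sequences``.
    """

    label: str
    color: str
    sequences: tuple[str, ...]
    ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.sequences) < 1:
            raise NoSequencesError(f"group {self.label!r}: no sequences")
        n_cols = len(self.sequences[0])
        if n_cols < 2:
            raise NotAlignedError(
                f"group {self.label!r}: alignments need at least 2 columns, got {n_cols}"
            )
        bad = [k for k, s in enumerate(self.sequences) if len(s) != n_cols]
        if bad:
            ids = [self.ids[k] if self.ids else str(k) for k in bad]
            raise NotAlignedError(
                f"group {self.label!r}: not aligned, records with deviating "
                f"length: {', '.join(ids)}"
            )

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0])

    def with_display(self, label: str | None = None, color: str | None = None) -> "AlignmentGroup":
        """Return a copy with label and/or color replaced."""
        return AlignmentGroup(
            label=label if label is not None else self.label,
            color=color if color is not None else self.color,
            sequences=self.sequences,
            ids=self.ids,
        )


@dataclass
class ValidationReport:
    """Outcome of cross-group compatibility checks."""

    ok: bool
    n_columns: int
    messages: list[str] = field(default_factory=list)


def read_alignment_fasta(
    path: str | Path,
    alphabet: Iterable[str] | None = None,
    *,
    label: str | None = None,
    color: str = "",
    dot_as_gap: bool = False,
) -> AlignmentGroup:
    """Read one aligned FASTA file into an :class:`AlignmentGroup`.

    ``alphabet`` is the set of accepted residue symbols (typically
    ``scheme.accepted_symbols``); the gap ``-`` is always accepted.  When
    ``alphabet`` is None only alignment structure is validated.  ``.`` is
    rejected unless ``dot_as_gap`` maps it to ``-``.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise NoSequencesError(f"{path}: no sequences")

    accepted = None if alphabet is None else {c.upper() for c in alphabet} | {GAP}
    ids: list[str] = []
    seqs: list[str] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            warnings.warn(f"{path}: duplicate record id {rec.id!r}", stacklevel=2)
        seen.add(rec.id)
        s = str(rec.seq).upper()
        if dot_as_gap:
            s = s.replace(".", GAP)
        if accepted is not None:
            for col, ch in enumerate(s):
                if ch not in accepted:
                    raise UnknownResidueError(
                        f"{path}: unknown residue {ch!r} in record {rec.id!r}, "
                        f"column {col + 1}"
                    )
        ids.append(rec.id)
        seqs.append(s)

    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        bad = [i for i, s in zip(ids, seqs) if len(s) != len(seqs[0])]
        raise NotAlignedError(
            f"{path}: not aligned, records with deviating length: {', '.join(bad)}"
        )

    return AlignmentGroup(
        label=label if label is not None else path.stem,
        color=color,
        sequences=tuple(seqs),
        ids=tuple(ids),
    )


def write_alignment_fasta(group: AlignmentGroup, path: str | Path) -> None:
    """Write a group back to FASTA, preserving record order and ids."""
    ids = group.ids if group.ids else tuple(f"seq{k}" for k in range(group.n_sequences))
    records = [
        SeqRecord(Seq(s), id=i, description="") for i, s in zip(ids, group.sequences)
    ]
    SeqIO.write(records, str(path), "fasta-2line")


def validate_group_set(groups: Sequence[AlignmentGroup]) -> ValidationReport:
    """Check that groups can share one diagram.

    Overlaying requires a common x-axis, so all groups must have identical
    column counts; duplicated labels or colors are reported as warnings,
    not errors.
    """
    if not groups:
        raise ValueError("need at least one group")
    n_cols = {g.n_columns for g in groups}
    if len(n_cols) > 1:
        detail = ", ".join(f"{g.label}={g.n_columns}" for g in groups)
        raise IncompatibleAlignmentsError(f"incompatible alignments: {detail}")

    report = ValidationReport(ok=True, n_columns=groups[0].n_columns)
    labels = [g.label for g in groups]
    if len(set(labels)) != len(labels):
        report.messages.append("duplicate group labels")
    colors = [g.color for g in groups if g.color]
    if len(set(colors)) != len(colors):
        report.messages.append("duplicate group colors")
    for msg in report.messages:
        warnings.warn(msg, stacklevel=2)
    return report
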