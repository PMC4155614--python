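"""Synthetic aligned-group generator.

Emulates the structure of curated protein-family alignments such as the
adenylate kinase lid (AKL) domain: strong per-column conservation around a
modal sequence, a minority background spread over the remaining residues,
and optionally a subgroup of sequences whose modal path is shifted by a
fixed column offset — the "out of phase" parallel path that a comparative
diagram should reveal.  Columns are sampled independently; no
phylogenetic substitution model is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .msa_io import AlignmentGroup, write_alignment_fasta

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")

#: Modal 40-column sequences for the two demo samples.  Position 5 is P and
#: position 6 is A in both; the samples differ at positions 24 and 30, the
#: kind of single-column split that separates two subfamilies in an overlay.
AKL_MODAL_A = "GDIKPAVEQMTRLSAEKGFWDNLYHRCITVAPGSEDKMLQ"
AKL_MODAL_B = "GDIKPAVEQMTRLSAEKGFWDNLFHRCITIAPGSEDKMLQ"

#: Default study conditions for the two-sample demo fixture.
AKL_N_SEQUENCES = 500
AKL_MODAL_P = 0.85
AKL_SUBGROUP_FRACTION = 0.20
AKL_SUBGROUP_OFFSET = 1
AKL_SUBGROUP_START = 19  # 1-based column where the offset begins
AKL_SEED = 20140828


@dataclass(frozen=True)
class ConservationProfile:
    """Column-wise sampling model for one synthetic sample.

    Each column draws the modal residue with probability
    ``modal_probability`` and otherwise a uniform draw from ``background``
    minus that column's modal residue.  A ``subgroup_fraction`` of the
    sequences follows a modal path shifted by ``subgroup_offset`` columns
    starting at 1-based column ``subgroup_start``; where the shifted index
    falls outside the alignment the column is filled from the background.
    """

    n_columns: int
    modal_residues: str
    modal_probability: float = 0.85
    background: tuple = AMINO_ACIDS
    subgroup_fraction: float = 0.0
    subgroup_offset: int = 0
    subgroup_start: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.modal_residues) != self.n_columns:
            raise ValueError("modal_residues length must equal n_columns")
        lo = 1.0 / len(self.background)
        if not lo <= self.modal_probability <= 1.0:
            raise ValueError(
                f"modal_probability must be in [{lo:.3g}, 1], "
                f"got {self.modal_probability}"
            )
        if not 0.0 <= self.subgroup_fraction < 1.0:
            raise ValueError("subgroup_fraction must be in [0, 1)")
        if abs(self.subgroup_offset) >= self.n_columns:
            raise ValueError("|subgroup_offset| must be < n_columns")
        if not 1 <= self.subgroup_start <= self.n_columns:
            raise ValueError("subgroup_start is a 1-based column index")


def _sample_column(
    rng: np.random.Generator, n: int, modal: str | None, p: float, background: tuple
) -> np.ndarray:
    """Sample one column for ``n`` sequences; ``modal=None`` means
    background-only."""
    bg = [r for r in background if r != modal]
    draws = rng.choice(np.array(bg), size=n)
    if modal is None:
        return draws
    is_modal = rng.random(n) < p
    draws[is_modal] = modal
    return draws


def generate_group(
    profile: ConservationProfile,
    n_sequences: int,
    label: str,
    *,
    color: str = "",
) -> AlignmentGroup:
    """Sample an aligned group from a conservation profile.

    The last ``round(subgroup_fraction * n_sequences)`` sequences form the
    shifted subgroup.  A fixed profile seed gives identical output across
    calls.
    """
    if n_sequences < 1:
        raise ValueError("n_sequences must be >= 1")
    rng = np.random.default_rng(profile.seed)
    n_sub = int(round(profile.subgroup_fraction * n_sequences))
    n_main = n_sequences - n_sub
    L = profile.n_columns
    modal = profile.modal_residues

    cols = []
    for j in range(L):
        main = _sample_column(
            rng, n_main, modal[j], profile.modal_probability, profile.background
        )
        if n_sub:
            if j >= profile.subgroup_start - 1:
                src = j - profile.subgroup_offset
                m = modal[src] if 0 <= src < L else None
            else:
                m = modal[j]
            sub = _sample_column(
                rng, n_sub, m, profile.modal_probability, profile.background
            )
            cols.append(np.concatenate([main, sub]))
        else:
            cols.append(main)
    mat = np.stack(cols, axis=1)
    seqs = tuple("".join(row) for row in mat)
    ids = tuple(f"{label}_{k:04d}" for k in range(n_sequences))
    return AlignmentGroup(label=label, color=color, sequences=seqs, ids=ids)


def akl_like_profiles(
    seed: int = AKL_SEED,
) -> tuple[ConservationProfile, ConservationProfile]:
    """The two demo profiles: sample A clean, sample B carrying a 20%
    subgroup offset by +1 column from column 19."""
    prof_a = ConservationProfile(
        n_columns=len(AKL_MODAL_A),
        modal_residues=AKL_MODAL_A,
        modal_probability=AKL_MODAL_P,
        seed=seed,
    )
    prof_b = ConservationProfile(
        n_columns=len(AKL_MODAL_B),
        modal_residues=AKL_MODAL_B,
        modal_probability=AKL_MODAL_P,
        subgroup_fraction=AKL_SUBGROUP_FRACTION,
        subgroup_offset=AKL_SUBGROUP_OFFSET,
        subgroup_start=AKL_SUBGROUP_START,
        seed=seed + 1,
    )
    return prof_a, prof_b


def akl_like_groups(
    seed: int = AKL_SEED, n_sequences: int = AKL_N_SEQUENCES
) -> tuple[AlignmentGroup, AlignmentGroup]:
    """Generate the two-sample demo alignment pair."""
    prof_a, prof_b = akl_like_profiles(seed)
    group_a = generate_group(prof_a, n_sequences, "sample_a")
    group_b = generate_group(prof_b, n_sequences, "sample_b")
    return group_a, group_b


def write_demo_fasta(
    outdir: str | Path,
    seed: int = AKL_SEED,
    n_sequences: int = AKL_N_SEQUENCES,
) -> tuple[Path, Path]:
    """Write the demo pair as aligned FASTA files; returns the two paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    group_a, group_b = akl_like_groups(seed, n_sequences)
    path_a = outdir / "sample_a.fasta"
    path_b = outdir / "sample_b.fasta"
    write_alignment_fasta(group_a, path_a)
    write_alignment_fasta(group_b, path_b)
    return path_a, path_b
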