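from pathlib import Path

import pytest

from seqdiv import (
    DiagramConfig,
    default_protein_scheme,
    filter_transitions,
    read_alignment_fasta,
    transition_frequencies,
)

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def protein_scheme():
    return default_protein_scheme()


@pytest.fixture(scope="session")
def config():
    return DiagramConfig()


@pytest.fixture
def toy_fasta(tmp_path):
    """Four 2-column records: P-A three times, L-P once."""
    p = tmp_path / "toy.fasta"
    p.write_text(">a\nPA\n>b\nPA\n>c\nLP\n>d\nPA\n")
    return p


@pytest.fixture
def toy_group(toy_fasta, protein_scheme):
    return read_alignment_fasta(toy_fasta, protein_scheme.accepted_symbols)


@pytest.fixture(scope="session")
def demo_groups(protein_scheme):
    """The committed two-sample demo alignments (sample B carries the
    offset subgroup)."""
    a = read_alignment_fasta(DATA / "sample_a.fasta", protein_scheme.accepted_symbols)
    b = read_alignment_fasta(DATA / "sample_b.fasta", protein_scheme.accepted_symbols)
    return a, b


@pytest.fixture(scope="session")
def demo_filtered(demo_groups, protein_scheme):
    """Filtered transition tables for the demo pair at the 1% default."""
    return tuple(
        filter_transitions(transition_frequencies(g, protein_scheme), 0.01)
        for g in demo_groups
    )
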