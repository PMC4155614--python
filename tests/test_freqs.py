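"""Frequency counting, entropy / information content, and the filter."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from seqdiv import (
    AlignmentGroup,
    chain_survives,
    dominant_transition,
    filter_transitions,
    information_content,
    position_frequencies,
    shannon_entropy,
    surviving_chains,
    transition_frequencies,
)
from seqdiv.scheme import GAP, default_protein_scheme

SCHEME = default_protein_scheme()


def group_of(*seqs):
    return AlignmentGroup("g", "", tuple(seqs))


def naive_pair_counts(group, scheme):
    """Independent oracle: explicit double loop over sequences and columns."""
    out = {}
    for s in group.sequences:
        for i in range(len(s) - 1):
            key = (i, scheme.canonical(s[i]), scheme.canonical(s[i + 1]))
            out[key] = out.get(key, 0) + 1
    return out


# ---------------------------------------------------------------- positions

def test_toy_column_frequencies(toy_group, protein_scheme):
    pft = position_frequencies(toy_group, protein_scheme)
    assert pft.rel_freq[(0, "P")] == 0.75
    assert pft.rel_freq[(0, "L")] == 0.25
    assert pft.rel_freq[(1, "A")] == 0.75
    assert pft.rel_freq[(0, "W")] == 0.0  # absent residues carry zeros


def test_constant_and_all_gap_columns():
    pft = position_frequencies(group_of("PP", "PP"), SCHEME)
    assert pft.rel_freq[(0, "P")] == 1.0
    pft = position_frequencies(group_of("P-", "P-"), SCHEME)
    assert pft.rel_freq[(1, GAP)] == 1.0


def test_column_sums_equal_n_and_one(demo_groups, protein_scheme):
    g = demo_groups[0]
    pft = position_frequencies(g, protein_scheme)
    for i in range(g.n_columns):
        assert sum(pft.column_counts(i).values()) == g.n_sequences
        assert math.isclose(sum(pft.column_freqs(i).values()), 1.0, abs_tol=1e-9)


# -------------------------------------------------------------- transitions

def test_toy_pair_counts_and_freqs(toy_group, protein_scheme):
    tt = transition_frequencies(toy_group, protein_scheme)
    assert tt.pair_counts == {(0, "P", "A"): 3, (0, "L", "P"): 1}
    assert tt.pair_freq[(0, "P", "A")] == 0.75
    assert tt.pair_freq[(0, "L", "P")] == 0.25


def test_single_sequence_all_pairs_are_certain():
    tt = transition_frequencies(group_of("PAK"), SCHEME)
    assert set(tt.pair_freq.values()) == {1.0}


def test_combined_denominator_policy(toy_group, protein_scheme):
    tt = transition_frequencies(
        toy_group, protein_scheme, denominator_policy="combined", combined_total=8
    )
    assert tt.pair_freq[(0, "P", "A")] == 3 / 8


def test_gap_pairs_counted_or_excluded():
    g = group_of("P-", "PA")
    with_gaps = transition_frequencies(g, SCHEME)
    assert with_gaps.pair_counts[(0, "P", GAP)] == 1
    without = transition_frequencies(g, SCHEME, include_gap_pairs=False)
    assert (0, "P", GAP) not in without.pair_counts


@st.composite
def random_alignments(draw):
    n_cols = draw(st.integers(2, 20))
    n_seqs = draw(st.integers(1, 50))
    alphabet = "ACDEFGHIKLMNPQRSTVWY-"
    seqs = draw(
        st.lists(
            st.text(alphabet, min_size=n_cols, max_size=n_cols),
            min_size=n_seqs, max_size=n_seqs,
        )
    )
    return AlignmentGroup("r", "", tuple(seqs))


@given(random_alignments())
@settings(max_examples=100, deadline=None, derandomize=True)
def test_pair_counts_match_naive_double_loop(group):
    tt = transition_frequencies(group, SCHEME)
    assert tt.pair_counts == naive_pair_counts(group, SCHEME)


@given(random_alignments())
@settings(max_examples=100, deadline=None, derandomize=True)
def test_marginal_consistency(group):
    pft = position_frequencies(group, SCHEME)
    tt = transition_frequencies(group, SCHEME)
    for i in range(group.n_columns - 1):
        for a in pft.rows:
            left = sum(
                c for (j, x, _), c in tt.pair_counts.items() if j == i and x == a
            )
            assert left == pft.counts[(i, a)]
            right = sum(
                c for (j, _, y), c in tt.pair_counts.items() if j == i and y == a
            )
            assert right == pft.counts[(i + 1, a)]
        assert sum(
            c for (j, _, _), c in tt.pair_counts.items() if j == i
        ) == group.n_sequences


@given(random_alignments(), st.randoms(use_true_random=False))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_tables_invariant_under_sequence_permutation(group, rnd):
    shuffled = list(group.sequences)
    rnd.shuffle(shuffled)
    g2 = AlignmentGroup("r", "", tuple(shuffled))
    assert transition_frequencies(g2, SCHEME).pair_counts == \
        transition_frequencies(group, SCHEME).pair_counts
    assert position_frequencies(g2, SCHEME).counts == \
        position_frequencies(group, SCHEME).counts


# ---------------------------------------------------- entropy / information

def test_entropy_closed_forms():
    uniform20 = {a: 1 / 20 for a in "ACDEFGHIKLMNPQRSTVWY"}
    assert math.isclose(shannon_entropy(uniform20), math.log2(20), abs_tol=1e-9)
    assert shannon_entropy({"P": 1.0}) == 0.0
    assert math.isclose(shannon_entropy({"P": 0.5, "A": 0.5}), 1.0, abs_tol=1e-9)


def test_entropy_rejects_improper_distributions():
    with pytest.raises(ValueError, match="sum"):
        shannon_entropy({"P": 0.6})
    with pytest.raises(ValueError, match="negative"):
        shannon_entropy({"P": 1.2, "A": -0.2})


@given(st.lists(st.floats(0.001, 1.0), min_size=2, max_size=20))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_entropy_bounded_by_uniform_and_zero_iff_constant(weights):
    total = sum(weights)
    freqs = {f"r{k}": w / total for k, w in enumerate(weights)}
    h = shannon_entropy(freqs)
    assert -1e-9 <= h <= math.log2(len(weights)) + 1e-9
    effective = [p for p in freqs.values() if p > 0]
    if len(effective) > 1:
        assert h > 0.0


def test_information_content_endpoints():
    uniform20 = {a: 1 / 20 for a in "ACDEFGHIKLMNPQRSTVWY"}
    assert math.isclose(information_content(uniform20, 20), 0.0, abs_tol=1e-9)
    assert math.isclose(
        information_content({"P": 1.0}, 20), math.log2(20), abs_tol=1e-9
    )


def test_information_content_small_sample_correction():
    expected = math.log2(20) - 19 / (2 * math.log(2) * 4)
    got = information_content({"P": 1.0}, 20, n_sequences=4, correction=True)
    assert math.isclose(got, expected, abs_tol=1e-9)
    with pytest.raises(ValueError, match="alphabet_size"):
        information_content({"P": 1.0}, 1)


# ------------------------------------------------------------------ filter

def test_filter_is_strict_less_than(toy_group, protein_scheme):
    tt = transition_frequencies(toy_group, protein_scheme)
    assert filter_transitions(tt, 0.0).pair_counts == tt.pair_counts
    # 0.25 sits exactly at the threshold and must survive
    assert (0, "L", "P") in filter_transitions(tt, 0.25).pair_freq
    assert (0, "L", "P") not in filter_transitions(tt, 0.2500001).pair_freq
    # nothing reaches 1.0 here, so everything goes
    assert filter_transitions(tt, 1.0).pair_counts == {}


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_filter_monotone_over_threshold_sweep(seed):
    import numpy as np

    rng = np.random.default_rng(seed)
    seqs = tuple(
        "".join(rng.choice(list("PALKG"), size=6)) for _ in range(30)
    )
    tt = transition_frequencies(AlignmentGroup("m", "", seqs), SCHEME)
    sizes = [
        len(filter_transitions(tt, t).pair_counts)
        for t in sorted(rng.uniform(0, 1, size=8))
    ]
    assert sizes == sorted(sizes, reverse=True)


# ------------------------------------------------------- dominant / chains

def test_dominant_transition_toy(toy_group, protein_scheme):
    tt = transition_frequencies(toy_group, protein_scheme)
    dom = dominant_transition(tt, 0)
    assert dom.pair == ("P", "A") and dom.freq == 0.75 and not dom.tie


def test_dominant_tie_breaks_alphabetically():
    tt = transition_frequencies(group_of("PA", "LP"), SCHEME)
    dom = dominant_transition(tt, 0)
    assert dom.pair == ("L", "P") and dom.tie


def test_dominant_on_empty_junction_raises(toy_group, protein_scheme):
    tt = filter_transitions(
        transition_frequencies(toy_group, protein_scheme), 1.0
    )
    with pytest.raises(ValueError, match="no transitions"):
        dominant_transition(tt, 0)


def test_surviving_chains_enumerates_unbroken_paths():
    g = group_of(*(["PAK"] * 8 + ["LGK"] * 2))
    tt = transition_frequencies(g, SCHEME)
    chains = surviving_chains(tt, 0, 2)
    assert (("P", "A", "K"), 0.8) in chains
    assert (("L", "G", "K"), 0.2) in chains
    assert chain_survives(tt, "PAK", 0)
    assert not chain_survives(tt, "PGK", 0)
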