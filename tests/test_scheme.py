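"""Alphabet schemes, grouping invariants and config round-trips."""

import pytest
from hypothesis import given, settings, strategies as st

from seqdiv import (
    AlphabetScheme,
    DiagramConfig,
    Geometry,
    default_nucleotide_scheme,
    default_protein_scheme,
    load_config,
    write_config,
)
from seqdiv.errors import AmbiguousGroupingError, ConfigError
from seqdiv.scheme import GAP, OTHER, parse_color


def test_protein_scheme_partitions_all_twenty_residues(protein_scheme):
    flat = [r for _, rs in protein_scheme.groups for r in rs]
    assert sorted(flat) == sorted("ACDEFGHIKLMNPQRSTVWY")
    assert len(flat) == len(set(flat)) == 20


def test_protein_grouping_follows_side_chain_chemistry(protein_scheme):
    by_residue = {
        r: lbl for lbl, rs in protein_scheme.groups for r in rs
    }
    assert by_residue["K"] == by_residue["R"]          # both basic
    assert by_residue["P"] != by_residue["A"]          # special vs aliphatic
    assert by_residue["D"] == by_residue["E"] == "negative"


def test_row_order_is_stable_and_ends_with_other_and_gap(protein_scheme):
    assert protein_scheme.rows == default_protein_scheme().rows
    assert protein_scheme.rows[-2:] == (OTHER, GAP)


def test_nucleotide_scheme_purine_pyrimidine():
    s = default_nucleotide_scheme()
    d = {r: lbl for lbl, rs in s.groups for r in rs}
    assert d["A"] == d["G"] == "purine"
    assert d["C"] == d["T"] == d["U"] == "pyrimidine"
    rna = default_nucleotide_scheme(rna=True)
    assert "T" not in rna.alphabet and "U" in rna.alphabet
    merged = default_nucleotide_scheme(merge_tu=True)
    assert "U" not in merged.alphabet


def test_canonical_maps_ambiguity_to_other_row(protein_scheme):
    assert protein_scheme.canonical("x") == OTHER
    assert protein_scheme.canonical("-") == GAP
    assert protein_scheme.canonical("p") == "P"
    with pytest.raises(KeyError):
        protein_scheme.canonical("1")


def test_residue_in_two_groups_is_rejected():
    with pytest.raises(AmbiguousGroupingError, match="ambiguous grouping"):
        AlphabetScheme(groups=(("g1", ("P", "A")), ("g2", ("P",))))


@given(
    st.permutations(list("ACDEFGHIKLMNPQRSTVWY")),
    st.lists(st.integers(1, 19), min_size=1, max_size=6),
)
@settings(max_examples=50, deadline=None)
def test_random_groupings_satisfy_partition_invariant(perm, cuts):
    bounds = sorted({0, 20, *[c for c in cuts if c < 20]})
    groups = tuple(
        (f"g{k}", tuple(perm[lo:hi]))
        for k, (lo, hi) in enumerate(zip(bounds, bounds[1:]))
    )
    s = AlphabetScheme(groups=groups, ambiguity_symbols=frozenset())
    flat = [r for _, rs in s.groups for r in rs]
    assert sorted(flat) == sorted("ACDEFGHIKLMNPQRSTVWY")
    assert all(s.canonical(r) == r for r in flat)


def test_empty_config_gives_protein_defaults(tmp_path):
    p = tmp_path / "empty.yml"
    p.write_text("")
    scheme, cfg = load_config(p)
    assert scheme.alphabet == default_protein_scheme().alphabet
    assert cfg.filter_threshold == 0.01


def test_threshold_overrides_and_bounds(tmp_path):
    p = tmp_path / "c.yml"
    p.write_text("filter:\n  threshold: 0\n")
    _, cfg = load_config(p)
    assert cfg.filter_threshold == 0.0
    p.write_text("filter:\n  threshold: 1.5\n")
    with pytest.raises(ConfigError, match="threshold"):
        load_config(p)


def test_duplicated_residue_in_config_groups_errors(tmp_path):
    p = tmp_path / "c.yml"
    p.write_text("groups:\n  one: [P, A]\n  two: [P]\n")
    with pytest.raises(AmbiguousGroupingError):
        load_config(p)


def test_unknown_key_warns_but_loads(tmp_path):
    p = tmp_path / "c.yml"
    p.write_text("no_such_key: 1\n")
    with pytest.warns(UserWarning, match="unknown config key"):
        scheme, cfg = load_config(p)
    assert cfg.filter_threshold == 0.01


def test_config_round_trip(tmp_path):
    scheme = default_nucleotide_scheme(rna=True)
    cfg = DiagramConfig(
        filter_threshold=0.05,
        group_colors=(("x", ("#d62728", 0.5)), ("y", ("#1f77b4", 0.25))),
        geometry=Geometry(column_spacing=30.0, group_gap=9.0),
        masked_positions=frozenset({3, 7}),
        output_format="png",
        denominator_policy="combined",
        include_gap_pairs=False,
    )
    p = tmp_path / "rt.yml"
    write_config(scheme, cfg, p)
    scheme2, cfg2 = load_config(p)
    assert scheme2 == scheme
    assert cfg2 == cfg


def test_color_token_parsing():
    assert parse_color("#D62728") == ("#d62728", 0.5)
    hex6, alpha = parse_color("#1f77b4ff")
    assert hex6 == "#1f77b4" and alpha == 1.0
    with pytest.raises(ConfigError):
        parse_color("red")
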