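"""Species-tree parsing, lineage counting and lifestyle propagation."""

import io

import numpy as np
import pytest

from orcevo.simulate import simulate_species_tree
from orcevo.trees import (
    AnnotationError,
    NewickParseError,
    count_lineages,
    parse_newick,
    propagate_lifestyle,
    read_annotations,
    write_annotations,
    write_newick,
)


@pytest.mark.parametrize(
    "newick, n_leaves, n_nodes",
    [
        ("((A,B),C);", 3, 5),
        ("(A);", 1, 2),  # degenerate single-leaf tree
        ("((A,B,C),D);", 4, 6),  # multifurcation preserved
        ("(((A,B),(C,D)),(E,F));", 6, 11),
    ],
)
def test_parse_structure(newick, n_leaves, n_nodes):
    tree = parse_newick(newick)
    assert len(tree.leaves()) == n_leaves
    assert tree.n_nodes() == n_nodes


@pytest.mark.parametrize(
    "bad",
    ["((A,B),C;", "((A,B),A);", "", "(A,B))C;("],
)
def test_parse_errors(bad):
    with pytest.raises(NewickParseError):
        parse_newick(bad)


def test_parse_error_names_duplicate_label():
    with pytest.raises(NewickParseError, match="A"):
        parse_newick("((A,B),A);")


def test_roundtrip_random_trees():
    """parse(write(T)) reproduces T exactly for 1000 seeded random trees."""
    rng = np.random.default_rng(7)
    for _ in range(1000):
        n = int(rng.integers(2, 20))
        tree = simulate_species_tree(n, rng)
        text = write_newick(tree)
        again = parse_newick(text)
        assert write_newick(again) == text
        assert again.n_nodes() == tree.n_nodes()


@pytest.mark.parametrize(
    "newick, expected",
    [
        ("((A,B),C);", 5),  # 2n-1 for binary
        ("((A,B,C),D);", 6),  # trifurcation: one fewer node than binary
    ],
)
def test_lineage_count(newick, expected):
    tree = parse_newick(newick)
    assert len(count_lineages(tree)) == expected


def test_132_taxa_gives_263_lineages():
    tree = simulate_species_tree(132, 0)
    assert len(count_lineages(tree)) == 263


def test_lifestyle_propagation_rule():
    # ancestor of an all-parasite clade is parasitic; root is not
    tree = parse_newick("((P1,P2),F);")
    propagate_lifestyle(tree, ["P1", "P2"])
    flags = {tree.node_id(n): n.parasitic for n in tree.preorder()}
    assert flags["P1..P2"] is True
    assert tree.root.parasitic is not True
    # a clade mixing lifestyles stays non-parasitic
    tree = parse_newick("((P1,F),P2);")
    propagate_lifestyle(tree, ["P1", "P2"])
    assert not any(n.parasitic for n in tree.preorder() if not n.is_leaf)
    # universal parasitism reaches the root
    tree = parse_newick("((P1,P2),P3);")
    propagate_lifestyle(tree, ["P1", "P2", "P3"])
    assert all(n.parasitic for n in tree.preorder())


def test_lifestyle_propagation_idempotent():
    rng = np.random.default_rng(3)
    tree = simulate_species_tree(12, rng)
    labels = tree.leaf_labels()
    para = [lb for lb in labels if rng.random() < 0.5]
    propagate_lifestyle(tree, para)
    first = {tree.node_id(n): n.parasitic for n in tree.preorder()}
    propagate_lifestyle(tree, para)
    second = {tree.node_id(n): n.parasitic for n in tree.preorder()}
    assert first == second


def test_propagate_unknown_leaf_listed():
    tree = parse_newick("((A,B),C);")
    with pytest.raises(AnnotationError, match="Zzz"):
        propagate_lifestyle(tree, ["A", "Zzz"])


def test_annotation_sidecar_roundtrip():
    tree = parse_newick("((A,B),C);")
    propagate_lifestyle(tree, ["A", "B"])
    tree.leaf("A").centrioles = True
    tree.node_by_id("A..B").wgd = "reported"
    tree.node_by_id("C").wgd = "uncertain"
    text = write_annotations(tree)
    tree2 = parse_newick("((A,B),C);")
    read_annotations(tree2, io.StringIO(text))
    assert write_annotations(tree2) == text
    ls = count_lineages(tree2)
    assert ls.parasitic == {"A", "B", "A..B"}
    assert ls.wgd == {"A..B"}  # 'uncertain' excluded by default
    assert count_lineages(tree2, include_uncertain_wgd=True).wgd == {"A..B", "C"}


def test_annotation_unknown_node_rejected():
    tree = parse_newick("((A,B),C);")
    text = "node_id\tparasitic\twgd\tcentrioles\nNOPE\t1\tnone\tNA\n"
    with pytest.raises(AnnotationError, match="NOPE"):
        read_annotations(tree, io.StringIO(text))


def test_internal_node_ids_unique_and_stable():
    tree = parse_newick("((((A,D),B),C),E);")
    ids = [tree.node_id(n) for n in tree.preorder()]
    assert len(set(ids)) == len(ids)
    # nested clades sharing extreme labels are disambiguated by clade size
    assert "A..D..2" in ids and "A..D..3" in ids


def test_reroot_on_edge():
    tree = parse_newick("((A,B),(C,D));")
    out = tree.reroot_on_edge("A")
    assert set(out.leaf_labels()) == {"A", "B", "C", "D"}
    assert out.root.children[0].label == "A"
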