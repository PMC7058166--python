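"""Duplication/loss parsimony: worked examples, oracle equivalence, replay."""

import numpy as np
import pytest

from helpers import brute_force_min_events
from orcevo.reconcile import (
    ConstraintSet,
    EventMap,
    InfeasibleConstraints,
    ReplayError,
    TerminalDuplications,
    ForbiddenDuplicationClade,
    infer_events,
    merge_event_maps,
    read_constraints,
    replay_events,
    tally_events,
    write_events_tsv,
    read_events_tsv,
)
from orcevo.simulate import simulate_species_tree
from orcevo.trees import count_lineages, parse_newick


def test_whole_clade_absence_is_one_stem_loss():
    """A family absent from a clade is lost once on the clade's stem."""
    tree = parse_newick("(((Ehis,Enut),Einv),Out);")
    em = infer_events(
        tree, {"Ehis": 0, "Enut": 0, "Einv": 0, "Out": 1}, root_count=1
    )
    assert em.n_events == 1
    assert em.losses == {"Ehis..Enut..3": 1}  # stem of the three-species clade
    assert replay_events(tree, 1, em) == {"Ehis": 0, "Enut": 0, "Einv": 0, "Out": 1}


def test_species_specific_paralog_constraint():
    tree = parse_newick("((Cang,Amac),Out);")
    counts = {"Cang": 2, "Amac": 2, "Out": 1}
    # unconstrained: one ancestral duplication beats two terminal ones
    free = infer_events(tree, counts, root_count=1)
    assert free.duplications == {"Amac..Cang": 1} and free.n_events == 1
    # asserting species-specific paralogs forces two terminal duplications
    cset = ConstraintSet(
        (
            TerminalDuplications("ORC4", "Cang", 1),
            TerminalDuplications("ORC4", "Amac", 1),
        )
    )
    pinned = infer_events(tree, counts, root_count=1, constraints=cset, family="ORC4")
    assert pinned.duplications == {"Cang": 1, "Amac": 1} and pinned.n_events == 2


def test_no_change_means_no_events():
    tree = parse_newick("((A,B),(C,D));")
    em = infer_events(tree, dict.fromkeys("ABCD", 2), root_count=2)
    assert em.n_events == 0
    assert replay_events(tree, 2, em) == dict.fromkeys("ABCD", 2)


def test_forbidden_stem_duplication_moves_events():
    tree = parse_newick("((A,B),C);")
    counts = {"A": 2, "B": 2, "C": 1}
    free = infer_events(tree, counts, root_count=1)
    assert free.duplications == {"A..B": 1}
    cset = ConstraintSet(
        forbidden_duplication_clades=(ForbiddenDuplicationClade("F", "A..B"),)
    )
    forced = infer_events(tree, counts, root_count=1, constraints=cset, family="F")
    assert forced.duplications == {"A": 1, "B": 1}


def test_infeasible_constraint_reported():
    tree = parse_newick("((A,B),C);")
    cset = ConstraintSet((TerminalDuplications("F", "A", 5),))
    with pytest.raises(InfeasibleConstraints):
        infer_events(tree, {"A": 1, "B": 1, "C": 1}, root_count=1,
                     constraints=cset, family="F")


def test_constraints_never_decrease_event_count():
    rng = np.random.default_rng(11)
    for _ in range(50):
        tree = simulate_species_tree(int(rng.integers(3, 7)), rng)
        counts = {lb: int(rng.integers(0, 4)) for lb in tree.leaf_labels()}
        candidates = [lb for lb, c in counts.items() if c >= 2]
        if not candidates:
            continue
        free = infer_events(tree, counts, root_count=1)
        cset = ConstraintSet((TerminalDuplications("F", candidates[0], 1),))
        try:
            pinned = infer_events(tree, counts, root_count=1,
                                  constraints=cset, family="F")
        except InfeasibleConstraints:
            continue
        assert pinned.n_events >= free.n_events


def test_dp_matches_exhaustive_minimization():
    """DP optimum equals brute-force enumeration on 200 random instances."""
    rng = np.random.default_rng(5)
    for _ in range(200):
        n = int(rng.integers(2, 7))
        tree = simulate_species_tree(n, rng)
        counts = {lb: int(rng.integers(0, 4)) for lb in tree.leaf_labels()}
        root = int(rng.integers(1, 4))
        em = infer_events(tree, counts, root_count=root)
        assert em.n_events == brute_force_min_events(tree, counts, root)
        assert replay_events(tree, root, em) == counts


def test_replay_guards():
    tree = parse_newick("((A,B),C);")
    bad = EventMap(family=None, root_count=1, losses={"A": 2})
    with pytest.raises(ReplayError, match="A"):
        replay_events(tree, 1, bad)
    stray = EventMap(family=None, root_count=1, losses={"NOPE": 1})
    with pytest.raises(ReplayError, match="NOPE"):
        replay_events(tree, 1, stray)
    empty = EventMap(family=None, root_count=3)
    assert replay_events(tree, 3, empty) == {"A": 3, "B": 3, "C": 3}


def test_tally_and_merge():
    tree = parse_newick("((P1,P2),F);")
    from orcevo.trees import propagate_lifestyle

    propagate_lifestyle(tree, ["P1", "P2"])
    lineages = count_lineages(tree)
    m1 = EventMap(family="ORC2", root_count=1, losses={"P1..P2": 1})
    m2 = EventMap(family="ORC3", root_count=1, duplications={"F": 2})
    tally = tally_events({"ORC2": m1, "ORC3": m2}, lineages)
    assert tally.per_family == {"ORC2": (1, 0), "ORC3": (0, 2)}
    assert (tally.total_losses, tally.total_duplications) == (1, 2)
    assert tally.class_tallies["parasitic"] == {"losses": 1, "duplications": 0}
    merged = merge_event_maps([m1, m2])
    assert merged.n_losses == 1 and merged.n_duplications == 2


def test_events_tsv_roundtrip(tmp_path):
    m = EventMap(family="ORC2", root_count=1,
                 losses={"X": 1}, duplications={"Y": 2})
    path = str(tmp_path / "events.tsv")
    write_events_tsv({"ORC2": m}, path)
    again = read_events_tsv(path, {"ORC2": 1})
    assert again["ORC2"].losses == m.losses
    assert again["ORC2"].duplications == m.duplications


def test_constraints_yaml(tmp_path):
    path = tmp_path / "c.yaml"
    path.write_text(
        "terminal_duplications:\n"
        "  - {family: ORC4, taxon: Cang, min_dups: 1}\n"
        "forbidden_duplication_clades:\n"
        "  - {family: ORC4, clade: Amac..Cang}\n"
    )
    cset = read_constraints(str(path))
    assert cset.terminal_duplications[0].taxon == "Cang"
    assert cset.for_family("ORC2") == ConstraintSet()
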