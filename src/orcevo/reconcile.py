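"""Minimal duplication/loss histories for gene-family copy numbers.

Given a rooted species tree, the copy number of one gene family in every
extant species, and the copy number at the root, this module infers the
smallest set of single-copy gain (duplication) and single-copy loss events
that explains the leaf counts — the algorithmic form of mapping family
expansions and contractions onto a species tree by parsimony.

The model is Dollo-like on presence and free on copy number:

* the family originates once, at the root (origin events are not counted);
* once a lineage reaches zero copies the family is never regained below it;
* along any branch the copy number may change by any integer amount; a
  change of +k counts as k duplication events, -k as k loss events.

The optimum is found with a Sankoff-style dynamic program over copy-number
states ``0 .. max(leaf count, root count) + 1`` with edge cost
``|parent - child|`` and the Dollo restriction that a zero-copy parent
cannot have a positive-copy child.  Among co-optimal histories the
backtrack prefers the *smallest* ancestral copy number, which places
duplications as late (tipward) as possible and losses as early (rootward)
as possible — e.g. a family absent from a whole clade is lost once on the
clade's stem, and species-specific paralogs stay on terminal branches.

Gene-tree knowledge that parsimony alone cannot see enters through
:class:`ConstraintSet`: an assertion that a taxon's extra copies are
species-specific paralogs forces the duplications onto that terminal
branch, and a clade can be barred from ancestral duplications on its stem.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import yaml

from .trees import LineageSet, Node, SpeciesTree

__all__ = [
    "EventMap",
    "ConstraintSet",
    "TerminalDuplications",
    "ForbiddenDuplicationClade",
    "InfeasibleConstraints",
    "ReplayError",
    "infer_events",
    "replay_events",
    "tally_events",
    "merge_event_maps",
    "EventTally",
    "read_constraints",
    "read_events_tsv",
    "write_events_tsv",
]

INF = math.inf


class InfeasibleConstraints(ValueError):
    """No copy-number history satisfies the constraint set."""


class ReplayError(ValueError):
    """Replaying events produced a negative copy number."""


@dataclass(frozen=True)
class TerminalDuplications:
    """Assert that ``taxon`` carries at least ``min_dups`` duplications on
    its terminal branch for ``family`` (species-specific paralogs)."""

    family: str
    taxon: str
    min_dups: int = 1


@dataclass(frozen=True)
class ForbiddenDuplicationClade:
    """Forbid duplications on the stem branch of the clade ``clade_id`` for
    ``family``."""

    family: str
    clade_id: str


@dataclass(frozen=True)
class ConstraintSet:
    terminal_duplications: tuple[TerminalDuplications, ...] = ()
    forbidden_duplication_clades: tuple[ForbiddenDuplicationClade, ...] = ()

    def for_family(self, family: str | None) -> "ConstraintSet":
        if family is None:
            return self
        return ConstraintSet(
            tuple(t for t in self.terminal_duplications if t.family == family),
            tuple(f for f in self.forbidden_duplication_clades if f.family == family),
        )

    def __bool__(self) -> bool:
        return bool(self.terminal_duplications or self.forbidden_duplication_clades)


@dataclass
class EventMap:
    """Duplication and loss events per lineage for one family.

    ``duplications`` / ``losses`` map lineage id -> event count (>= 1 only;
    absent keys mean zero).  ``states`` records the inferred copy number at
    every node, so replaying the events is a lookup-free invariant check.
    """

    family: str | None
    root_count: int
    duplications: dict[str, int] = field(default_factory=dict)
    losses: dict[str, int] = field(default_factory=dict)
    states: dict[str, int] = field(default_factory=dict)

    @property
    def n_duplications(self) -> int:
        return sum(self.duplications.values())

    @property
    def n_losses(self) -> int:
        return sum(self.losses.values())

    @property
    def n_events(self) -> int:
        return self.n_duplications + self.n_losses

    def per_lineage(self, event_type: str) -> dict[str, int]:
        if event_type == "loss":
            return dict(self.losses)
        if event_type == "duplication":
            return dict(self.duplications)
        raise ValueError(f"bad event_type: {event_type!r}")


def merge_event_maps(maps: Iterable[EventMap]) -> EventMap:
    """Pool several families' events into one map (for enrichment tests)."""
    merged = EventMap(family=None, root_count=0)
    for m in maps:
        merged.root_count += m.root_count
        for lid, c in m.duplications.items():
            merged.duplications[lid] = merged.duplications.get(lid, 0) + c
        for lid, c in m.losses.items():
            merged.losses[lid] = merged.losses.get(lid, 0) + c
    return merged


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def infer_events(
    tree: SpeciesTree,
    leaf_counts: Mapping[str, int],
    root_count: int = 1,
    constraints: ConstraintSet | None = None,
    family: str | None = None,
) -> EventMap:
    """Infer a minimal duplication/loss history for one family.

    ``leaf_counts`` maps every leaf label to its copy number.  The returned
    :class:`EventMap` attains the minimum total event count among all
    ancestral copy-number assignments that satisfy the Dollo no-regain rule
    and every applicable constraint; ties are broken deterministically
    (smallest ancestral state, i.e. latest duplications).
    """
    constraints = (constraints or ConstraintSet()).for_family(family)
    leaves = tree.leaves()
    missing = [lf.label for lf in leaves if lf.label not in leaf_counts]
    if missing:
        raise ValueError("leaf_counts missing taxa: " + ", ".join(sorted(missing)))
    if root_count < 0 or any(leaf_counts[lf.label] < 0 for lf in leaves):
        raise ValueError("copy numbers must be non-negative")

    min_terminal: dict[str, int] = {}
    for tc in constraints.terminal_duplications:
        if tc.taxon not in tree.leaf_labels():
            raise InfeasibleConstraints(
                f"constraint references unknown taxon {tc.taxon!r}"
            )
        min_terminal[tc.taxon] = max(min_terminal.get(tc.taxon, 0), tc.min_dups)
    no_dup_stems: set[str] = set()
    for fc in constraints.forbidden_duplication_clades:
        tree.node_by_id(fc.clade_id)  # raises on unknown id
        no_dup_stems.add(fc.clade_id)

    max_state = max([root_count] + [leaf_counts[lf.label] for lf in leaves]) + 1
    states = range(max_state + 1)

    def edge_cost(parent_state: int, child: Node, child_state: int) -> float:
        if parent_state == 0 and child_state > 0:
            return INF  # Dollo: no regain below a zero-copy lineage
        if tree.node_id(child) in no_dup_stems and child_state > parent_state:
            return INF
        if child.is_leaf and child.label in min_terminal:
            if child_state - parent_state < min_terminal[child.label]:
                return INF
        return abs(parent_state - child_state)

    # bottom-up Sankoff pass
    cost: dict[int, list[float]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            c = leaf_counts[node.label]
            cost[id(node)] = [0.0 if s == c else INF for s in states]
        else:
            vec = []
            for s in states:
                tot = 0.0
                for child in node.children:
                    best = min(
                        cost[id(child)][cs] + edge_cost(s, child, cs) for cs in states
                    )
                    tot += best
                    if tot == INF:
                        break
                vec.append(tot)
            cost[id(node)] = vec

    if cost[id(tree.root)][root_count] == INF:
        detail = []
        if min_terminal:
            detail.append(f"terminal-duplication minima {min_terminal}")
        if no_dup_stems:
            detail.append(f"duplication-free stems {sorted(no_dup_stems)}")
        raise InfeasibleConstraints(
            f"no history with root count {root_count} satisfies the constraints"
            + (": " + "; ".join(detail) if detail else "")
        )

    # top-down backtrack; ties -> smallest state (latest duplications)
    events = EventMap(family=family, root_count=root_count)
    assignment: dict[int, int] = {id(tree.root): root_count}
    for node in tree.preorder():
        s = assignment[id(node)]
        events.states[tree.node_id(node)] = s
        for child in node.children:
            best = min(cost[id(child)][cs] + edge_cost(s, child, cs) for cs in states)
            chosen = next(
                cs
                for cs in states
                if cost[id(child)][cs] + edge_cost(s, child, cs) == best
            )
            assignment[id(child)] = chosen
            delta = chosen - s
            cid = tree.node_id(child)
            if delta > 0:
                events.duplications[cid] = delta
            elif delta < 0:
                events.losses[cid] = -delta
    return events


# ---------------------------------------------------------------------------
# Replay and tallies
# ---------------------------------------------------------------------------

def replay_events(
    tree: SpeciesTree, root_count: int, events: EventMap
) -> dict[str, int]:
    """Apply ``events`` along every root-to-leaf path; returns leaf counts.

    Raises :class:`ReplayError` if any lineage's count would drop below
    zero, naming the lineage.
    """
    known = {tree.node_id(n) for n in tree.preorder()}
    stray = (set(events.duplications) | set(events.losses)) - known
    if stray:
        raise ReplayError("events on unknown lineages: " + ", ".join(sorted(stray)))
    counts: dict[int, int] = {id(tree.root): root_count}
    out: dict[str, int] = {}
    for node in tree.preorder():
        if node is not tree.root:
            nid = tree.node_id(node)
            c = counts[id(node.parent)]
            c += events.duplications.get(nid, 0)
            c -= events.losses.get(nid, 0)
            if c < 0:
                raise ReplayError(
                    f"copy number drops below zero on lineage {nid!r}"
                )
            counts[id(node)] = c
        if node.is_leaf:
            out[node.label] = counts[id(node)]
    if tree.root.is_leaf:  # degenerate single-leaf tree
        out[tree.root.label] = root_count
    return out


@dataclass(frozen=True)
class EventTally:
    """Global and per-family duplication/loss totals, with lineage-class
    sub-tallies when a :class:`~orcevo.trees.LineageSet` is supplied."""

    per_family: dict[str, tuple[int, int]]  # family -> (losses, duplications)
    total_losses: int
    total_duplications: int
    class_tallies: dict[str, dict[str, int]]  # class -> {losses, duplications}


def tally_events(
    event_maps: Mapping[str, EventMap], lineages: LineageSet | None = None
) -> EventTally:
    """Sum events per family and globally; optionally split by lineage class."""
    per_family = {
        fam: (m.n_losses, m.n_duplications) for fam, m in event_maps.items()
    }
    total_losses = sum(l for l, _ in per_family.values())
    total_dups = sum(d for _, d in per_family.values())
    class_tallies: dict[str, dict[str, int]] = {}
    if lineages is not None:
        for cls, members in (("parasitic", lineages.parasitic), ("wgd", lineages.wgd)):
            losses = sum(
                c
                for m in event_maps.values()
                for lid, c in m.losses.items()
                if lid in members
            )
            dups = sum(
                c
                for m in event_maps.values()
                for lid, c in m.duplications.items()
                if lid in members
            )
            class_tallies[cls] = {"losses": losses, "duplications": dups}
    return EventTally(per_family, total_losses, total_dups, class_tallies)


# ---------------------------------------------------------------------------
# File interfaces
# ---------------------------------------------------------------------------

def read_constraints(source) -> ConstraintSet:
    """Load a constraint YAML: keys ``terminal_duplications`` (list of
    {family, taxon, min_dups}) and ``forbidden_duplication_clades`` (list of
    {family, clade})."""
    if isinstance(source, str):
        with open(source) as fh:
            data = yaml.safe_load(fh)
    else:
        data = yaml.safe_load(source)
    data = data or {}
    terms = tuple(
        TerminalDuplications(d["family"], d["taxon"], int(d.get("min_dups", 1)))
        for d in data.get("terminal_duplications", [])
    )
    forb = tuple(
        ForbiddenDuplicationClade(d["family"], d["clade"])
        for d in data.get("forbidden_duplication_clades", [])
    )
    return ConstraintSet(terms, forb)


def read_events_tsv(source, root_counts: Mapping[str, int] | None = None) -> dict[str, EventMap]:
    """Read an events TSV (columns lineage_id, family, n_dup, n_loss) back
    into per-family :class:`EventMap` objects.  ``root_counts`` supplies the
    per-family root copy numbers (default 0: unknown)."""
    if isinstance(source, str):
        with open(source) as fh:
            return read_events_tsv(fh, root_counts)
    root_counts = dict(root_counts or {})
    maps: dict[str, EventMap] = {}
    header = None
    for raw in source:
        line = raw.rstrip("\n")
        if not line:
            continue
        parts = line.split("\t")
        if header is None:
            header = parts
            if header != ["lineage_id", "family", "n_dup", "n_loss"]:
                raise ValueError(f"bad events header: {header}")
            continue
        lid, fam, nd, nl = parts
        m = maps.setdefault(fam, EventMap(family=fam, root_count=root_counts.get(fam, 0)))
        if int(nd):
            m.duplications[lid] = m.duplications.get(lid, 0) + int(nd)
        if int(nl):
            m.losses[lid] = m.losses.get(lid, 0) + int(nl)
    if header is None:
        raise ValueError("empty events file")
    return maps


def write_events_tsv(event_maps: Mapping[str, EventMap], dest) -> None:
    """Write events as TSV: lineage_id, family, n_dup, n_loss."""
    lines = ["lineage_id\tfamily\tn_dup\tn_loss"]
    for fam in sorted(event_maps):
        m = event_maps[fam]
        for lid in sorted(set(m.duplications) | set(m.losses)):
            lines.append(
                f"{lid}\t{fam}\t{m.duplications.get(lid, 0)}\t{m.losses.get(lid, 0)}"
            )
    text = "\n".join(lines) + "\n"
    if isinstance(dest, str):
        with open(dest, "w") as fh:
            fh.write(text)
    else:
        dest.write(text)
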