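"""Rooted, annotated species trees.

The species tree is the scaffold for every downstream analysis: each of its
nodes — the root included — is a *lineage* (the node plus the branch
subtending it), so a fully binary tree over ``n`` taxa carries ``2n - 1``
lineages.  Lineages carry three annotations:

``parasitic``
    Lifestyle flag.  Leaves are annotated from data; an ancestral lineage is
    parasitic if and only if *all* of its descendant species are parasites
    (see :func:`propagate_lifestyle`).
``wgd``
    Whole-genome-duplication status, one of ``none`` / ``reported`` /
    ``uncertain`` (``uncertain`` meaning a WGD is reported only by some
    sources).  By default uncertain lineages are excluded from the WGD class.
``centrioles``
    Presence of centrioles; meaningful on leaves only.

Newick reading/writing is delegated to :mod:`dendropy`; the classes here add
the annotation layer, stable lineage identifiers and the class masks used by
the enrichment statistics.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import dendropy

__all__ = [
    "NewickParseError",
    "AnnotationError",
    "Node",
    "SpeciesTree",
    "LineageSet",
    "parse_newick",
    "write_newick",
    "count_lineages",
    "propagate_lifestyle",
    "read_annotations",
    "write_annotations",
]

WGD_STATES = ("none", "reported", "uncertain")


class NewickParseError(ValueError):
    """Malformed Newick input (unbalanced parentheses, duplicate labels...)."""


class AnnotationError(ValueError):
    """Annotation refers to unknown nodes or carries illegal values."""


class Node:
    """A tree node; the branch subtending it is one lineage."""

    __slots__ = ("label", "children", "parent", "parasitic", "wgd", "centrioles")

    def __init__(self, label: str | None = None):
        self.label = label
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.parasitic: bool | None = None
        self.wgd: str = "none"
        self.centrioles: bool | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal[{len(self.children)}]"
        return f"<Node {self.label!r} {kind}>"


class SpeciesTree:
    """Rooted species tree with unique leaf labels and per-node annotations."""

    def __init__(self, root: Node):
        self.root = root
        labels = [lf.label for lf in self.leaves()]
        if any(lb is None or lb == "" for lb in labels):
            raise NewickParseError("every leaf must carry a label")
        dupes = {lb for lb in labels if labels.count(lb) > 1}
        if dupes:
            raise NewickParseError(
                "duplicate leaf label(s): " + ", ".join(sorted(dupes))
            )
        self._leaf_by_label = {lf.label: lf for lf in self.leaves()}
        self._ids: dict[int, str] = {}
        self._assign_ids()

    # -- traversal ---------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def nodes(self) -> list[Node]:
        return list(self.preorder())

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def leaf(self, label: str) -> Node:
        try:
            return self._leaf_by_label[label]
        except KeyError:
            raise AnnotationError(f"unknown leaf label: {label!r}") from None

    def clade_leaves(self, node: Node) -> list[Node]:
        stack, out = [node], []
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n)
            else:
                stack.extend(n.children)
        return out

    # -- lineage identifiers ----------------------------------------------

    def _assign_ids(self) -> None:
        """Stable node ids: leaves use their label; an internal node uses its
        own label if present, otherwise ``min..max`` over its clade's leaf
        labels, suffixed with the clade size on the (nested-clade) collisions
        where two internal nodes share the same extreme pair."""
        provisional: dict[int, tuple[str, int]] = {}
        for node in self.preorder():
            if node.is_leaf:
                provisional[id(node)] = (node.label, 1)
            elif node.label:
                provisional[id(node)] = (node.label, 0)
            else:
                labels = sorted(lf.label for lf in self.clade_leaves(node))
                provisional[id(node)] = (f"{labels[0]}..{labels[-1]}", len(labels))
        seen: dict[str, int] = {}
        for key, (base, _) in provisional.items():
            seen[base] = seen.get(base, 0) + 1
        self._ids = {}
        for node in self.preorder():
            base, size = provisional[id(node)]
            if seen[base] > 1 and not node.is_leaf:
                self._ids[id(node)] = f"{base}..{size}"
            else:
                self._ids[id(node)] = base
        if len(set(self._ids.values())) != len(self._ids):
            raise AnnotationError("could not derive unique node identifiers")

    def node_id(self, node: Node) -> str:
        return self._ids[id(node)]

    def node_by_id(self, node_id: str) -> Node:
        for node in self.preorder():
            if self.node_id(node) == node_id:
                return node
        raise AnnotationError(f"unknown node id: {node_id!r}")

    # -- structure ---------------------------------------------------------

    def n_nodes(self) -> int:
        return sum(1 for _ in self.preorder())

    def copy(self) -> "SpeciesTree":
        def clone(node: Node) -> Node:
            new = Node(node.label)
            new.parasitic = node.parasitic
            new.wgd = node.wgd
            new.centrioles = node.centrioles
            for child in node.children:
                new.add_child(clone(child))
            return new

        return SpeciesTree(clone(self.root))

    def reroot_on_edge(self, node_id: str) -> "SpeciesTree":
        """Reroot on the branch above ``node_id`` (utility).  The target clade
        becomes one child of the new root; the rest of the tree, folded over,
        becomes the other.  Internal lifestyle flags are reset because clades
        change; re-run :func:`propagate_lifestyle` afterwards."""
        tree = self.copy()
        target = tree.node_by_id(node_id)
        if target.parent is None:
            return tree
        # ancestors of target, nearest first
        path: list[Node] = []
        node = target.parent
        while node is not None:
            path.append(node)
            node = node.parent
        # detach each path node from its own parent and from the previous
        # path member, then fold the chain under the new root
        prev: Node = target
        for anc in path:
            anc.children = [c for c in anc.children if c is not prev]
            prev = anc
        carry: Node | None = None
        for anc in reversed(path):  # old root first
            for c in anc.children:
                c.parent = anc
            if carry is not None:
                anc.add_child(carry)
            carry = anc
        new_root = Node(None)
        target.parent = None
        new_root.add_child(target)
        if carry is not None and (carry.is_leaf or carry.children):
            new_root.add_child(carry)
        out = SpeciesTree(_suppress_unifurcations(new_root))
        for n in out.preorder():
            if not n.is_leaf:
                n.parasitic = None
        return out

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<SpeciesTree n_leaves={len(self.leaves())} n_nodes={self.n_nodes()}>"


def _suppress_unifurcations(root: Node) -> Node:
    while len(root.children) == 1 and not root.children[0].is_leaf:
        root = root.children[0]
        root.parent = None
    for node in list(_preorder(root)):
        for i, child in enumerate(list(node.children)):
            while len(child.children) == 1:
                child = child.children[0]
            child.parent = node
            node.children[i] = child
    return root


def _preorder(root: Node) -> Iterator[Node]:
    stack = [root]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(reversed(n.children))


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def parse_newick(text: str) -> SpeciesTree:
    """Parse a rooted Newick string into a :class:`SpeciesTree`.

    Multifurcations are preserved; a degenerate single-leaf tree ``(A);`` is
    accepted.  Duplicate leaf labels or malformed syntax raise
    :class:`NewickParseError` naming the offending token.
    """
    if not text or not text.strip():
        raise NewickParseError("empty Newick input")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    def convert(dnode: dendropy.Node) -> Node:
        if dnode.taxon is not None:
            label = dnode.taxon.label
        else:
            label = dnode.label
        node = Node(label)
        for dchild in dnode.child_nodes():
            node.add_child(convert(dchild))
        return node

    root = convert(dtree.seed_node)
    # dendropy wraps "(A);" as root with a single leaf child — keep as-is
    return SpeciesTree(root)


def write_newick(tree: SpeciesTree) -> str:
    """Serialize to Newick (labels only; no branch lengths)."""

    def fmt(node: Node) -> str:
        if node.is_leaf:
            return node.label
        inner = ",".join(fmt(c) for c in node.children)
        return f"({inner}){node.label or ''}"

    return fmt(tree.root) + ";"


# ---------------------------------------------------------------------------
# Lineages and class masks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LineageSet:
    """Ordered lineage identifiers (one per tree node, root included) with
    the parasitic / WGD class masks used by the enrichment tests."""

    ids: tuple[str, ...]
    parasitic: frozenset[str] = field(default_factory=frozenset)
    wgd: frozenset[str] = field(default_factory=frozenset)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_parasitic(self) -> int:
        return len(self.parasitic)

    @property
    def n_wgd(self) -> int:
        return len(self.wgd)


def count_lineages(tree: SpeciesTree, include_uncertain_wgd: bool = False) -> LineageSet:
    """One lineage per node (root included): ``2n - 1`` for a binary tree of
    ``n`` leaves.  WGD lineages flagged ``uncertain`` are excluded from the
    WGD mask unless ``include_uncertain_wgd`` is set."""
    ids = []
    parasitic = set()
    wgd = set()
    accepted = {"reported", "uncertain"} if include_uncertain_wgd else {"reported"}
    for node in tree.preorder():
        nid = tree.node_id(node)
        ids.append(nid)
        if node.parasitic:
            parasitic.add(nid)
        if node.wgd in accepted:
            wgd.add(nid)
    return LineageSet(tuple(ids), frozenset(parasitic), frozenset(wgd))


def propagate_lifestyle(tree: SpeciesTree, parasitic_leaves: Sequence[str]) -> SpeciesTree:
    """Flag leaves in ``parasitic_leaves`` as parasites and propagate the
    lifestyle rootward: an ancestral lineage is parasitic iff every descendant
    species is a parasite.  Returns the same tree, annotated in place."""
    unknown = [lb for lb in parasitic_leaves if lb not in tree._leaf_by_label]
    if unknown:
        raise AnnotationError(
            "parasitic_leaves not in tree: " + ", ".join(sorted(unknown))
        )
    wanted = set(parasitic_leaves)
    for node in tree.postorder():
        if node.is_leaf:
            node.parasitic = node.label in wanted
        else:
            node.parasitic = all(c.parasitic for c in node.children)
    return tree


# ---------------------------------------------------------------------------
# Annotation sidecar TSV
# ---------------------------------------------------------------------------

_TRUTHY = {"1": True, "0": False}


def read_annotations(tree: SpeciesTree, source) -> SpeciesTree:
    """Apply a node-annotation sidecar TSV to ``tree`` (in place).

    Columns: ``node_id``, ``parasitic`` {0,1}, ``wgd`` {none,reported,
    uncertain}, ``centrioles`` {0,1,NA}.  ``node_id`` is a leaf label or an
    internal identifier as produced by :meth:`SpeciesTree.node_id`.  After
    loading, leaf lifestyles are re-propagated so the all-descendants rule
    always holds.
    """
    if isinstance(source, str):
        with open(source) as fh:
            return read_annotations(tree, fh)
    by_id = {tree.node_id(n): n for n in tree.preorder()}
    header = None
    parasitic_leaves: list[str] = []
    for raw in source:
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if header is None:
            header = parts
            expected = ["node_id", "parasitic", "wgd", "centrioles"]
            if header != expected:
                raise AnnotationError(
                    f"annotation header must be {expected}, got {header}"
                )
            continue
        nid, para, wgd, cent = parts
        if nid not in by_id:
            raise AnnotationError(f"annotation for unknown node id: {nid!r}")
        node = by_id[nid]
        if para not in ("", "NA"):
            if para not in _TRUTHY:
                raise AnnotationError(f"bad parasitic value {para!r} for {nid}")
            if _TRUTHY[para] and node.is_leaf:
                parasitic_leaves.append(nid)
            node.parasitic = _TRUTHY[para]
        if wgd not in WGD_STATES:
            raise AnnotationError(f"bad wgd value {wgd!r} for {nid}")
        node.wgd = wgd
        if cent not in ("", "NA"):
            if cent not in _TRUTHY:
                raise AnnotationError(f"bad centrioles value {cent!r} for {nid}")
            node.centrioles = _TRUTHY[cent]
    if header is None:
        raise AnnotationError("empty annotation file")
    propagate_lifestyle(tree, parasitic_leaves)
    return tree


def write_annotations(tree: SpeciesTree, dest=None) -> str:
    """Write the annotation sidecar TSV; returns the text (and writes it to
    ``dest`` path/handle if given)."""
    buf = io.StringIO()
    buf.write("node_id\tparasitic\twgd\tcentrioles\n")
    for node in tree.preorder():
        para = "NA" if node.parasitic is None else str(int(node.parasitic))
        cent = "NA" if node.centrioles is None else str(int(node.centrioles))
        buf.write(f"{tree.node_id(node)}\t{para}\t{node.wgd}\t{cent}\n")
    text = buf.getvalue()
    if dest is not None:
        if isinstance(dest, str):
            with open(dest, "w") as fh:
                fh.write(text)
        else:
            dest.write(text)
    return text
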