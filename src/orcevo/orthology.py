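"""Family assignment from gene-tree placement, and false-paralog removal.

Candidate sequences are classified into subunit families by where they sit
in a reference-labeled gene tree: a query takes the family of the smallest
enclosing clade whose reference leaves all belong to one family.  CDC6 and
ORC1 references are pooled into the single family ``CDC6/ORC1``, so a clade
mixing the two still counts as pure for the pooled family.

Confidence tiers follow the bona-fide / likely vocabulary used for
phylogenetically classified orthologs; the precise rules here are this
package's declared reconstruction:

``bona_fide``   the supporting pure clade holds >= 2 reference leaves;
``likely``      it holds exactly 1;
``uncertain``   no family-pure enclosing clade exists below the root
                (family ``unassigned``).

Species-specific false paralogs — near-identical same-species sequences
that would otherwise inflate copy numbers — are collapsed by single-linkage
grouping at a global-identity threshold, keeping the longest member.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .pact import global_align
from .trees import Node, SpeciesTree, parse_newick

__all__ = [
    "GeneTreeLeaf",
    "FamilyAssignment",
    "POOLED_FAMILIES",
    "parse_gene_tree",
    "classify_by_placement",
    "filter_false_paralogs",
    "pairwise_identity",
]

#: family labels pooled into one (deep CDC6/ORC1 splits are often unresolvable)
POOLED_FAMILIES: Mapping[str, str] = {"CDC6": "CDC6/ORC1", "ORC1": "CDC6/ORC1"}


@dataclass(frozen=True)
class GeneTreeLeaf:
    seq_id: str
    species: str
    family: str | None  # reference label, None for queries


@dataclass(frozen=True)
class FamilyAssignment:
    seq_id: str
    species: str
    family: str  # pooled family label or "unassigned"
    confidence: str  # bona_fide | likely | uncertain


def _pool(family: str) -> str:
    return POOLED_FAMILIES.get(family, family)


def parse_gene_tree(newick: str) -> tuple[SpeciesTree, dict[str, GeneTreeLeaf]]:
    """Parse a gene tree whose leaves are named ``seqid|species|family`` for
    references and ``seqid|species`` for queries."""
    tree = parse_newick(newick)
    leaves: dict[str, GeneTreeLeaf] = {}
    for lf in tree.leaves():
        parts = lf.label.split("|")
        if len(parts) == 3:
            leaves[lf.label] = GeneTreeLeaf(parts[0], parts[1], parts[2])
        elif len(parts) == 2:
            leaves[lf.label] = GeneTreeLeaf(parts[0], parts[1], None)
        else:
            raise ValueError(
                f"gene-tree leaf {lf.label!r} is not seqid|species[|family]"
            )
    return tree, leaves


def classify_by_placement(
    tree: SpeciesTree, leaves: Mapping[str, GeneTreeLeaf] | None = None
) -> list[FamilyAssignment]:
    """Assign each query leaf the family of its smallest family-pure
    enclosing clade (see module docstring for the confidence tiers).

    Deterministic and invariant to child-order rotations: the result
    depends only on the ancestor chain of each query.
    """
    if leaves is None:
        _, leaves = parse_gene_tree_from(tree)
    ref_leaves = [lb for lb, g in leaves.items() if g.family is not None]
    if not ref_leaves:
        raise ValueError("gene tree has no reference leaves")
    out: list[FamilyAssignment] = []
    for lf in tree.leaves():
        meta = leaves[lf.label]
        if meta.family is not None:
            continue  # reference leaf
        assignment = ("unassigned", "uncertain")
        node: Node | None = lf.parent
        while node is not None and node.parent is not None:
            fams = {
                _pool(leaves[x.label].family)
                for x in tree.clade_leaves(node)
                if leaves[x.label].family is not None
            }
            if len(fams) == 1:
                n_ref = sum(
                    1
                    for x in tree.clade_leaves(node)
                    if leaves[x.label].family is not None
                )
                conf = "bona_fide" if n_ref >= 2 else "likely"
                assignment = (next(iter(fams)), conf)
                break
            if len(fams) > 1:
                break  # larger clades can only get more mixed
            node = node.parent
        out.append(FamilyAssignment(meta.seq_id, meta.species, *assignment))
    return out


def parse_gene_tree_from(tree: SpeciesTree) -> tuple[SpeciesTree, dict[str, GeneTreeLeaf]]:
    leaves: dict[str, GeneTreeLeaf] = {}
    for lf in tree.leaves():
        parts = lf.label.split("|")
        if len(parts) == 3:
            leaves[lf.label] = GeneTreeLeaf(parts[0], parts[1], parts[2])
        else:
            leaves[lf.label] = GeneTreeLeaf(parts[0], parts[-1] if len(parts) > 1 else "", None)
    return tree, leaves


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity: identical columns / gap-free columns."""
    aln = global_align(seq_a, seq_b)
    paired = [(r, q) for r, q in aln.columns() if r != "-" and q != "-"]
    if not paired:
        return 0.0
    return sum(1 for r, q in paired if r == q) / len(paired)


def filter_false_paralogs(
    assignments: Sequence[FamilyAssignment],
    sequences: Mapping[str, str],
    identity_threshold: float = 0.95,
) -> tuple[list[FamilyAssignment], list[dict]]:
    """Collapse near-identical same-species, same-family sequences.

    Within every (species, family) group, sequences are single-linkage
    grouped at ``identity_threshold`` global identity; each linkage group
    keeps its longest member (ties: lexicographically smallest id).  Returns
    (retained assignments, removal log); each log entry names the removed
    sequence, the retained representative and the triggering identity.
    The last member of a group is never removed.
    """
    missing = [a.seq_id for a in assignments if a.seq_id not in sequences]
    if missing:
        raise ValueError("sequences missing for: " + ", ".join(sorted(missing)))
    by_group: dict[tuple[str, str], list[FamilyAssignment]] = {}
    for a in assignments:
        by_group.setdefault((a.species, a.family), []).append(a)
    retained: list[FamilyAssignment] = []
    log: list[dict] = []
    for (species, family), members in by_group.items():
        if len(members) == 1 or family == "unassigned":
            retained.extend(members)
            continue
        ids = sorted(a.seq_id for a in members)
        # single-linkage components at the identity threshold
        parent = {i: i for i in ids}

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        trigger: dict[tuple[str, str], float] = {}
        for k, i in enumerate(ids):
            for j in ids[k + 1:]:
                ident = pairwise_identity(sequences[i], sequences[j])
                if ident >= identity_threshold:
                    trigger[(i, j)] = ident
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[max(ri, rj)] = min(ri, rj)
        components: dict[str, list[str]] = {}
        for i in ids:
            components.setdefault(find(i), []).append(i)
        by_id = {a.seq_id: a for a in members}
        for comp in components.values():
            keep = min(comp, key=lambda i: (-len(sequences[i]), i))
            retained.append(by_id[keep])
            for i in comp:
                if i == keep:
                    continue
                pair_idents = [
                    v for (a_, b_), v in trigger.items() if i in (a_, b_)
                ]
                log.append(
                    {
                        "removed": i,
                        "kept": keep,
                        "species": species,
                        "family": family,
                        "identity": max(pair_idents) if pair_idents else None,
                    }
                )
    order = {a.seq_id: k for k, a in enumerate(assignments)}
    retained.sort(key=lambda a: order[a.seq_id])
    return retained, log
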