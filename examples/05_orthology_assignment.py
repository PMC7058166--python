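"""Classify candidate sequences from gene-tree placement, drop false paralogs.

A query falling inside a clade whose reference leaves all carry one family
label takes that family; CDC6 and ORC1 references pool into one family.
Near-identical same-species sequences (assembly artifacts / isoforms) are
collapsed to the longest representative.
"""

from orcevo import classify_by_placement, filter_false_paralogs, parse_gene_tree

newick = (
    "(((q1|Xenu,(HsORC2|Hsap|ORC2,ScORC2|Scer|ORC2)),"
    "(q2|Xenu,(HsCDC6|Hsap|CDC6,HsORC1|Hsap|ORC1))),out|Tbru|ORC4);"
)
tree, leaves = parse_gene_tree(newick)
assignments = classify_by_placement(tree, leaves)
for a in assignments:
    print(f"{a.seq_id} ({a.species}): {a.family} [{a.confidence}]")

# Two near-identical ORC2 copies in the same species: one is a false paralog.
seqs = {
    "q1": "MKVLITGGAGFIGSHLVDRLMA",
    "q1b": "MKVLITGGAGFIGSHLVDRLMAQQ",  # 100% identical over the overlap
}
assignments = [a for a in assignments if a.seq_id == "q1"]
from orcevo.orthology import FamilyAssignment

assignments.append(FamilyAssignment("q1b", "Xenu", "ORC2", "likely"))
kept, log = filter_false_paralogs(assignments, seqs, identity_threshold=0.95)
print("\nretained:", [a.seq_id for a in kept])
for entry in log:
    print(f"removed {entry['removed']} (kept {entry['kept']}, "
          f"identity {entry['identity']:.2f})")
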