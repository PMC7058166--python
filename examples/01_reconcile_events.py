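"""Infer minimal duplication/loss histories on a species tree.

Two classic situations: a gene family absent from an entire clade (one loss
on the clade's stem beats independent losses in each species), and extra
copies in two sister species that a gene tree shows to be species-specific
paralogs (a constraint forces two terminal duplications instead of the
cheaper single ancestral one).
"""

from orcevo import ConstraintSet, TerminalDuplications, infer_events, parse_newick
from orcevo.reconcile import replay_events

# A family present in the outgroup but absent from a three-species clade.
tree = parse_newick("(((Ehis,Enut),Einv),Out);")
counts = {"Ehis": 0, "Enut": 0, "Einv": 0, "Out": 1}
events = infer_events(tree, counts, root_count=1, family="ORC2")
print("clade absence:")
print("  losses:", events.losses, "duplications:", events.duplications)
print("  replay check:", replay_events(tree, 1, events) == counts)

# Two sister species with two copies each: unconstrained parsimony puts one
# duplication on their common ancestor ...
tree2 = parse_newick("((Cang,Amac),Out);")
counts2 = {"Cang": 2, "Amac": 2, "Out": 1}
free = infer_events(tree2, counts2, root_count=1, family="ORC4")
print("sister duplication, unconstrained:")
print("  duplications:", free.duplications, f"({free.n_events} event)")

# ... but if the gene tree says the paralogs are species-specific, the
# constraint moves them onto the terminal branches (2 events).
constraints = ConstraintSet(
    (
        TerminalDuplications("ORC4", "Cang", 1),
        TerminalDuplications("ORC4", "Amac", 1),
    )
)
pinned = infer_events(tree2, counts2, root_count=1, constraints=constraints, family="ORC4")
print("with species-specific-paralog constraint:")
print("  duplications:", pinned.duplications, f"({pinned.n_events} events)")
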