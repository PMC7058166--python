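"""Independent oracles shared by unit and acceptance tests.

Everything here is deliberately written by a different route than the
library code it checks: exhaustive enumeration instead of dynamic
programming, pair counting instead of rank sums.
"""

from __future__ import annotations

import itertools

from orcevo.trees import SpeciesTree


def brute_force_min_events(
    tree: SpeciesTree, leaf_counts: dict[str, int], root_count: int
) -> int:
    """Exhaustive minimization over all ancestral copy-number assignments.

    States range over 0 .. max(count, root)+1; assignments violating the
    no-regain rule (a zero-copy node with a positive-copy child) are
    discarded; the cost of an assignment is the sum of |parent - child|
    over all branches.  Exponential; for trees up to ~6 leaves only.
    """
    internals = [
        n for n in tree.preorder() if not n.is_leaf and n is not tree.root
    ]
    top = max([root_count] + list(leaf_counts.values())) + 1
    best = None
    for combo in itertools.product(range(top + 1), repeat=len(internals)):
        assign = {id(n): s for n, s in zip(internals, combo)}
        assign[id(tree.root)] = root_count
        for lf in tree.leaves():
            assign[id(lf)] = leaf_counts[lf.label]
        cost = 0
        ok = True
        for node in tree.preorder():
            if node is tree.root:
                continue
            p, c = assign[id(node.parent)], assign[id(node)]
            if p == 0 and c > 0:
                ok = False
                break
            cost += abs(p - c)
        if ok and (best is None or cost < best):
            best = cost
    return best


def brute_force_mw_tails(x, y, u_obs: float) -> tuple[float, float]:
    """(P(U <= u), P(U >= u)) by enumerating every assignment of the pooled
    values to the two groups, computing U by direct pair counting (ties
    count one half) — no ranks involved."""
    pooled = list(x) + list(y)
    n1 = len(x)
    le = ge = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = sum(
            1.0 if a > b else (0.5 if a == b else 0.0) for a in xs for b in ys
        )
        total += 1
        if u <= u_obs + 1e-9:
            le += 1
        if u >= u_obs - 1e-9:
            ge += 1
    return le / total, ge / total
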