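"""Exact nonparametric statistics for branch-class enrichment analyses.

Three classical tests, implemented here in exact form:

* one-tailed Fisher exact test — the upper hypergeometric tail
  ``P(X >= a)`` with all margins fixed, summed exactly via log-factorials;
* Mann–Whitney U — exact by enumeration of rank assignments for small
  samples, normal approximation with tie and continuity corrections
  otherwise;
* Spearman rank correlation — Pearson correlation of midranks.

On top of these sits :func:`enrichment_test`, which asks whether
duplication/loss events are over-represented in a class of species-tree
lineages (parasitic lineages, whole-genome-duplication lineages).  The 2x2
table is built in "concatenated margins" form — first row the event counts
inside/outside the class, second row the lineage counts inside/outside —
with a hypergeometric "placement" alternative (events drawn onto lineages
without replacement) available via ``construction``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "ContingencyTable2x2",
    "StatResult",
    "fisher_one_tailed",
    "hypergeom_logpmf",
    "hypergeom_support",
    "mann_whitney",
    "spearman",
    "midranks",
    "enrichment_test",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Cells ``[[a, b], [c, d]]``; row 1 = events in/out of the lineage
    class, row 2 = lineages in/out of the class."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                if float(v) != int(v):
                    raise ValueError(f"cell {name} must be an integer, got {v!r}")
                object.__setattr__(self, name, int(v))
            if getattr(self, name) < 0:
                raise ValueError(f"cell {name} is negative: {v}")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("all-zero contingency table")

    def as_rows(self) -> list[list[int]]:
        return [[self.a, self.b], [self.c, self.d]]


@dataclass(frozen=True)
class StatResult:
    """Outcome of one test: named statistic, P-value, tails and method."""

    name: str
    statistic: float
    pvalue: float
    tails: str  # "one" | "two"
    method: str  # "exact" | "normal-approximation"
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.pvalue <= 1.0 + 1e-12):
            raise ValueError(f"P-value out of range: {self.pvalue}")


# ---------------------------------------------------------------------------
# Hypergeometric / Fisher
# ---------------------------------------------------------------------------

def hypergeom_support(N: int, K: int, n: int) -> range:
    """Support of the number of marked items in a draw of ``n`` from ``N``
    containing ``K`` marked."""
    return range(max(0, n + K - N), min(n, K) + 1)


def hypergeom_logpmf(k: int, N: int, K: int, n: int) -> float:
    """log P(X = k) for X ~ Hypergeom(N, K, n), via log-factorials."""
    if k not in hypergeom_support(N, K, n):
        return -math.inf
    lg = math.lgamma
    lchoose = lambda a, b: lg(a + 1) - lg(b + 1) - lg(a - b + 1)
    return lchoose(K, k) + lchoose(N - K, n - k) - lchoose(N, n)


def fisher_one_tailed(table: ContingencyTable2x2) -> StatResult:
    """One-tailed (upper) Fisher exact test on a 2x2 table.

    With margins fixed, cell ``a`` follows Hypergeom(N, a+c, a+b); the
    reported P is the exact upper tail P(X >= a), summed from the observed
    cell to the top of the support.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    N = a + b + c + d
    K = a + c
    n = a + b
    support = hypergeom_support(N, K, n)
    if a <= support.start:
        p = 1.0  # the whole support: certain, exactly
    else:
        p = min(
            sum(math.exp(hypergeom_logpmf(k, N, K, n)) for k in range(a, support.stop)),
            1.0,
        )
    return StatResult(
        name="fisher-one-tailed",
        statistic=float(a),
        pvalue=p,
        tails="one",
        method="exact",
        extras={"table": table.as_rows(), "N": N, "K": K, "n": n},
    )


# ---------------------------------------------------------------------------
# Ranks
# ---------------------------------------------------------------------------

def midranks(values: Sequence[float]) -> list[float]:
    """Ranks 1..n with ties given their average (mid) rank."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1.0  # average of ranks i+1 .. j+1
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    return ranks


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

#: sample-size bound (n1 + n2) under which the tie-free exact null is used
EXACT_LIMIT = 20


def _u_statistic(x: Sequence[float], y: Sequence[float]) -> float:
    """U for sample x: concordant (x > y) pairs, ties counting one half."""
    ranks = midranks(list(x) + list(y))
    n1 = len(x)
    r1 = sum(ranks[:n1])
    return r1 - n1 * (n1 + 1) / 2


def _exact_u_cdf_no_ties(n1: int, n2: int) -> list[int]:
    """Null distribution of U without ties: ``counts[u]`` = number of rank
    splits with U = u, via the standard recurrence."""
    # f(n1, n2, u): recurrence f = f(n1-1, n2, u - n2) + f(n1, n2-1, u)
    maxu = n1 * n2
    table = [[[0] * (maxu + 1) for _ in range(n2 + 1)] for _ in range(n1 + 1)]
    for j in range(n2 + 1):
        table[0][j][0] = 1
    for i in range(1, n1 + 1):
        table[i][0][0] = 1
    for i in range(1, n1 + 1):
        for j in range(1, n2 + 1):
            for u in range(maxu + 1):
                v = table[i][j - 1][u]
                if u >= j:
                    v += table[i - 1][j][u - j]
                table[i][j][u] = v
    return table[n1][n2]


def _exact_pvalues_no_ties(n1: int, n2: int, u: float) -> tuple[float, float]:
    counts = _exact_u_cdf_no_ties(n1, n2)
    total = math.comb(n1 + n2, n1)
    ui = int(round(u))
    p_le = sum(counts[: ui + 1]) / total
    p_ge = sum(counts[ui:]) / total
    return p_le, p_ge


def _exact_pvalues_permutation(
    x: Sequence[float], y: Sequence[float], u: float
) -> tuple[float, float]:
    """Exact tail probabilities by enumerating every split of the pooled
    midranks (handles ties); the independent, brute-force route."""
    ranks = midranks(list(x) + list(y))
    n1 = len(x)
    offset = n1 * (n1 + 1) / 2
    le = ge = total = 0
    for idx in itertools.combinations(range(len(ranks)), n1):
        uu = sum(ranks[i] for i in idx) - offset
        total += 1
        if uu <= u + 1e-9:
            le += 1
        if uu >= u - 1e-9:
            ge += 1
    return le / total, ge / total


def _normal_pvalues(x: Sequence[float], y: Sequence[float], u: float) -> tuple[float, float]:
    n1, n2 = len(x), len(y)
    N = n1 + n2
    pooled = sorted(list(x) + list(y))
    tie_term = 0.0
    i = 0
    while i < N:
        j = i
        while j + 1 < N and pooled[j + 1] == pooled[i]:
            j += 1
        t = j - i + 1
        tie_term += t**3 - t
        i = j + 1
    mean = n1 * n2 / 2
    var = n1 * n2 / 12 * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0:
        return 1.0, 1.0
    sd = math.sqrt(var)
    # continuity-corrected tails
    p_ge = 0.5 * math.erfc((u - mean - 0.5) / (sd * math.sqrt(2)))
    p_le = 0.5 * math.erfc((mean - u - 0.5) / (sd * math.sqrt(2)))
    return min(p_le, 1.0), min(p_ge, 1.0)


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    method: str = "auto",
) -> StatResult:
    """Mann–Whitney U test; U is reported for sample ``x``.

    ``alternative``: ``"less"`` (x stochastically smaller), ``"greater"``,
    or ``"two-sided"`` (twice the smaller tail, capped at 1).  ``method``:
    ``"auto"`` uses the tie-free exact null when ``n1 + n2 <=`` the exact
    limit (20) and no ties are present, the normal approximation with tie
    and continuity corrections otherwise; ``"exact"`` forces enumeration
    (every split of the pooled midranks); ``"approx"`` forces the normal
    approximation.
    """
    if len(x) == 0 or len(y) == 0:
        raise ValueError("mann_whitney: empty sample")
    if alternative not in ("less", "greater", "two-sided"):
        raise ValueError(f"bad alternative: {alternative!r}")
    u = _u_statistic(x, y)
    pooled = list(x) + list(y)
    has_ties = len(set(pooled)) != len(pooled)
    if method == "auto":
        method = "exact" if (len(pooled) <= EXACT_LIMIT and not has_ties) else "approx"
    if method == "exact":
        if has_ties:
            p_le, p_ge = _exact_pvalues_permutation(x, y, u)
        else:
            p_le, p_ge = _exact_pvalues_no_ties(len(x), len(y), u)
        used = "exact"
    elif method == "approx":
        p_le, p_ge = _normal_pvalues(x, y, u)
        used = "normal-approximation"
    else:
        raise ValueError(f"bad method: {method!r}")
    if alternative == "less":
        p, tails = p_le, "one"
    elif alternative == "greater":
        p, tails = p_ge, "one"
    else:
        p, tails = min(1.0, 2 * min(p_le, p_ge)), "two"
    return StatResult(
        name="mann-whitney-u",
        statistic=float(u),
        pvalue=p,
        tails=tails,
        method=used,
        extras={"n1": len(x), "n2": len(y), "ties": has_ties},
    )


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

def spearman(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Spearman rank correlation: Pearson correlation of midranks.

    Midranking subsumes the classical tie correction.  No P-value is
    attached by default beyond the large-sample t approximation recorded in
    ``extras`` — the analyses here use rho itself.
    """
    if len(x) != len(y):
        raise ValueError("spearman: unequal lengths")
    n = len(x)
    if n < 3:
        raise ValueError("spearman: need at least 3 pairs")
    if len(set(x)) == 1 or len(set(y)) == 1:
        raise ValueError("spearman: constant vector, rho undefined")
    rx, ry = midranks(x), midranks(y)
    mx = sum(rx) / n
    my = sum(ry) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    rho = cov / math.sqrt(vx * vy)
    rho = max(-1.0, min(1.0, rho))
    # two-sided t approximation, recorded for reference
    if abs(rho) < 1.0 and n > 3:
        t = rho * math.sqrt((n - 2) / (1 - rho * rho))
        # Student-t tail via the regularized incomplete beta is overkill here;
        # use the normal approximation on t for the recorded extra.
        p_norm = math.erfc(abs(t) / math.sqrt(2))
    else:
        p_norm = 0.0 if abs(rho) == 1.0 else 1.0
    return StatResult(
        name="spearman-rho",
        statistic=rho,
        pvalue=min(1.0, p_norm),
        tails="two",
        method="exact",
        extras={"n": n},
    )


# ---------------------------------------------------------------------------
# Branch-class enrichment
# ---------------------------------------------------------------------------

def enrichment_test(
    events,
    lineages,
    event_type: str = "loss",
    lineage_class: str = "parasitic",
    construction: str = "concat-margins",
) -> StatResult:
    """Are events of ``event_type`` enriched in a lineage class?

    ``events`` is an :class:`~orcevo.reconcile.EventMap` (or anything with a
    ``per_lineage(event_type)`` mapping); ``lineages`` a
    :class:`~orcevo.trees.LineageSet`.  The default table is the
    concatenated-margins form [[events in class, events outside],
    [lineages in class, lineages outside]] with the one-tailed Fisher upper
    tail; ``construction="placement"`` instead treats each event as a draw of
    a lineage without replacement and takes the hypergeometric upper tail
    directly.
    """
    if event_type not in ("loss", "duplication"):
        raise ValueError(f"bad event_type: {event_type!r}")
    if lineage_class == "parasitic":
        klass = set(lineages.parasitic)
    elif lineage_class == "wgd":
        klass = set(lineages.wgd)
    else:
        raise ValueError(f"bad lineage_class: {lineage_class!r}")
    if not klass:
        raise ValueError(f"empty lineage class: {lineage_class}")
    per_lineage = events.per_lineage(event_type)
    unknown = set(per_lineage) - set(lineages.ids)
    if unknown:
        raise ValueError(
            "events reference lineages absent from the lineage set: "
            + ", ".join(sorted(unknown)[:5])
        )
    in_class = sum(c for lid, c in per_lineage.items() if lid in klass)
    total = sum(per_lineage.values())
    out_class = total - in_class
    if total == 0:
        raise ValueError(f"no {event_type} events to test")
    n_class = len(klass)
    n_out = len(lineages) - n_class
    table = ContingencyTable2x2(in_class, out_class, n_class, n_out)
    if construction == "concat-margins":
        res = fisher_one_tailed(table)
    elif construction == "placement":
        N, K, n = len(lineages), n_class, total
        p = 0.0
        for k in range(in_class, hypergeom_support(N, K, n).stop):
            p += math.exp(hypergeom_logpmf(k, N, K, n))
        res = StatResult(
            name="fisher-one-tailed",
            statistic=float(in_class),
            pvalue=min(p, 1.0),
            tails="one",
            method="exact",
            extras={"table": table.as_rows(), "N": N, "K": K, "n": n},
        )
    else:
        raise ValueError(f"bad construction: {construction!r}")
    extras = dict(res.extras)
    extras.update(
        event_type=event_type,
        lineage_class=lineage_class,
        construction=construction,
    )
    return StatResult(res.name, res.statistic, res.pvalue, res.tails, res.method, extras)
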