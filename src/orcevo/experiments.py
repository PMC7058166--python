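"""Calibration and recovery experiments on synthetic data.

These are the package's standard self-checks, shared by the test suite and
the acceptance script:

* :func:`event_recovery_experiment` — can parsimony recover the true number
  of duplication/loss events when the per-branch rates are low?  Each
  replicate simulates one gene family down a random species tree and
  reconciles the resulting leaf counts; at low rates parsimony is a
  consistent estimator and the inferred total matches the truth in most
  replicates (it can only undercount, when distinct events cancel or
  coincide).
* :func:`enrichment_power_experiment` — does the parasite-loss enrichment
  test fire when lineage classes really differ (loss-rate multiplier > 1)
  and stay quiet when they do not (multiplier 1)?
* :func:`uniform_placement_null` — type-I error of the enrichment test when
  events land on lineages uniformly at random.
* :func:`pact_null_pvalues` / :func:`pact_power_experiment` — calibration
  and power of the centriole-group comparison of motif conservation
  ratios.

Every experiment takes an explicit base seed; replicate ``i`` uses
``base_seed + i`` so runs are reproducible and replicates independent.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .pact import MotifSpec, pact_ratio, compare_centriole_groups
from .reconcile import EventMap, infer_events, merge_event_maps
from .simulate import (
    SimulationConfig,
    mark_parasitic_clades,
    simulate_gene_content,
    simulate_orc1_sequences,
    simulate_species_tree,
)
from .stats import enrichment_test
from .trees import count_lineages

__all__ = [
    "event_recovery_experiment",
    "enrichment_power_experiment",
    "uniform_placement_null",
    "pact_null_pvalues",
    "pact_power_experiment",
]


def event_recovery_experiment(
    n_replicates: int = 100,
    n_taxa: int = 16,
    dup_rate: float = 0.03,
    loss_rate: float = 0.05,
    base_seed: int = 0,
) -> dict:
    """Fraction of single-family replicates whose parsimony event total
    equals the truth exactly, and within 10%.

    Event totals are small integers (a 16-taxon tree at these rates carries
    two or three events on average), so "within 10%" is evaluated at integer
    resolution: ``|inferred - truth| <= max(1, 0.1 * truth)``.  Parsimony
    can undercount (coinciding or cancelling events are invisible) and,
    rarely, overcount (the simulator permits a regain after zero copies,
    which the Dollo constraint forbids)."""
    cfg = SimulationConfig(
        n_taxa=n_taxa,
        families={"FAM": 1},
        dup_rate=dup_rate,
        loss_rate=loss_rate,
        parasitic_loss_multiplier=1.0,
        parasitic_fraction=0.0,
        n_wgd=0,
    )
    exact = close = 0
    for i in range(n_replicates):
        rng = np.random.default_rng(base_seed + i)
        tree = simulate_species_tree(n_taxa, rng)
        mark_parasitic_clades(tree, 0.0, rng)
        matrix, maps = simulate_gene_content(tree, cfg, rng, wgd_branches=())
        truth = maps["FAM"].n_events
        inferred = infer_events(
            tree, matrix["FAM"].to_dict(), root_count=1
        ).n_events
        if inferred == truth:
            exact += 1
        if abs(inferred - truth) <= max(1, 0.1 * truth):
            close += 1
    return {
        "n_replicates": n_replicates,
        "exact_fraction": exact / n_replicates,
        "within_10pct_fraction": close / n_replicates,
    }


def enrichment_power_experiment(
    n_replicates: int = 100,
    n_taxa: int = 132,
    loss_multiplier: float = 5.0,
    parasitic_fraction: float = 0.25,
    alpha: float = 0.05,
    base_seed: int = 0,
) -> dict:
    """Fraction of replicates where the parasite-loss enrichment P < alpha.

    Events are re-inferred from the simulated leaf counts (the full
    analysis path), not read from the simulation truth.
    """
    cfg = SimulationConfig(
        n_taxa=n_taxa,
        parasitic_loss_multiplier=loss_multiplier,
        parasitic_fraction=parasitic_fraction,
        n_wgd=0,
    )
    hits = 0
    used = 0
    for i in range(n_replicates):
        rng = np.random.default_rng(base_seed + i)
        tree = simulate_species_tree(n_taxa, rng)
        mark_parasitic_clades(tree, parasitic_fraction, rng)
        matrix, _ = simulate_gene_content(tree, cfg, rng, wgd_branches=())
        lineages = count_lineages(tree)
        maps = {
            fam: infer_events(
                tree, matrix[fam].to_dict(), root_count=cfg.families[fam], family=fam
            )
            for fam in matrix.columns
        }
        merged = merge_event_maps(maps.values())
        if merged.n_losses == 0 or not lineages.parasitic:
            continue  # nothing to test in this replicate
        used += 1
        res = enrichment_test(merged, lineages, "loss", "parasitic")
        if res.pvalue < alpha:
            hits += 1
    return {
        "n_replicates": used,
        "significant_fraction": hits / used if used else float("nan"),
    }


def uniform_placement_null(
    n_simulations: int = 2000,
    n_lineages: int = 263,
    n_class: int = 83,
    n_events: int = 69,
    alpha: float = 0.05,
    base_seed: int = 0,
) -> dict:
    """Type-I error of the enrichment test when each event independently
    lands on a uniformly random lineage."""
    rng = np.random.default_rng(base_seed)
    ids = [f"L{i}" for i in range(n_lineages)]
    from .trees import LineageSet

    lineages = LineageSet(tuple(ids), frozenset(ids[:n_class]), frozenset())
    rejections = 0
    for _ in range(n_simulations):
        placement = rng.integers(0, n_lineages, size=n_events)
        emap = EventMap(family=None, root_count=0)
        for k in placement:
            emap.losses[ids[k]] = emap.losses.get(ids[k], 0) + 1
        res = enrichment_test(emap, lineages, "loss", "parasitic")
        if res.pvalue < alpha:
            rejections += 1
    return {
        "n_simulations": n_simulations,
        "type_i_error": rejections / n_simulations,
    }


def _pact_group_pvalue(cfg: SimulationConfig, seed: int, n_per_group: int) -> dict:
    rng = np.random.default_rng(seed)
    centrioles = {f"C{i:02d}": True for i in range(n_per_group)}
    centrioles.update({f"N{i:02d}": False for i in range(n_per_group)})
    ref, seqs = simulate_orc1_sequences(centrioles, cfg, rng)
    motifs = MotifSpec(cfg.motifs)
    records = [
        pact_ratio(ref, seq, motifs, taxon=t, centrioles=centrioles[t])
        for t, seq in seqs.items()
    ]
    comp = compare_centriole_groups(records)
    return {k: r.pvalue for k, r in comp.items()}


def pact_null_pvalues(
    n_replicates: int = 100, n_per_group: int = 20, base_seed: int = 0
) -> list[float]:
    """Identity-ratio comparison P-values when both centriole classes share
    the same motif substitution probability (no effect: P ~ Uniform[0,1])."""
    cfg = SimulationConfig()  # both motif probabilities equal by default
    return [
        _pact_group_pvalue(cfg, base_seed + i, n_per_group)["identity_ratio"]
        for i in range(n_replicates)
    ]


def pact_power_experiment(
    n_replicates: int = 100,
    n_per_group: int = 20,
    motif_sub_prob_centrioles: float = 0.25,
    alpha: float = 0.01,
    base_seed: int = 0,
) -> dict:
    """Detection rate when motif columns are conserved about twice as well
    in centriole-bearing taxa (substitution probability halved)."""
    cfg = replace(
        SimulationConfig(), motif_sub_prob_centrioles=motif_sub_prob_centrioles
    )
    hits = 0
    for i in range(n_replicates):
        ps = _pact_group_pvalue(cfg, base_seed + i, n_per_group)
        if ps["identity_ratio"] < alpha:
            hits += 1
    return {"n_replicates": n_replicates, "significant_fraction": hits / n_replicates}
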