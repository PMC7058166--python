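"""End-to-end workflow: reconcile -> enrich -> cluster -> PACT, one config.

:func:`run_pipeline` binds the analysis stages together.  Inputs are either
paths to the standard files (Newick tree + annotation sidecar, copy-number
TSV, metrics TSV, ORC1 FASTA + motif YAML) or, if the config carries a
``simulate`` block, a synthetic dataset written to ``outdir/inputs`` first
and then analysed exactly like real data.  Outputs: ``events.tsv``,
``enrichment.json``, ``cluster.tsv``, ``pact.tsv`` and a ``manifest.json``
(package/python versions, seed, config hash, output checksums) sufficient
to re-run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import os
import sys
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

from . import __version__
from .cluster import count_distances, heatmap_table, hierarchical_cluster
from .content import (
    ANCESTRAL_PROFILE,
    read_copy_numbers,
    read_taxon_metrics,
    summarize,
    write_copy_numbers,
)
from .pact import compare_centriole_groups, pact_ratio, read_fasta, read_motifs, records_to_rows
from .reconcile import (
    ConstraintSet,
    infer_events,
    merge_event_maps,
    read_constraints,
    tally_events,
    write_events_tsv,
)
from .simulate import SimulationConfig, simulate_dataset
from .stats import enrichment_test
from .trees import count_lineages, parse_newick, read_annotations, write_annotations, write_newick

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the input context."""


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    tree: str | None = None
    annotations: str | None = None
    counts: str | None = None
    metrics: str | None = None
    fasta: str | None = None
    ref_id: str | None = None
    motifs: str | None = None
    constraints: str | None = None
    root_counts: dict[str, int] = field(default_factory=lambda: dict(ANCESTRAL_PROFILE))
    cluster_metric: str = "euclidean"
    cluster_linkage: str = "complete"
    simulate: dict | None = None

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)}")
        if "outdir" not in data:
            raise PipelineError("config: 'outdir' is required")
        return cls(**data)


def _require(path: str | None, stage: str, what: str) -> str:
    if path is None:
        raise PipelineError(f"{stage}: no {what} configured")
    if not os.path.exists(path):
        raise PipelineError(f"{stage}: {what} not found: {path}")
    return path


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_inputs(cfg: RunConfig) -> None:
    """Materialize a simulated dataset as ordinary input files."""
    indir = os.path.join(cfg.outdir, "inputs")
    os.makedirs(indir, exist_ok=True)
    sim_params = dict(cfg.simulate or {})
    sim_cfg = SimulationConfig(**sim_params)
    ds = simulate_dataset(sim_cfg, cfg.seed)
    cfg.tree = os.path.join(indir, "tree.nwk")
    with open(cfg.tree, "w") as fh:
        fh.write(write_newick(ds.tree) + "\n")
    cfg.annotations = os.path.join(indir, "nodes.tsv")
    write_annotations(ds.tree, cfg.annotations)
    cfg.counts = os.path.join(indir, "counts.tsv")
    write_copy_numbers(ds.matrix, cfg.counts)
    cfg.metrics = os.path.join(indir, "metrics.tsv")
    ds.metrics.to_csv(cfg.metrics, sep="\t", index_label="taxon")
    cfg.fasta = os.path.join(indir, "orc1.faa")
    cfg.ref_id = "REFERENCE"
    with open(cfg.fasta, "w") as fh:
        fh.write(f">REFERENCE\n{ds.reference}\n")
        for taxon in sorted(ds.sequences):
            fh.write(f">{taxon}\n{ds.sequences[taxon]}\n")
    cfg.motifs = os.path.join(indir, "motifs.yaml")
    with open(cfg.motifs, "w") as fh:
        yaml.safe_dump(
            {"motifs": [{"start": s, "end": e} for s, e in ds.motifs.intervals]}, fh
        )


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Run every configured stage; returns the manifest dictionary."""
    os.makedirs(cfg.outdir, exist_ok=True)
    outputs: dict[str, str] = {}

    if cfg.simulate is not None:
        try:
            _write_inputs(cfg)
        except Exception as exc:
            raise PipelineError(f"simulate: {exc}") from exc

    # --- tree ------------------------------------------------------------
    tree_path = _require(cfg.tree, "tree", "species tree")
    try:
        with open(tree_path) as fh:
            tree = parse_newick(fh.read())
        if cfg.annotations:
            read_annotations(tree, _require(cfg.annotations, "tree", "annotation sidecar"))
        lineages = count_lineages(tree)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"tree: {tree_path}: {exc}") from exc

    # --- reconciliation --------------------------------------------------
    counts_path = _require(cfg.counts, "reconcile", "copy-number matrix")
    try:
        matrix = read_copy_numbers(counts_path)
        constraints = (
            read_constraints(cfg.constraints) if cfg.constraints else ConstraintSet()
        )
        event_maps = {}
        for family in matrix.columns:
            event_maps[family] = infer_events(
                tree,
                matrix[family].to_dict(),
                root_count=cfg.root_counts.get(family, 1),
                constraints=constraints,
                family=family,
            )
        events_path = os.path.join(cfg.outdir, "events.tsv")
        write_events_tsv(event_maps, events_path)
        outputs["events"] = events_path
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"reconcile: {counts_path}: {exc}") from exc

    # --- enrichment ------------------------------------------------------
    try:
        merged = merge_event_maps(event_maps.values())
        tally = tally_events(event_maps, lineages)
        enrich: dict[str, Any] = {
            "tally": {
                "per_family": {
                    f: {"losses": l, "duplications": d}
                    for f, (l, d) in tally.per_family.items()
                },
                "total_losses": tally.total_losses,
                "total_duplications": tally.total_duplications,
                "class_tallies": tally.class_tallies,
            }
        }
        for etype, klass in (("loss", "parasitic"), ("duplication", "wgd")):
            key = f"{etype}_{klass}"
            try:
                for construction in ("concat-margins", "placement"):
                    res = enrichment_test(
                        merged, lineages, etype, klass, construction=construction
                    )
                    enrich[f"{key}:{construction}"] = {
                        "table": res.extras["table"],
                        "statistic": res.statistic,
                        "P": res.pvalue,
                        "method": res.method,
                    }
            except ValueError as exc:
                enrich[key] = {"skipped": str(exc)}
        enrich_path = os.path.join(cfg.outdir, "enrichment.json")
        with open(enrich_path, "w") as fh:
            json.dump(enrich, fh, indent=2, sort_keys=True)
            fh.write("\n")
        outputs["enrichment"] = enrich_path
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"enrich: {exc}") from exc

    # --- clustering ------------------------------------------------------
    try:
        metrics = read_taxon_metrics(cfg.metrics) if cfg.metrics else None
        distances = count_distances(matrix, metric=cfg.cluster_metric)
        dend = hierarchical_cluster(distances, linkage=cfg.cluster_linkage)
        table = heatmap_table(dend, matrix, metrics)
        cluster_path = os.path.join(cfg.outdir, "cluster.tsv")
        table.to_csv(cluster_path, sep="\t", index_label="taxon")
        outputs["cluster"] = cluster_path
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"cluster: {exc}") from exc

    # --- PACT ------------------------------------------------------------
    if cfg.fasta:
        fasta_path = _require(cfg.fasta, "pact", "ORC1 FASTA")
        try:
            seqs = read_fasta(fasta_path)
            ref_id = cfg.ref_id or next(iter(seqs))
            if ref_id not in seqs:
                raise ValueError(f"reference id {ref_id!r} not in FASTA")
            motifs = read_motifs(_require(cfg.motifs, "pact", "motif config"))
            cent: dict[str, bool | None] = {}
            if metrics is not None and "centrioles" in metrics.columns:
                for taxon, v in metrics["centrioles"].items():
                    cent[taxon] = None if str(v) == "NA" else bool(int(v))
            records = []
            for taxon, seq in seqs.items():
                if taxon == ref_id:
                    continue
                records.append(
                    pact_ratio(
                        seqs[ref_id], seq, motifs, taxon=taxon,
                        centrioles=cent.get(taxon),
                    )
                )
            pact_path = os.path.join(cfg.outdir, "pact.tsv")
            rows = records_to_rows(records)
            cols = list(rows[0]) if rows else []
            with open(pact_path, "w") as fh:
                fh.write("\t".join(cols) + "\n")
                for row in rows:
                    fh.write("\t".join(_fmt(row[c]) for c in cols) + "\n")
            outputs["pact"] = pact_path
            has_both = any(r.centrioles is True for r in records) and any(
                r.centrioles is False for r in records
            )
            if has_both:
                comp = compare_centriole_groups(records)
                comp_path = os.path.join(cfg.outdir, "pact_comparison.json")
                with open(comp_path, "w") as fh:
                    json.dump(
                        {
                            k: {"U": r.statistic, "P": r.pvalue, **r.extras}
                            for k, r in comp.items()
                        },
                        fh,
                        indent=2,
                        sort_keys=True,
                    )
                    fh.write("\n")
                outputs["pact_comparison"] = comp_path
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"pact: {fasta_path}: {exc}") from exc

    # --- manifest --------------------------------------------------------
    cfg_dict = {
        k: getattr(cfg, k) for k in cfg.__dataclass_fields__ if k != "outdir"
    }
    cfg_blob = yaml.safe_dump(cfg_dict, sort_keys=True).encode()
    manifest = {
        "package": "orcevo",
        "version": __version__,
        "python": sys.version.split()[0],
        "seed": cfg.seed,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_blob).hexdigest(),
        "summary": {
            "n_taxa": int(len(matrix)),
            "n_lineages": len(lineages),
            "mean_subunits": summarize(matrix).mean_subunits
            if set(matrix.columns) == set(ANCESTRAL_PROFILE)
            else None,
        },
        "outputs": {k: {"path": v, "sha256": _sha256(v)} for k, v in outputs.items()},
    }
    manifest_path = os.path.join(cfg.outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)
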