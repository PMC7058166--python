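"""Per-species subunit copy numbers, genome metrics and configuration classes.

The replication-initiation gene families tracked by default are the pooled
``CDC6/ORC1`` family (the two AAA+ ATPase initiator paralogs are counted
together because deeply diverged sequences often cannot be assigned to one or
the other) and ``ORC2``–``ORC5``.  The ancestral eukaryotic configuration is
taken to be two CDC6/ORC1 copies plus one copy of each of ORC2–5, i.e. six
subunits in total.

A taxon's copy-number row is summarised into one of four configuration
classes relative to that reference profile:

``ancestral``
    exactly the reference profile;
``expanded``
    at least the reference everywhere and strictly more somewhere;
``reduced``
    at most the reference everywhere and strictly fewer somewhere;
``mixed``
    extra paralogs in some families alongside losses in others.

Genome metrics are normalised the way large cross-eukaryote comparisons
usually display them: genome size on a log10 scale relative to the largest
genome in the data set, gene content linearly relative to the largest
proteome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_FAMILIES",
    "ANCESTRAL_PROFILE",
    "CONFIGURATION_CLASSES",
    "classify_configuration",
    "classify_matrix",
    "normalize_metrics",
    "summarize",
    "MatrixSummary",
    "read_copy_numbers",
    "write_copy_numbers",
    "read_taxon_metrics",
]

DEFAULT_FAMILIES: tuple[str, ...] = ("CDC6/ORC1", "ORC2", "ORC3", "ORC4", "ORC5")

#: LECA reference: 2 CDC6/ORC1 copies, 1 copy of each of ORC2-5.
ANCESTRAL_PROFILE: Mapping[str, int] = {
    "CDC6/ORC1": 2,
    "ORC2": 1,
    "ORC3": 1,
    "ORC4": 1,
    "ORC5": 1,
}

CONFIGURATION_CLASSES = ("ancestral", "expanded", "reduced", "mixed")


def _as_profile(values, families: Sequence[str] | None) -> dict[str, int]:
    if isinstance(values, Mapping):
        return {str(k): int(v) for k, v in values.items()}
    if families is None:
        raise ValueError("family names required for positional counts")
    values = list(values)
    if len(values) != len(families):
        raise ValueError("count vector length does not match family list")
    return {f: int(v) for f, v in zip(families, values)}


def classify_configuration(
    row,
    reference: Mapping[str, int] = ANCESTRAL_PROFILE,
    families: Sequence[str] | None = None,
) -> str:
    """Classify one taxon's per-family counts against a reference profile.

    ``row`` may be a mapping family -> count or a positional sequence paired
    with ``families``.  The four classes are exhaustive and mutually
    exclusive; family order is irrelevant.
    """
    row_map = _as_profile(row, families or list(reference))
    if set(row_map) != set(reference):
        raise ValueError(
            f"family sets differ: {sorted(row_map)} vs {sorted(reference)}"
        )
    if any(v < 0 for v in row_map.values()):
        raise ValueError("negative copy number")
    above = any(row_map[f] > reference[f] for f in reference)
    below = any(row_map[f] < reference[f] for f in reference)
    if not above and not below:
        return "ancestral"
    if above and not below:
        return "expanded"
    if below and not above:
        return "reduced"
    return "mixed"


def classify_matrix(
    matrix: pd.DataFrame, reference: Mapping[str, int] = ANCESTRAL_PROFILE
) -> pd.Series:
    """Configuration class per taxon (index) of a copy-number matrix."""
    _check_matrix(matrix)
    return pd.Series(
        {
            taxon: classify_configuration(matrix.loc[taxon].to_dict(), reference)
            for taxon in matrix.index
        },
        name="configuration",
    ).loc[matrix.index]


@dataclass(frozen=True)
class MatrixSummary:
    """Copy-number matrix digest: mean total subunits, extreme taxa and the
    per-configuration-class tallies."""

    n_taxa: int
    mean_subunits: float
    min_taxon: str
    min_count: int
    max_taxon: str
    max_count: int
    class_tally: dict[str, int]
    single_cdc6_orc1: int  # taxa retaining a single CDC6/ORC1 copy


def summarize(
    matrix: pd.DataFrame, reference: Mapping[str, int] = ANCESTRAL_PROFILE
) -> MatrixSummary:
    """Digest a copy-number matrix (mean subunit count, extremes, classes)."""
    _check_matrix(matrix)
    if matrix.empty:
        raise ValueError("empty copy-number matrix")
    totals = matrix.sum(axis=1)
    classes = classify_matrix(matrix, reference)
    tally = {cls: int((classes == cls).sum()) for cls in CONFIGURATION_CLASSES}
    pooled = "CDC6/ORC1"
    single = int((matrix[pooled] == 1).sum()) if pooled in matrix.columns else 0
    return MatrixSummary(
        n_taxa=len(matrix),
        mean_subunits=float(totals.mean()),
        min_taxon=str(totals.idxmin()),
        min_count=int(totals.min()),
        max_taxon=str(totals.idxmax()),
        max_count=int(totals.max()),
        class_tally=tally,
        single_cdc6_orc1=single,
    )


def normalize_metrics(metrics: pd.DataFrame) -> pd.DataFrame:
    """Normalise genome metrics for heatmap display.

    Input columns: ``genome_size_bp`` and ``gene_count`` (taxon as index).
    Output adds ``gs_norm`` = log10(GS) / log10(max GS) and ``gc_norm`` =
    GC / max GC, both in (0, 1] with the maximal taxon at exactly 1.0.
    """
    for col in ("genome_size_bp", "gene_count"):
        if col not in metrics.columns:
            raise ValueError(f"metrics table lacks column {col!r}")
        bad = metrics.index[metrics[col] <= 0]
        if len(bad):
            raise ValueError(
                f"non-positive {col} for taxa: {', '.join(map(str, bad))}"
            )
    out = metrics.copy()
    log_gs = np.log10(out["genome_size_bp"].astype(float))
    out["gs_norm"] = log_gs / log_gs.max()
    out["gc_norm"] = out["gene_count"].astype(float) / out["gene_count"].max()
    return out


# ---------------------------------------------------------------------------
# TSV interfaces
# ---------------------------------------------------------------------------

def _check_matrix(matrix: pd.DataFrame) -> None:
    if matrix.index.has_duplicates:
        dupes = matrix.index[matrix.index.duplicated()].unique()
        raise ValueError("duplicate taxon labels: " + ", ".join(map(str, dupes)))
    if (matrix.values < 0).any():
        raise ValueError("copy-number matrix has negative entries")


def read_copy_numbers(path) -> pd.DataFrame:
    """Read a taxa x families copy-number TSV (first column = taxon label)."""
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    matrix = matrix.astype(int)
    _check_matrix(matrix)
    return matrix


def write_copy_numbers(matrix: pd.DataFrame, path) -> None:
    _check_matrix(matrix)
    matrix.to_csv(path, sep="\t", index_label="taxon")


def read_taxon_metrics(path) -> pd.DataFrame:
    """Read the per-taxon metrics TSV: columns ``taxon``, ``genome_size_bp``,
    ``gene_count``, ``lifestyle`` (parasite|nonparasite), ``centrioles``
    ({0,1,NA})."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    required = {"genome_size_bp", "gene_count", "lifestyle"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"metrics table lacks columns: {sorted(missing)}")
    bad = set(table["lifestyle"]) - {"parasite", "nonparasite"}
    if bad:
        raise ValueError(f"bad lifestyle values: {sorted(bad)}")
    return table
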