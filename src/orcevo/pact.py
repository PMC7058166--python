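"""PACT-region conservation of ORC1 relative to the human reference.

Human ORC1 carries two short C-terminal motifs (the PACT region) that
target the protein to the centrosome.  If that role were ancestral, the
alignment positions corresponding to the motifs should be better conserved
in centriole-bearing eukaryotes than in lineages that lost centrioles.
The analysis here quantifies that:

1. each taxon's ORC1 is globally aligned to the reference sequence
   (Needleman–Wunsch/Gotoh with affine gaps, BLOSUM62 by default);
2. alignment columns are split into *motif* columns (reference residue
   inside a PACT motif) and *background* columns (everything else;
   reference-gap columns are background by definition);
3. identity and similarity are computed per column set — similarity uses
   the Fitch (1966) criterion, amino-acid pairs whose closest codons differ
   by at most one nucleotide;
4. each taxon's motif measures are divided by its background measures, and
   the ratio distributions of centriole-bearing vs centriole-lacking taxa
   are compared with a two-tailed Mann–Whitney U test.

A ratio of 1 means the motifs are no better conserved than the rest of the
protein; ratios above 1 indicate excess motif conservation.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .stats import StatResult, mann_whitney

__all__ = [
    "AlignmentPair",
    "MotifSpec",
    "ConservationRecord",
    "AlignmentError",
    "global_align",
    "split_by_motifs",
    "conservation_measures",
    "fitch_distance_matrix",
    "fitch_distance",
    "pact_ratio",
    "compare_centriole_groups",
    "read_fasta",
    "read_motifs",
    "records_to_rows",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
NEG = -1e18  # effectively -infinity for the DP


class AlignmentError(ValueError):
    """Bad sequence input or degenerate alignment."""


# ---------------------------------------------------------------------------
# Fitch (1966) minimum-codon-change distances
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1)
def fitch_distance_matrix() -> dict[tuple[str, str], int]:
    """Minimum nucleotide changes between codons of two amino acids.

    Derived from the standard genetic code at call time; symmetric, zero on
    the diagonal, values in {0, 1, 2, 3}.  Stop codons are excluded.
    """
    code = unambiguous_dna_by_id[1].forward_table  # codon -> amino acid
    codons_by_aa: dict[str, list[str]] = {}
    for codon, aa in code.items():
        codons_by_aa.setdefault(aa, []).append(codon)
    out: dict[tuple[str, str], int] = {}
    for a in AMINO_ACIDS:
        for b in AMINO_ACIDS:
            d = min(
                sum(x != y for x, y in zip(ca, cb))
                for ca in codons_by_aa[a]
                for cb in codons_by_aa[b]
            )
            out[(a, b)] = d
    return out


def fitch_distance(a: str, b: str) -> int:
    """Fitch distance between two residues; unknowns (X) are maximally
    distant unless identical."""
    if a == b:
        return 0
    return fitch_distance_matrix().get((a, b), 3)


# ---------------------------------------------------------------------------
# Global alignment (Gotoh affine gaps)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentPair:
    """One pairwise global alignment; rows are equal-length gapped strings.

    ``ref_index[k]`` is the 1-based reference residue index at column ``k``,
    or ``None`` on reference-gap columns.
    """

    ref: str
    query: str
    score: float
    ref_index: tuple[int | None, ...]

    def __post_init__(self):
        if len(self.ref) != len(self.query):
            raise AlignmentError("alignment rows differ in length")

    def __len__(self) -> int:
        return len(self.ref)

    def columns(self) -> list[tuple[str, str]]:
        return list(zip(self.ref, self.query))


def _check_sequence(seq: str, name: str) -> str:
    if not seq:
        raise AlignmentError(f"{name}: empty sequence")
    seq = seq.upper()
    bad = set(seq) - set(AMINO_ACIDS + "X")
    if bad:
        raise AlignmentError(
            f"{name}: illegal residue(s) {sorted(bad)} (20 amino acids + X allowed)"
        )
    return seq


@lru_cache(maxsize=4)
def _matrix_as_array(name: str) -> tuple[np.ndarray, dict[str, int]]:
    mat = substitution_matrices.load(name)
    alpha = "".join(mat.alphabet)
    idx = {ch: i for i, ch in enumerate(alpha)}
    return np.asarray(mat, dtype=float), idx


def global_align(
    ref: str,
    query: str,
    matrix: str = "BLOSUM62",
    gap_open: float = -10.0,
    gap_extend: float = -1.0,
) -> AlignmentPair:
    """Optimal global alignment of two protein sequences, affine gaps.

    ``gap_open`` scores the first residue of a gap, ``gap_extend`` each
    further residue (a length-L gap scores ``gap_open + (L-1) * gap_extend``).
    End gaps are penalized.  Traceback ties are broken in fixed operator
    order — match/mismatch, then gap in query, then gap in reference — so
    the output is deterministic.
    """
    a = _check_sequence(ref, "reference")
    b = _check_sequence(query, "query")
    sub, idx = _matrix_as_array(matrix)
    ai = np.array([idx[ch] for ch in a])
    bi = np.array([idx[ch] for ch in b])
    n, m = len(a), len(b)
    go, ge = float(gap_open), float(gap_extend)

    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in query (consumes reference)
    Y = np.full((n + 1, m + 1), NEG)  # gap in reference (consumes query)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = go + (i - 1) * ge
    for j in range(1, m + 1):
        Y[0, j] = go + (j - 1) * ge

    scores = sub[np.ix_(ai, bi)]  # (n, m) substitution scores
    karr = np.arange(m + 1, dtype=float)
    for i in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = scores[i - 1] + prev_best[:-1]
        X[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:] + go, Y[i - 1, 1:] + go), X[i - 1, 1:] + ge
        )
        base = np.maximum(M[i], X[i])  # Y's same-row predecessors
        running = np.maximum.accumulate(base[:-1] - karr[:-1] * ge)
        Y[i, 1:] = go + karr[:-1] * ge + running

    # traceback; ties: M (diagonal) > X (up) > Y (left)
    i, j = n, m
    finals = (M[n, m], X[n, m], Y[n, m])
    state = int(np.argmax([finals[0] + 1e-9, finals[1], finals[2]]))
    score = max(finals)
    ra: list[str] = []
    qa: list[str] = []
    while i > 0 or j > 0:
        if state == 0:  # M: a[i-1] ~ b[j-1]
            ra.append(a[i - 1])
            qa.append(b[j - 1])
            target = M[i, j] - scores[i - 1, j - 1]
            i, j = i - 1, j - 1
            state = _pick_state(M[i, j], X[i, j], Y[i, j], target)
        elif state == 1:  # X: a[i-1] ~ gap
            ra.append(a[i - 1])
            qa.append(GAP)
            cands = (M[i - 1, j] + go, X[i - 1, j] + ge, Y[i - 1, j] + go)
            state = _pick_candidate(cands, X[i, j])
            i -= 1
        else:  # Y: gap ~ b[j-1]
            ra.append(GAP)
            qa.append(b[j - 1])
            cands = (M[i, j - 1] + go, X[i, j - 1] + go, Y[i, j - 1] + ge)
            state = _pick_candidate(cands, Y[i, j])
            j -= 1
        if i == 0 and j == 0:
            break
    ra.reverse()
    qa.reverse()
    ref_row = "".join(ra)
    qry_row = "".join(qa)
    ref_index: list[int | None] = []
    pos = 0
    for ch in ref_row:
        if ch == GAP:
            ref_index.append(None)
        else:
            pos += 1
            ref_index.append(pos)
    return AlignmentPair(ref_row, qry_row, float(score), tuple(ref_index))


def _pick_state(m: float, x: float, y: float, target: float) -> int:
    for k, v in enumerate((m, x, y)):
        if abs(v - target) < 1e-6:
            return k
    raise AssertionError("traceback lost the optimal path")  # pragma: no cover


def _pick_candidate(cands: tuple[float, float, float], target: float) -> int:
    for k, v in enumerate(cands):
        if abs(v - target) < 1e-6:
            return k
    raise AssertionError("traceback lost the optimal path")  # pragma: no cover


# ---------------------------------------------------------------------------
# Motifs and conservation measures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifSpec:
    """Non-overlapping 1-based inclusive intervals on the reference."""

    intervals: tuple[tuple[int, int], ...]

    def __post_init__(self):
        ivs = sorted(self.intervals)
        for start, end in ivs:
            if not (1 <= start <= end):
                raise ValueError(f"bad motif interval ({start}, {end})")
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise ValueError("motif intervals overlap")
        object.__setattr__(self, "intervals", tuple(ivs))

    def contains(self, position: int) -> bool:
        return any(s <= position <= e for s, e in self.intervals)

    def validate_against(self, ref_length: int) -> None:
        for start, end in self.intervals:
            if end > ref_length:
                raise ValueError(
                    f"motif interval ({start}, {end}) exceeds reference length "
                    f"{ref_length}"
                )

    @property
    def span(self) -> int:
        return sum(e - s + 1 for s, e in self.intervals)


def split_by_motifs(
    aln: AlignmentPair, motifs: MotifSpec
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Partition alignment columns into (motif, background).

    A column belongs to the motif set iff its reference residue index falls
    inside a motif interval; reference-gap columns always go to background.
    """
    ref_len = sum(1 for ch in aln.ref if ch != GAP)
    motifs.validate_against(ref_len)
    motif_cols: list[tuple[str, str]] = []
    background: list[tuple[str, str]] = []
    for (r, q), pos in zip(aln.columns(), aln.ref_index):
        if pos is not None and motifs.contains(pos):
            motif_cols.append((r, q))
        else:
            background.append((r, q))
    return motif_cols, background


def conservation_measures(
    columns: Sequence[tuple[str, str]], similarity_threshold: int = 1
) -> tuple[float, float]:
    """(identity, similarity) over a set of aligned columns.

    Columns with a gap in either row are excluded from the denominator.
    Similarity counts residue pairs whose Fitch distance is at most
    ``similarity_threshold`` (identical pairs always count), so
    similarity >= identity.
    """
    if not columns:
        raise AlignmentError("empty column set")
    paired = [(r, q) for r, q in columns if r != GAP and q != GAP]
    if not paired:
        raise AlignmentError("no gap-free columns to measure")
    ident = sum(1 for r, q in paired if r == q)
    simil = sum(1 for r, q in paired if fitch_distance(r, q) <= similarity_threshold)
    n = len(paired)
    return ident / n, simil / n


@dataclass(frozen=True)
class ConservationRecord:
    """Per-taxon motif-vs-background conservation, plus centriole status."""

    taxon: str
    identity_pact: float
    identity_nonpact: float
    similarity_pact: float
    similarity_nonpact: float
    identity_ratio: float
    similarity_ratio: float
    centrioles: bool | None = None


def pact_ratio(
    ref: str,
    query: str,
    motifs: MotifSpec,
    taxon: str = "query",
    centrioles: bool | None = None,
    similarity_threshold: int = 1,
    matrix: str = "BLOSUM62",
    gap_open: float = -10.0,
    gap_extend: float = -1.0,
) -> ConservationRecord:
    """Align ``query`` to ``ref``, split by motifs and return the motif /
    background identity and similarity ratios.

    Raises :class:`AlignmentError` if a background measure is zero (ratio
    undefined).
    """
    aln = global_align(ref, query, matrix=matrix, gap_open=gap_open, gap_extend=gap_extend)
    motif_cols, background = split_by_motifs(aln, motifs)
    if not motif_cols:
        raise AlignmentError("no motif columns in alignment")
    id_p, sim_p = conservation_measures(motif_cols, similarity_threshold)
    id_b, sim_b = conservation_measures(background, similarity_threshold)
    if id_b == 0 or sim_b == 0:
        raise AlignmentError(
            f"{taxon}: background identity/similarity is zero, ratio undefined"
        )
    return ConservationRecord(
        taxon=taxon,
        identity_pact=id_p,
        identity_nonpact=id_b,
        similarity_pact=sim_p,
        similarity_nonpact=sim_b,
        identity_ratio=id_p / id_b,
        similarity_ratio=sim_p / sim_b,
        centrioles=centrioles,
    )


def compare_centriole_groups(
    records: Iterable[ConservationRecord],
) -> dict[str, StatResult]:
    """Two-tailed Mann–Whitney comparison of the identity- and
    similarity-ratio distributions between centriole-bearing and
    centriole-lacking taxa; unknown-status taxa are excluded."""
    with_c = [r for r in records if r.centrioles is True]
    without_c = [r for r in records if r.centrioles is False]
    if not with_c or not without_c:
        raise ValueError(
            "both centriole groups must be non-empty "
            f"(got {len(with_c)} with, {len(without_c)} without)"
        )
    out: dict[str, StatResult] = {}
    for key, attr in (
        ("identity_ratio", "identity_ratio"),
        ("similarity_ratio", "similarity_ratio"),
    ):
        xs = [getattr(r, attr) for r in with_c]
        ys = [getattr(r, attr) for r in without_c]
        res = mann_whitney(xs, ys, alternative="two-sided")
        extras = dict(res.extras)
        extras.update(
            median_centrioles=float(np.median(xs)),
            median_no_centrioles=float(np.median(ys)),
        )
        out[key] = StatResult(
            res.name, res.statistic, res.pvalue, res.tails, res.method, extras
        )
    return out


# ---------------------------------------------------------------------------
# File interfaces
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """FASTA -> ordered {id: sequence} (first header token as id)."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seqs:
            raise AlignmentError(f"duplicate FASTA id: {rec.id}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise AlignmentError(f"no sequences in {path}")
    return seqs


def read_motifs(source) -> MotifSpec:
    """Motif YAML: a list of {start, end} (1-based inclusive) under the key
    ``motifs`` (or a bare list)."""
    import yaml

    if isinstance(source, str):
        with open(source) as fh:
            data = yaml.safe_load(fh)
    else:
        data = yaml.safe_load(source)
    if isinstance(data, Mapping):
        data = data.get("motifs", [])
    intervals = tuple((int(d["start"]), int(d["end"])) for d in data)
    if not intervals:
        raise ValueError("no motif intervals in config")
    return MotifSpec(intervals)


def records_to_rows(records: Iterable[ConservationRecord]) -> list[dict]:
    rows = []
    for r in records:
        rows.append(
            {
                "taxon": r.taxon,
                "identity_PACT": r.identity_pact,
                "identity_nonPACT": r.identity_nonpact,
                "similarity_PACT": r.similarity_pact,
                "similarity_nonPACT": r.similarity_nonpact,
                "identity_ratio": r.identity_ratio,
                "similarity_ratio": r.similarity_ratio,
                "centrioles": "NA" if r.centrioles is None else int(r.centrioles),
            }
        )
    return rows
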