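"""Aligner, Fitch similarity, motif splitting and conservation ratios."""

import numpy as np
import pytest
from Bio import Align
from Bio.Align import substitution_matrices

from orcevo.pact import (
    AMINO_ACIDS,
    AlignmentError,
    AlignmentPair,
    MotifSpec,
    compare_centriole_groups,
    conservation_measures,
    fitch_distance,
    fitch_distance_matrix,
    global_align,
    pact_ratio,
    split_by_motifs,
)


def _biopython_aligner():
    al = Align.PairwiseAligner(mode="global", open_gap_score=-10, extend_gap_score=-1)
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    return al


def test_identical_sequences_align_gap_free():
    aln = global_align("MKVLITAA", "MKVLITAA")
    assert aln.ref == aln.query == "MKVLITAA"
    assert conservation_measures(aln.columns()) == (1.0, 1.0)


def test_align_textbook_pair_matches_independent_dp():
    aln = global_align("HEAGAWGHEE", "PAWHEAE")
    assert aln.score == _biopython_aligner().score("HEAGAWGHEE", "PAWHEAE")
    assert aln.ref.replace("-", "") == "HEAGAWGHEE"
    assert aln.query.replace("-", "") == "PAWHEAE"


def test_short_query_forces_gap_columns():
    aln = global_align("AAAAA", "A")
    assert sum(1 for q in aln.query if q == "-") == 4


def test_align_score_equals_oracle_on_random_pairs():
    """Optimal score matches Biopython's independent DP on 200 random
    short pairs (the full affine-gap search space)."""
    rng = np.random.default_rng(6)
    oracle = _biopython_aligner()
    letters = np.array(list(AMINO_ACIDS))
    for _ in range(200):
        n1, n2 = rng.integers(1, 13, size=2)
        a = "".join(rng.choice(letters, size=n1))
        b = "".join(rng.choice(letters, size=n2))
        aln = global_align(a, b)
        assert aln.score == oracle.score(a, b), (a, b)
        assert aln.ref.replace("-", "") == a
        assert aln.query.replace("-", "") == b


def test_align_input_validation():
    with pytest.raises(AlignmentError):
        global_align("", "AAA")
    with pytest.raises(AlignmentError):
        global_align("AC1", "AAA")


def test_fitch_matrix_properties_and_spot_values():
    table = fitch_distance_matrix()
    for a in AMINO_ACIDS:
        assert table[(a, a)] == 0
        for b in AMINO_ACIDS:
            assert table[(a, b)] == table[(b, a)]
            assert 0 <= table[(a, b)] <= 3
    # GAU/GAC (Asp) vs GAA/GAG (Glu): one change
    assert fitch_distance("D", "E") == 1
    # UGG (Trp) vs CCN (Pro): two changes minimum
    assert fitch_distance("W", "P") == 2
    # Met (AUG) vs Tyr (UAU/UAC): all three positions differ
    assert fitch_distance("M", "Y") == 3


def test_conservation_measures_counts_similar_pairs():
    cols = [("A", "A"), ("D", "E"), ("W", "P")]
    ident, sim = conservation_measures(cols, similarity_threshold=1)
    assert ident == pytest.approx(1 / 3)
    assert sim == pytest.approx(2 / 3)  # D~E is one codon change away
    with pytest.raises(AlignmentError):
        conservation_measures([("A", "-"), ("C", "-")])


def test_similarity_never_below_identity():
    rng = np.random.default_rng(8)
    letters = np.array(list(AMINO_ACIDS))
    for _ in range(50):
        a = "".join(rng.choice(letters, size=30))
        b = "".join(rng.choice(letters, size=int(rng.integers(20, 40))))
        aln = global_align(a, b)
        ident, sim = conservation_measures(aln.columns())
        assert sim >= ident


def test_split_by_motifs():
    aln = AlignmentPair("ACDEFG", "ACDEFG", 0.0, (1, 2, 3, 4, 5, 6))
    motif, back = split_by_motifs(aln, MotifSpec(((1, 3),)))
    assert len(motif) == 3 and len(back) == 3
    motif, back = split_by_motifs(aln, MotifSpec(((2, 3), (5, 5))))
    assert len(motif) == 3
    # reference-gap columns fall to background even inside a motif span
    gapped = AlignmentPair("AC-DEF", "ACXDEF", 0.0, (1, 2, None, 3, 4, 5))
    motif, back = split_by_motifs(gapped, MotifSpec(((1, 3),)))
    assert len(motif) == 3 and ("-", "X") in back
    with pytest.raises(ValueError, match="exceeds reference length"):
        split_by_motifs(aln, MotifSpec(((1, 99),)))


def test_motif_spec_validation():
    with pytest.raises(ValueError):
        MotifSpec(((3, 2),))
    with pytest.raises(ValueError):
        MotifSpec(((1, 5), (4, 8)))


def test_pact_ratio_identity_case_and_constructed_fixture():
    ref = "ACDEFGHIKL" * 4
    motifs = MotifSpec(((1, 10),))
    same = pact_ratio(ref, ref, motifs)
    assert same.identity_ratio == 1.0 and same.similarity_ratio == 1.0
    # mutate exactly half of the background positions, keep the motif intact:
    # identity ratio = 1.0 / 0.5 = 2
    q = list(ref)
    for k in range(10, 40, 2):
        q[k] = "W" if q[k] != "W" else "Y"
    rec = pact_ratio(ref, "".join(q), motifs)
    assert rec.identity_pact == 1.0
    assert rec.identity_nonpact == pytest.approx(0.5)
    assert rec.identity_ratio == pytest.approx(2.0)


def test_pact_ratio_zero_background_identity_rejected():
    ref = "AAAAAAAAAA"
    query = "AAAAAWWWWW"  # motif conserved, background fully diverged
    with pytest.raises(AlignmentError, match="ratio undefined"):
        pact_ratio(ref, query, MotifSpec(((1, 5),)))


def test_compare_centriole_groups():
    def rec(taxon, ratio, cent):
        from orcevo.pact import ConservationRecord

        return ConservationRecord(taxon, 0.5, 0.5, 0.6, 0.6, ratio, ratio, cent)

    same = [rec(f"A{i}", 1.0, True) for i in range(5)] + [
        rec(f"B{i}", 1.0, False) for i in range(5)
    ]
    out = compare_centriole_groups(same)
    assert out["identity_ratio"].pvalue == 1.0
    shifted = [rec(f"A{i}", 2.0 + i * 0.01, True) for i in range(8)] + [
        rec(f"B{i}", 1.0 + i * 0.01, False) for i in range(8)
    ]
    assert compare_centriole_groups(shifted)["identity_ratio"].pvalue < 0.01
    with pytest.raises(ValueError, match="non-empty"):
        compare_centriole_groups([rec("A", 1.0, True)])
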