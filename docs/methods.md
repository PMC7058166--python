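# Methods

This note documents the models and procedures implemented in `orcevo`, the
parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical conventions that
make every run deterministic.

## Species trees and lineages

A *lineage* is a node of the rooted species tree together with the branch
subtending it; the root is a lineage too, so a fully binary tree over `n`
taxa carries `2n − 1` lineages (263 for the 132-taxon panels typical of
cross-eukaryote studies). Multifurcations are accepted everywhere and
never binarized.

Lifestyle is propagated rootward by the all-descendants rule: an ancestral
lineage is parasitic iff every descendant species is a parasite. The rule
is idempotent and re-applied whenever leaf annotations are loaded, so the
invariant cannot be violated by a stale sidecar file.

WGD status is a three-level annotation (`none` / `reported` /
`uncertain`). The enrichment class mask uses `reported` lineages only by
default; `uncertain` (WGDs claimed by only some sources) can be included
via a flag. Internal nodes are addressed in files by the pair of extreme
(lexicographically smallest/largest) leaf labels of their clade, suffixed
with clade size when two nested clades share extremes — deterministic and
unique on any tree.

## Reconciliation (duplication/loss parsimony)

Per family, given leaf copy numbers and a root count, the inference
minimizes the total number of ±1 copy events over all ancestral
assignments subject to a Dollo-style no-regain rule: a zero-copy lineage
never has a positive-copy descendant. This is solved exactly with a
Sankoff dynamic program over copy-number states `0 .. max(count, root) + 1`
(edge cost `|parent − child|`, transitions out of state 0 forbidden).
Extending the state space one unit above the maximum observed count allows
histories that overshoot and lose again; widening it further can never
help, since any assignment using a state `s > max + 1` can be clamped to
`max + 1` without raising any edge cost. The exhaustive-enumeration oracle
in the test suite confirms optimality on random instances.

Co-optimal histories are resolved during top-down backtracking by choosing
the **smallest** ancestral state among minimizers. This places
duplications as late (tipward) and losses as early (rootward) as possible:
a family absent from a whole clade is lost once on the clade stem, and a
copy shared by two sister species is duplicated in their ancestor only if
nothing contradicts it. The choice makes output deterministic and mirrors
how curators treat species-specific paralogs.

Knowledge from gene trees that copy numbers alone cannot carry enters as
constraints: a *terminal-duplications* assertion (taxon X's extra copies
are species-specific paralogs, so ≥ k duplications must sit on its
terminal branch) and a *duplication-free stem* (no copy-number increase on
the branch into a named clade). Both are implemented as edge-cost
restrictions inside the same DP, so constrained inference is still exact;
infeasible constraint sets raise an error describing the conflict. Root
counts default to the ancestral profile (2 for the pooled CDC6/ORC1
family, 1 for ORC2–5) and are configurable per family.

Events are integers per lineage: a +2 change on one branch is two
duplication events, matching how event tallies are usually reported.
Origin events at the root are not counted.

## Configuration classes

CDC6 and ORC1 are pooled into one family throughout, because deeply
diverged initiator sequences often cannot be assigned to one or the other.
The reference (ancestral) profile is `(2, 1, 1, 1, 1)` over
`(CDC6/ORC1, ORC2..ORC5)` — six subunits. Classification of a taxon's row
against the reference is exhaustive and mutually exclusive: `ancestral`
(equal), `expanded` (≥ everywhere, > somewhere), `reduced` (≤ everywhere,
< somewhere), `mixed` (both directions). A taxon retaining a single
CDC6/ORC1 copy and one of everything else is therefore `reduced`; the
count of such single-copy taxa is also reported separately, since the
single-copy state is of independent interest and published taxon tallies
have described the "one of each subunit" cluster ambiguously.

Genome metrics are normalized for display the way large comparative
heatmaps do it: genome size as `log10(GS) / log10(max GS)`, gene content
as `GC / max GC`; both in `(0, 1]` with the maximal taxon at exactly 1.

## Enrichment statistics

All tests are implemented exactly, from first principles:

* **Fisher one-tailed.** The 2×2 table is built in concatenated-margins
  form — row 1 the event counts inside/outside the lineage class, row 2
  the lineage counts — and the P-value is the exact hypergeometric upper
  tail `P(X ≥ a)` with margins fixed, summed from the observed cell via
  log-factorials (`lgamma`); the whole-support tail returns exactly 1.0.
  This construction reproduces the published parasite-loss P-value
  (2.43e−05 from 41/69 events on 83/263 lineages) and is the default. An
  alternative *placement* construction — each event drawn onto a lineage
  without replacement, upper tail of Hypergeom(N=lineages, K=class,
  n=events) — is available via `construction="placement"`; the two answer
  slightly different questions and neither reproduces the published
  WGD-duplication P-value (2.117e−05), so the package reports both for
  that test. Under a uniform-placement null the default construction is
  conservative (measured type-I error ≈ 2% at nominal 5%).
* **Mann–Whitney U.** U is reported for the first sample. The tie-free
  exact null distribution is computed by the standard counting recurrence
  when `n1 + n2 ≤ 20`; forcing `method="exact"` with ties enumerates every
  split of the pooled midranks. Otherwise a normal approximation with the
  tie-corrected variance and a 0.5 continuity correction is used.
  Two-sided P is twice the smaller tail, capped at 1 (the R convention).
* **Spearman.** Pearson correlation of midranks; midranking subsumes the
  classical tie correction. Constant vectors are an error (ρ undefined).

No multiple-testing correction is applied anywhere: the analysis makes a
small number of pre-specified tests.

## PACT-region conservation

Each taxon's ORC1 is aligned to the reference with an affine-gap global
aligner (Gotoh three-state DP, vectorized row-wise): BLOSUM62, gap open
−10 for the first gap residue, extend −1 for each further one — defaults
in the range protein workflows use; matrix and penalties are arguments.
End gaps are penalized. Traceback ties are broken in fixed operator order
(match/mismatch, gap in query, gap in reference), so alignments are
deterministic. The aligner replaces an external MSA tool because the
analysis is strictly pairwise against one reference; scores are verified
against an independent dynamic-programming implementation in the tests.

Motif coordinates are configuration input (1-based inclusive intervals on
the reference), not hard-coded: the exact PACT motif boundaries on human
ORC1 are defined in the experimental literature rather than printed in
comparative tables. A column belongs to the motif set iff its reference
residue index lies in an interval; reference-gap columns are background by
definition. Identity and similarity are computed over columns with both
residues present (gap columns excluded from the denominator); similarity
counts pairs whose Fitch (1966) distance — the minimum number of
nucleotide changes between any codons encoding the two residues, derived
at run time from the standard genetic code — is ≤ 1, so similarity ≥
identity always. Each taxon's motif measures are divided by its background
measures; a zero background measure makes the ratio undefined and raises.
The centriole-group comparison applies the two-tailed Mann–Whitney test to
the identity- and similarity-ratio distributions, excluding taxa of
unknown centriole status.

The identity/similarity definitions are this package's explicit
reconstruction of the usual seqinr-style pairwise measures; they are the
standard pairwise-identity convention, but other denominators
(reference-length) exist and can be selected in `conservation_measures`
callers by pre-filtering columns.

## Orthology assignment

Queries are classified by gene-tree placement: walking rootward from the
query, the first clade (below the root) whose reference leaves are pure
for one family — CDC6 and ORC1 pooling into `CDC6/ORC1` — assigns its
family. Confidence is `bona_fide` with ≥ 2 supporting reference leaves,
`likely` with exactly 1, `uncertain` (and family `unassigned`) when no
pure clade exists. These tiers are a declared reconstruction of the
bona-fide/likely vocabulary; the exact published criteria live in
supplementary material not reproduced here. False species-specific
paralogs are collapsed within each (species, family) group by
single-linkage clustering at a global-identity threshold (default 0.95,
logged in output), keeping the longest sequence; the last member of a
group is never removed.

## Synthetic data

The generator's defaults are the study conditions: 132 taxa; per-branch,
per-family Poisson duplication rate 0.03 and loss rate 0.05 (≈ 69 losses
/ 263 lineages / 5 families, the observed regime); parasitic lineages —
about 25% of all lineages, marked as whole clades, matching 83/263 — lose
copies at 5× the base rate; 8 WGD branches carry a doubling pulse
(reported-WGD density ≈ 20/263, of which the generator flags the subset it
doubles). WGD candidates are restricted to clades of at most ~1/16 of the
taxa: reported WGDs are lineage-specific pulses, and doubling a deep
branch would double half the panel and push mean subunit counts far above
anything observed. With these defaults the simulated panels average ≈ 5–6.5
subunits per taxon and ≈ 70–100 loss events — the magnitude real panels
show.

Per branch the order of operations is fixed and documented: the WGD pulse
doubles the count entering the branch (increment recorded as
duplications), then Poisson duplications, then Poisson losses capped at
the available copies. Losses discarded at the zero floor are *not*
recorded, so replaying the truth reproduces the matrix exactly — the
simulator's censoring convention, and the invariant that caught a
double-counting bug during development.

Sequence simulation: a uniformly random 400-residue reference with two
C-terminal motif intervals (321–350, 371–390; ≈ 50 motif columns, the
scale of two short targeting motifs on a large protein); per-taxon copies
substitute i.i.d. per site at probability 0.5 outside motifs (deep
eukaryotic divergence) and a centriole-class-specific probability inside
(0.5/0.5 by default, i.e. no effect; power experiments halve the
centriole-class probability). No indels by default.

What the generator does **not** emulate — and hence what passing tests do
not certify about real data: phylogenetic non-independence beyond shared
branches (no rate heterogeneity across families or time), gene conversion
or HGT, realistic amino-acid substitution processes (no WAG/LG, no indels,
no site-rate variation), correlation between copy number and genome
metrics beyond the parasite/non-parasite offset, and any error in
orthology detection upstream of the copy-number matrix.

All generators take explicit seeds (replicate `i` of an experiment uses
`base_seed + i`); there is no implicit seeding anywhere, and identical
(config, seed) pairs are bit-reproducible.

## Experiments and their design choices

* **Event recovery** (16 taxa, rates 0.03/0.05, no WGD, 100 replicates):
  one gene family per replicate, since the question is consistency of the
  per-family parsimony estimator; replicates are therefore independent
  copies of the branch process. Event totals are small integers (mean ≈
  2.4), so the "within 10%" tolerance is evaluated at integer resolution,
  `|inferred − truth| ≤ max(1, 0.1 · truth)`: a sub-integer band on an
  integer quantity would collapse into the exact-match criterion.
  Parsimony can undercount (cancelling or coinciding events are
  invisible) and — rarely — overcount, because the simulator permits a
  regain after zero copies that the Dollo constraint forbids.
* **Enrichment power/null** (132 taxa — the study's sampling — 100
  replicates): events are re-inferred from the simulated leaf counts, so
  the experiment exercises the full analysis path, not the simulation
  truth.
* **PACT calibration/power** (20 taxa per centriole group): with equal
  motif probabilities the comparison P-values are checked for uniformity
  (Kolmogorov–Smirnov); with the centriole-class motif substitution
  probability halved the detection rate at α = 0.01 is measured.

## Known limitations

* Parsimony reconciliation has no notion of rate or time: on fast-evolving
  families it systematically undercounts events, and the package makes no
  attempt at likelihood-based (birth–death) reconciliation.
* The enrichment tests treat events as exchangeable across lineages;
  events produced by one multi-copy change on one branch are correlated,
  which makes the gene-content null slightly anticonservative (measured
  ≈ 9% at nominal 5%) even though the uniform-placement null is
  conservative.
* Exact reproduction of a published event mapping requires the curator's
  gene-tree judgments; the constraint interface can encode them, but the
  package does not claim to regenerate published global tallies from a
  copy-number matrix alone.
* The aligner is strictly pairwise-global; it is not a substitute for an
  MSA when one is scientifically required.
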