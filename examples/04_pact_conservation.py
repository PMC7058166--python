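"""Is the PACT region more conserved in centriole-bearing taxa?

Simulates ORC1-like proteins in which the two C-terminal motifs are
strongly conserved only in centriole-bearing taxa, computes each taxon's
motif/background identity and similarity ratios against the reference, and
compares the two groups with a two-tailed Mann-Whitney test.
"""

import numpy as np

from orcevo import MotifSpec, compare_centriole_groups, pact_ratio
from orcevo.simulate import SimulationConfig, simulate_orc1_sequences

cfg = SimulationConfig(
    motif_sub_prob_centrioles=0.15,   # motifs conserved in centriole taxa
    motif_sub_prob_no_centrioles=0.5,  # ... and free-running otherwise
)
centrioles = {f"C{i:02d}": True for i in range(12)}
centrioles.update({f"N{i:02d}": False for i in range(12)})
rng = np.random.default_rng(4)
ref, seqs = simulate_orc1_sequences(centrioles, cfg, rng)

motifs = MotifSpec(cfg.motifs)
records = [
    pact_ratio(ref, seq, motifs, taxon=t, centrioles=centrioles[t])
    for t, seq in seqs.items()
]
for r in records[:3]:
    print(f"{r.taxon}: identity motif {r.identity_pact:.2f} vs background "
          f"{r.identity_nonpact:.2f} -> ratio {r.identity_ratio:.2f}")

comp = compare_centriole_groups(records)
for key, res in comp.items():
    print(f"{key}: U = {res.statistic:.0f}, two-tailed P = {res.pvalue:.2e} "
          f"(medians {res.extras['median_centrioles']:.2f} with vs "
          f"{res.extras['median_no_centrioles']:.2f} without centrioles)")
print("Ratios near 1 mean the motifs are no better conserved than the rest")
print("of the protein; here the centriole group's excess is detected.")
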