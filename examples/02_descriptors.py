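"""Featurize peptides into the five compositional descriptor sets.

Shows single-sequence descriptor vectors and the merged dataset matrix
with all-zero features removed — the input to feature selection.
"""

import numpy as np

import pepqsar as pq

seq = "SPTCLSLAC"
aac = pq.compute_aac(seq)
dc = pq.compute_dc(seq)
tc = pq.compute_tc(seq)
print(f"sequence {seq}: AAC dim {aac.size}, DC dim {dc.size}, TC dim {tc.size}")
print(f"row sums (each must be 1): {aac.sum():.6f}, {dc.sum():.6f}, {tc.sum():.6f}")

pc = pq.compute_pc_pseaac(seq, lam=3, w=0.05)
sc = pq.compute_sc_pseaac(seq, lam=3, w=0.05)
print(f"PC-PseAAC dim {pc.size} (20+lambda), SC-PseAAC dim {sc.size} (20+2*lambda)")

dataset = pq.generate_dataset(pq.paper_like_config(seed=0))
matrix = pq.featurize_dataset(dataset, sets=("aac", "dc", "tc"))
reduced = pq.remove_zero_features(matrix)
print(f"merged matrix: {matrix.n} x {matrix.p} -> {reduced.p} features after zero removal")
# Most of the 8000 tripeptide columns never occur in ~200 short peptides,
# so zero removal shrinks the matrix dramatically.
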