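"""Pairwise ICC(A,1) similarity and the connectivity threshold.

Builds the 155 x 155 ICC matrix, finds the largest threshold t* at which
the graph stays connected (reachability 1), and binarizes at t*.
"""

import numpy as np

from cogtypology import (apply_inclusion, apply_threshold, build_icc_matrix,
                         compound_scores, default_spec, generate,
                         max_connected_threshold, standardize_and_orient)

table, _ = generate(default_spec(seed=0))
included, _ = apply_inclusion(table)
cm = standardize_and_orient(compound_scores(included))

sim = build_icc_matrix(cm)
off = sim.icc_matrix[~np.eye(sim.n, dtype=bool)]
print(f"ICC matrix: {sim.icc_matrix.shape}, off-diagonal range "
      f"[{off.min():.3f}, {off.max():.3f}]")

t_star = max_connected_threshold(sim)
thr = apply_threshold(sim, t_star)
n_edges = int(thr.adjacency.sum() / 2)
print(f"connectivity threshold t* = {t_star:.4f} "
      f"(reachability {thr.reachability:.0f}, {n_edges} edges)")
print(f"one step higher disconnects the graph: reachability at t*+1e-6 = "
      f"{apply_threshold(sim, t_star + 1e-6).reachability:.3f}")
# t* is the sparsest binary graph in which every participant still
# reaches every other; it is the graph handed to community detection.
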