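"""Using the factors as offsets instead of dividing the counts.

Count-based models (GLMs, DE tests) should receive log S_gi as an offset
so the counts keep their sampling distribution. Background entries carry
no factor — the gene is not expressed there, so the value is irrelevant —
and are masked (NaN in memory, "NA" on disk).
"""

import math

import numpy as np

import sc2pnorm as sp

truth = sp.simulate(sp.SimConfig(
    n_genes=800, n_cells=30, bias_model="cellwise",
    bias_params={"s_range": (0.5, 2.0)}, seed=4,
))
run = sp.normalize_counts(truth.cm)

offsets = run.offset().values
n_total = offsets.size
n_masked = int(np.isnan(offsets).sum())
print(f"offset matrix: {offsets.shape[0]} genes x {offsets.shape[1]} cells")
print(f"masked (background) entries: {n_masked}/{n_total} "
      f"({100 * n_masked / n_total:.1f}%)")
g, c = np.argwhere(np.isfinite(offsets))[0]
print(f"example: gene {run.nf.gene_ids[g]} in cell {run.nf.cell_ids[c]}: "
      f"Y = {truth.cm.counts[g, c]}, log S = {offsets[g, c]:+.3f} "
      f"(S = {math.exp(offsets[g, c]):.3f})")
print("a Poisson/NB model would use: log E[Y] = offset + x'beta")
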