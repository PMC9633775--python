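"""Receptor-specific contributions with spatial-autocorrelation-preserving nulls.

For each receptor, its expression map is replaced by variogram-matched
surrogate maps, the neuromodulatory similarity rebuilt and the arousal-
binned GLM refit; the receptor is significant when the model with the true
map beats the surrogate null (right-tailed rank p, FDR-corrected across
receptors). Planted loaded receptors should pass, planted null receptors
should not.
"""

import numpy as np
from scipy.spatial.distance import pdist, squareform

import dyngrad as dg

cohort = dg.make_cohort(
    seed=4, n_regions=60, n_targets=30, n_scans=3, n_frames=500,
    n_receptors=8, n_null=3, w_static=0.40, mod_amplitude=0.45, expression_noise=0.3,
)
data = np.concatenate([ts.data for ts in cohort.scans])
arousal = np.concatenate(cohort.truth.arousal_signal)
assign = dg.bin_by_arousal(arousal, n_bins=10)
mats = [dg.ConnectivityMatrix(np.corrcoef(data[assign == b].T)) for b in range(10)]
sc = dg.vectorize_pairs(cohort.truth.sc_sim)
dmat = squareform(pdist(cohort.truth.coords))

pvals = []
for i, rec in enumerate(cohort.expression.receptor_labels):
    contrib = dg.receptor_contribution(
        mats, cohort.expression, rec, sc, n_shuffles=200, distance_matrix=dmat, seed=10 + i
    )
    p = dg.sa_pvalue(
        float(contrib["r2_full_per_bin"].mean()),
        contrib["r2_surrogate"].mean(axis=1),
        tail="right",
    )
    pvals.append(p)

reject, adj = dg.fdr_bh(np.array(pvals), q=0.05)
groups = {1: "loads G1", 2: "loads G2", 3: "loads both", 4: "null"}
for rec, g, p, q_, sig in zip(
    cohort.expression.receptor_labels, cohort.expression.truth_groups, pvals, adj, reject
):
    mark = "SIGNIFICANT" if sig else "n.s."
    print(f"{rec} ({groups[g]:10s}): p = {p:.4f}, FDR q = {q_:.4f} -> {mark}")

pca = dg.receptor_pca(cohort.expression, n_pc=2)
print("receptor PCA explained variance ratio:", np.round(pca["explained_variance_ratio"], 3))

# Significant receptors are those whose specific spatial topography carries
# the neuromodulatory contribution; null receptors survive only at the FDR's
# nominal false-positive rate.
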