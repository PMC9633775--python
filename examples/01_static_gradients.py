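"""Static connectivity gradients on a synthetic cohort.

Builds a small cohort with two planted gradients, computes the study FC,
embeds it (threshold → normalized angle → diffusion map), and compares the
leading gradients with the planted maps after Procrustes alignment.
"""

import numpy as np

import dyngrad as dg

cohort = dg.make_cohort(seed=0, n_regions=60, n_targets=30, n_scans=4, n_frames=400)

# study-level FC: scan-wise Pearson matrices averaged
fcs = [dg.compute_fc(ts) for ts in cohort.scans]
study_fc = dg.ConnectivityMatrix(np.mean([c.values for c in fcs], axis=0))

grad = dg.gradients_from_connectivity(study_fc, n_components=4, density=0.10)
print("explained variance (%):", np.round(grad.explained_variance * 100, 2))

maps = cohort.truth.gradient_maps[:, :2]
ref = dg.GradientSet(maps, np.ones(2), np.full(2, 0.5))
sub = dg.GradientSet(grad.components[:, :2], grad.eigenvalues[:2], np.full(2, 0.5))
aligned = dg.procrustes_align(sub, ref)
for k in range(2):
    r = abs(np.corrcoef(aligned.components[:, k], maps[:, k])[0, 1])
    print(f"gradient {k + 1} vs planted map: |r| = {r:.3f}")

# The explained-variance vector says how much connectivity structure each
# gradient carries; the |r| values confirm the embedding recovers the
# planted spatial modes (1.0 = perfect recovery).
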