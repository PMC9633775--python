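"""Behavioral and fMRI-based arousal indices.

Estimates the per-frame behavioral index from noisy, blink-interrupted pupil
traces, builds the arousal template (per-region correlation of BOLD with the
HRF-convolved index), projects every frame onto it, and checks both readouts
against the latent arousal process the cohort was generated from.
"""

import numpy as np

import dyngrad as dg

cohort = dg.make_cohort(
    seed=1, n_regions=100, n_targets=55, n_scans=4, n_frames=512, template_gain=1.2
)

beh = [dg.behavioral_index(p, cohort.fps, cohort.tr) for p in cohort.pupil_traces]
print("eye-open ratio per scan:", [round(b.eye_open_ratio, 3) for b in beh])

template = dg.arousal_template(cohort.scans, beh)
print(
    "template vs planted amplitude map: r =",
    round(float(np.corrcoef(template.map, cohort.truth.template)[0, 1]), 3),
)

idx = np.concatenate([dg.fmri_arousal_index(ts, template).index for ts in cohort.scans])
a_true = np.concatenate(cohort.truth.arousal_signal)
beh_all = np.concatenate([b.index for b in beh])
print("behavioral index vs latent arousal: r =", round(float(np.corrcoef(beh_all, a_true)[0, 1]), 3))
print("fMRI index vs latent arousal:       r =", round(float(np.corrcoef(idx, a_true)[0, 1]), 3))

# Both readouts track the latent process; the fMRI index needs no eye
# monitoring once the template is known, which is what makes arousal-binned
# connectivity analyses possible on scans without usable pupil video.
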