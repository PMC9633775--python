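"""Arousal indices: behavioral (pupil-derived) and fMRI template projection.

The behavioral index is the per-TR median of the valid pupil samples,
normalized by the per-scan maximum (so it is scale-invariant and lies in
[0, 1]). The fMRI index spatially correlates each BOLD frame with an
"arousal template" — the per-region correlation of BOLD with the
HRF-convolved behavioral index, Fisher-z averaged across scans. Frames are
assigned to equal-size arousal bins by rank.
"""

from __future__ import annotations

import warnings

import numpy as np

from .containers import ArousalTemplate, ArousalTrace, RegionTimeSeries

__all__ = [
    "behavioral_index",
    "canonical_hrf",
    "hrf_convolve",
    "arousal_template",
    "fmri_arousal_index",
    "bin_by_arousal",
]


def behavioral_index(pupil_trace: np.ndarray, fps: int, tr: float) -> ArousalTrace:
    """Per-frame median of valid pupil samples, divided by the per-scan maximum.

    Missing samples (NaN: blinks / closed eyes) are ignored within each bin;
    frame bins with no valid sample are linearly interpolated and flagged.
    eye_open_ratio = fraction of frames with at least half their samples valid.
    """
    spf = fps * tr
    if spf < 1 or abs(spf - round(spf)) > 1e-9:
        raise ValueError("fps × tr must be an integer ≥ 1 (samples per frame)")
    spf = int(round(spf))
    trace = np.asarray(pupil_trace, dtype=float)
    n_frames = trace.size // spf
    bins = trace[: n_frames * spf].reshape(n_frames, spf)
    valid = np.isfinite(bins)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins handled below
        med = np.nanmedian(bins, axis=1)
    flagged = ~np.isfinite(med)
    if flagged.all():
        raise ValueError("no valid pupil samples in any frame")
    if flagged.any():
        good = np.flatnonzero(~flagged)
        med[flagged] = np.interp(np.flatnonzero(flagged), good, med[good])
    mx = med.max()
    if mx <= 0:
        raise ValueError("pupil trace maximum must be positive for normalization")
    eye_open = float(np.mean(valid.sum(axis=1) >= spf / 2.0))
    return ArousalTrace(index=med / mx, kind="behavioral", eye_open_ratio=eye_open, flagged=flagged)


def canonical_hrf(tr: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at TR (peak 6 s, undershoot 16 s, ratio 1/6)."""
    from scipy.stats import gamma

    t = np.arange(0, duration + tr / 2, tr)
    peak = gamma.pdf(t, 6.0)  # shape 6, scale 1 → mode at 5 s ≈ peak 6 s response
    under = gamma.pdf(t, 16.0)
    h = peak - under / 6.0
    return h / h.sum()


def hrf_convolve(trace: np.ndarray, tr: float) -> np.ndarray:
    """Convolve a per-frame trace with the canonical HRF, truncated to input length."""
    x = np.asarray(trace, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("trace must be finite before HRF convolution")
    h = canonical_hrf(tr)
    return np.convolve(x, h)[: x.size]


def _fisher_mean(r: np.ndarray, axis: int = 0) -> np.ndarray:
    z = np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))
    return np.tanh(z.mean(axis=axis))


def arousal_template(
    scans: list[RegionTimeSeries], behavioral_traces: list[ArousalTrace]
) -> ArousalTemplate:
    """Per-region correlation of BOLD with the HRF-convolved behavioral index.

    Computed per scan, then Fisher-z averaged across scans and
    back-transformed.
    """
    if len(scans) == 0 or len(scans) != len(behavioral_traces):
        raise ValueError("need equally many scans and behavioral traces (≥ 1)")
    rows = []
    for ts, tr_beh in zip(scans, behavioral_traces):
        idx = tr_beh.index if isinstance(tr_beh, ArousalTrace) else np.asarray(tr_beh, float)
        n = min(ts.n_frames, idx.size)
        reg = hrf_convolve(idx[:n], ts.tr)
        x = ts.data[:n]
        reg_c = reg - reg.mean()
        x_c = x - x.mean(axis=0)
        denom = np.linalg.norm(x_c, axis=0) * np.linalg.norm(reg_c)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (x_c.T @ reg_c) / denom
        rows.append(np.nan_to_num(r))
    return ArousalTemplate(map=_fisher_mean(np.vstack(rows), axis=0))


def fmri_arousal_index(ts: RegionTimeSeries, template: ArousalTemplate) -> ArousalTrace:
    """Spatial correlation of each successive BOLD frame with the arousal template."""
    tmap = template.map
    if tmap.size != ts.n_regions:
        raise ValueError("template length must equal the number of regions")
    x = ts.data - ts.data.mean(axis=1, keepdims=True)
    t_c = tmap - tmap.mean()
    xn = np.linalg.norm(x, axis=1)
    flagged = xn == 0
    xn[flagged] = 1.0
    idx = (x @ t_c) / (xn * np.linalg.norm(t_c))
    idx[flagged] = 0.0
    return ArousalTrace(index=idx, kind="fmri_template", flagged=flagged)


def bin_by_arousal(trace: ArousalTrace | np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Assign frames to equal-size arousal bins by rank (ascending arousal).

    Remainder frames are dropped symmetrically from the rank extremes
    (assignment −1); ties are broken by frame order. Returns a per-frame
    integer array in {−1, 0, …, n_bins−1}.
    """
    idx = trace.index if isinstance(trace, ArousalTrace) else np.asarray(trace, dtype=float)
    n = idx.size
    if n < n_bins:
        raise ValueError("need at least n_bins frames")
    per_bin = n // n_bins
    rem = n - per_bin * n_bins
    order = np.argsort(idx, kind="stable")
    drop_low = rem // 2
    drop_high = rem - drop_low
    kept = order[drop_low : n - drop_high]
    assignment = np.full(n, -1, dtype=int)
    for b in range(n_bins):
        assignment[kept[b * per_bin : (b + 1) * per_bin]] = b
    return assignment
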