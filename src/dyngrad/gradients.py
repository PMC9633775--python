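"""Connectivity gradients: FC → row thresholding → normalized-angle affinity → diffusion embedding.

The embedding follows the diffusion-map convention used throughout the
functional-gradient literature: anisotropic normalization with α = 0.5,
transition-matrix eigendecomposition, components scaled by λ/(1−λ) at
diffusion time 0, and explained variance λ_k²/Σλ² over the retained
non-trivial spectrum. Gradient sets are compared via orthogonal Procrustes
alignment (no scaling) and fingerprinting correlation.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import orthogonal_procrustes
from scipy.sparse.csgraph import connected_components

from .containers import AffinityMatrix, ConnectivityMatrix, GradientSet, RegionTimeSeries

__all__ = [
    "compute_fc",
    "threshold_rows",
    "normalized_angle",
    "diffusion_embed",
    "gradients_from_connectivity",
    "procrustes_align",
    "fingerprint_similarity",
    "mean_absolute_strength",
]


def compute_fc(ts: RegionTimeSeries) -> ConnectivityMatrix:
    """Pearson correlation between every pair of region time courses."""
    x = ts.data
    if x.shape[0] < 3:
        raise ValueError("need at least 3 frames to correlate")
    sd = x.std(axis=0)
    if np.any(sd == 0):
        bad = [ts.labels[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant time series for region(s) {bad}: correlation undefined")
    c = np.corrcoef(x.T)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return ConnectivityMatrix(values=c, role="FC", labels=list(ts.labels))


def threshold_rows(c: ConnectivityMatrix, density: float = 0.10) -> np.ndarray:
    """Keep, per row, the ⌈density·(N−1)⌉ largest off-diagonal entries; zero the rest.

    Ties are broken toward the lower column index. The diagonal is zeroed.
    The result is generally asymmetric.
    """
    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1]")
    v = np.array(c.values, dtype=float)
    n = v.shape[0]
    np.fill_diagonal(v, -np.inf)
    keep = int(np.ceil(density * (n - 1)))
    out = np.zeros_like(v)
    # stable argsort on -value: among ties the lower column index comes first
    order = np.argsort(-v, axis=1, kind="stable")
    rows = np.repeat(np.arange(n), keep)
    cols = order[:, :keep].ravel()
    out[rows, cols] = v[rows, cols]
    out[out == -np.inf] = 0.0
    return out


def normalized_angle(thresholded: np.ndarray) -> AffinityMatrix:
    """Normalized-angle affinity between row profiles: 1 − arccos(cosine)/π."""
    x = np.asarray(thresholded, dtype=float)
    norms = np.linalg.norm(x, axis=1)
    if np.any(norms == 0):
        bad = np.flatnonzero(norms == 0).tolist()
        raise ValueError(f"all-zero connectivity profile for row(s) {bad}: isolated node")
    cos = (x @ x.T) / np.outer(norms, norms)
    cos = np.clip((cos + cos.T) / 2.0, -1.0, 1.0)
    a = 1.0 - np.arccos(cos) / np.pi
    np.fill_diagonal(a, 1.0)
    density = float(np.mean(x != 0))
    return AffinityMatrix(values=a, density=density)


def diffusion_embed(
    a: AffinityMatrix | np.ndarray,
    n_components: int = 10,
    alpha: float = 0.5,
    diffusion_time: float = 0.0,
) -> GradientSet:
    """Diffusion-map embedding of a symmetric nonnegative affinity matrix.

    W = D^−α A D^−α, P = D_w^−1 W; the non-trivial eigenvectors of P, scaled
    by λ/(1−λ) (diffusion_time = 0) or λ^t, are the gradients; explained
    variance is λ_k²/Σλ² over the retained spectrum, nonincreasing by
    eigenvalue ordering.
    """
    av = a.values if isinstance(a, AffinityMatrix) else np.asarray(a, dtype=float)
    n = av.shape[0]
    if av.shape[0] != av.shape[1] or not np.allclose(av, av.T, atol=1e-10):
        raise ValueError("affinity must be square and symmetric")
    if np.any(av < -1e-12):
        raise ValueError("affinity must be nonnegative")
    n_comp_graph, labels = connected_components(av > 0, directed=False)
    if n_comp_graph > 1:
        sizes = np.bincount(labels).tolist()
        raise ValueError(f"affinity graph is disconnected ({n_comp_graph} components, sizes {sizes})")
    if n_components > n - 1:
        raise ValueError("n_components must be ≤ N − 1")

    d = av.sum(axis=1)
    w = av / np.outer(d**alpha, d**alpha)
    dw = w.sum(axis=1)
    # symmetric conjugate of the transition matrix: same spectrum, orthogonal eigvecs
    inv_sqrt = 1.0 / np.sqrt(dw)
    m = w * np.outer(inv_sqrt, inv_sqrt)
    m = (m + m.T) / 2.0
    evals, evecs = np.linalg.eigh(m)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # right eigenvectors of P; the first (λ ≈ 1, constant) is trivial and dropped
    psi = evecs * inv_sqrt[:, None]
    lam = evals[1 : n_components + 1]
    comp = psi[:, 1 : n_components + 1]
    if diffusion_time == 0:
        scale = lam / (1.0 - np.clip(lam, None, 1.0 - 1e-12))
    else:
        scale = np.sign(lam) * np.abs(lam) ** diffusion_time
    comp = comp * scale
    # negative tail eigenvalues carry no diffusion structure: clip for the
    # variance shares so the EV vector is probability-like and nonincreasing
    lam_pos = np.clip(lam, 0.0, None)
    total = np.sum(lam_pos**2)
    ev = lam_pos**2 / total if total > 0 else np.zeros_like(lam)
    return GradientSet(components=comp, eigenvalues=lam, explained_variance=ev)


def gradients_from_connectivity(
    c: ConnectivityMatrix,
    n_components: int = 10,
    density: float = 0.10,
    alpha: float = 0.5,
    diffusion_time: float = 0.0,
) -> GradientSet:
    """Full gradient chain on one connectivity matrix.

    Row-threshold at the given density, symmetrize the normalized-angle
    affinity (the thresholded matrix is asymmetric; the embedding needs a
    symmetric kernel), and diffusion-embed.
    """
    thr = threshold_rows(c, density=density)
    aff = normalized_angle(thr)
    return diffusion_embed(aff, n_components=n_components, alpha=alpha, diffusion_time=diffusion_time)


def procrustes_align(g: GradientSet, ref: GradientSet) -> GradientSet:
    """Rotate/reflect g's components (no scaling) to best match the reference."""
    x, y = g.components, ref.components
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    q, _ = orthogonal_procrustes(x, y)
    return GradientSet(
        components=x @ q,
        eigenvalues=g.eigenvalues.copy(),
        explained_variance=g.explained_variance.copy(),
        reference_aligned=True,
    )


def fingerprint_similarity(ga: GradientSet, gb: GradientSet, k: int) -> tuple[np.ndarray, float]:
    """k×k matrix of |Pearson| between components, and an order-match score.

    Score = mean diagonal − mean off-diagonal; high when the two sets carry
    the same gradients in the same order (sign-flip invariant).
    """
    a, b = ga.components[:, :k], gb.components[:, :k]
    cc = np.empty((k, k))
    for i in range(k):
        for j in range(k):
            cc[i, j] = abs(np.corrcoef(a[:, i], b[:, j])[0, 1])
    diag = np.mean(np.diag(cc))
    off = (cc.sum() - np.trace(cc)) / (k * k - k) if k > 1 else 0.0
    return cc, float(diag - off)


def mean_absolute_strength(g: GradientSet, k: int) -> float:
    """Mean over regions of |gradient k| (1-based component index)."""
    if not 1 <= k <= g.n_components:
        raise ValueError(f"component {k} out of range 1..{g.n_components}")
    return float(np.mean(np.abs(g.components[:, k - 1])))
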