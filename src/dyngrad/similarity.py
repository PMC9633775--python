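"""Predictor similarity matrices: structural (tracing) and neuromodulatory (expression).

Structural similarity correlates log-transformed directed tracing profiles
between source regions; neuromodulatory similarity correlates receptor
expression profiles between regions. Receptor PCA summarizes the expression
matrix as principal spatial components.
"""

from __future__ import annotations

import warnings

import numpy as np

from .containers import DirectedTracingMatrix, ExpressionMatrix, SimilarityMatrix

__all__ = ["tracing_similarity", "expression_similarity", "receptor_pca"]


def tracing_similarity(m: DirectedTracingMatrix, epsilon: float = 1.0) -> SimilarityMatrix:
    """Log-transform tracing weights and Pearson-correlate source target-profiles.

    similarity(i, j) = Pearson(log(w_i· + ε), log(w_j· + ε)) over targets;
    ε (default 1) handles zero weights. Source regions with an all-ε profile
    are flagged low-confidence but still returned.
    """
    w = np.asarray(m.weights, dtype=float)
    if w.shape[0] < 3 or w.shape[1] < 3:
        raise ValueError("need at least 3 sources and 3 targets")
    logw = np.log(w + epsilon)
    flat = np.flatnonzero(logw.std(axis=1) == 0)
    if flat.size:
        warnings.warn(
            f"source region(s) {[m.source_labels[i] for i in flat]} have constant "
            "log-profiles; their similarities are low-confidence"
        )
        logw = logw.copy()
        logw[flat] += 1e-12 * np.random.default_rng(0).standard_normal(logw.shape[1])
    c = np.corrcoef(logw)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return SimilarityMatrix(values=c, role="SC", labels=list(m.source_labels))


def expression_similarity(
    e: ExpressionMatrix,
    receptor_subset: list[str] | None = None,
    replace: dict[str, np.ndarray] | None = None,
) -> SimilarityMatrix:
    """Region-pair Pearson correlation of receptor expression profiles.

    similarity(i, j) = Pearson over the subset's expression values at
    regions i and j (receptors as variables). `replace` substitutes one or
    more receptors' maps by surrogates before correlating — the mechanism
    behind the reduced-model receptor shuffles. Constant receptor rows are
    excluded with a warning.
    """
    labels = list(e.receptor_labels)
    if receptor_subset is None:
        receptor_subset = labels
    missing = [r for r in receptor_subset if r not in labels]
    if missing:
        raise KeyError(f"receptors not in expression matrix: {missing}")
    if len(receptor_subset) < 3:
        raise ValueError("need at least 3 receptors")
    rows = np.array([e.values[labels.index(r)] for r in receptor_subset], dtype=float)
    if replace:
        for name, new_map in replace.items():
            if name not in receptor_subset:
                raise KeyError(f"cannot replace {name!r}: not in the receptor subset")
            rows[receptor_subset.index(name)] = np.asarray(new_map, dtype=float)
    const = rows.std(axis=1) == 0
    if const.any():
        warnings.warn(
            f"excluding constant receptor(s) {[receptor_subset[i] for i in np.flatnonzero(const)]}"
        )
        rows = rows[~const]
        if rows.shape[0] < 3:
            raise ValueError("fewer than 3 non-constant receptors remain")
    c = np.corrcoef(rows.T)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return SimilarityMatrix(values=c, role="NS", labels=None)


def receptor_pca(e: ExpressionMatrix, n_pc: int = 3) -> dict[str, np.ndarray]:
    """PCA of z-scored receptor maps (regions as observations, receptors as variables).

    Each receptor map is z-scored across regions; the principal components
    of the region × receptor matrix give region-length PC maps (the scores)
    and signed per-receptor coefficients (the loadings). A constant offset
    or rescaling of any receptor leaves the result unchanged.
    """
    from sklearn.decomposition import PCA

    x = np.asarray(e.values, dtype=float)
    if x.shape[0] < n_pc:
        raise ValueError("need at least n_pc receptors")
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = ((x - x.mean(axis=1, keepdims=True)) / sd).T  # (N regions, G receptors)
    pca = PCA(n_components=n_pc, svd_solver="full")
    scores = pca.fit_transform(z)  # (N, n_pc): region-length PC maps
    return {
        "maps": scores.T,  # (n_pc, N)
        "coefficients": pca.components_.T,  # (G, n_pc) signed loadings
        "explained_variance_ratio": pca.explained_variance_ratio_,
    }
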