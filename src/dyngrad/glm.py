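"""Variance partitioning of FC into structural and neuromodulatory contributions.

The model is FC = b0 + b1·SC + b2·NS over region pairs (upper-triangle
vectors), solved by least squares with a small ridge penalty on the slopes
(intercept unpenalized; at the default penalty the solution coincides with
OLS on well-conditioned data). Three model families quantify contributions:

* full model — cross-validated R² (leave-one-scan-out),
* single-variable models — an upper bound per predictor,
* reduced models — the drop in cvR² when one predictor is shuffled
  (region identities permuted jointly, so the shuffled predictor remains a
  valid similarity matrix), a lower bound on its unique contribution.

Frame-wise fits extend the same model to dynamic FC, and
receptor_contribution measures each receptor's unique contribution to the
arousal-binned GLM by surrogate replacement of its expression map.
"""

from __future__ import annotations

import numpy as np

from .containers import ConnectivityMatrix, ExpressionMatrix, GLMFit, SimilarityMatrix, VariancePartition
from .similarity import expression_similarity

__all__ = [
    "vectorize_pairs",
    "unvectorize_pairs",
    "fit_glm",
    "loo_cv",
    "single_variable",
    "reduced_delta",
    "variance_partition",
    "framewise_glm",
    "binned_delta_r2",
    "receptor_contribution",
]


def vectorize_pairs(s: SimilarityMatrix | np.ndarray) -> np.ndarray:
    """Upper-triangle (i<j, row-major) pair vector of a symmetric matrix."""
    v = s.values if isinstance(s, SimilarityMatrix) else np.asarray(s, dtype=float)
    if v.ndim != 2 or v.shape[0] != v.shape[1]:
        raise ValueError("input must be square")
    if not np.allclose(v, v.T, atol=1e-10):
        raise ValueError("input must be symmetric")
    iu = np.triu_indices(v.shape[0], k=1)
    return v[iu].copy()


def unvectorize_pairs(vec: np.ndarray, n: int, diagonal: float = 1.0) -> np.ndarray:
    """Inverse of vectorize_pairs: restore the symmetric N×N matrix."""
    vec = np.asarray(vec, dtype=float)
    if vec.size != n * (n - 1) // 2:
        raise ValueError(f"pair vector of length {vec.size} does not match n={n}")
    out = np.full((n, n), diagonal, dtype=float)
    iu = np.triu_indices(n, k=1)
    out[iu] = vec
    out[(iu[1], iu[0])] = vec
    return out


def _design(predictors: dict[str, np.ndarray]) -> tuple[list[str], np.ndarray]:
    names = list(predictors)
    x = np.column_stack([np.asarray(predictors[k], dtype=float) for k in names])
    return names, x


def fit_glm(
    fc_vec: np.ndarray, predictors: dict[str, np.ndarray], ridge: float = 1e-6
) -> GLMFit:
    """Solve FC = b0 + Σ b_k·X_k with a trace-scaled ridge penalty on the slopes.

    The penalty is ridge · trace(XcᵀXc)/k on ‖b‖² (intercept unpenalized);
    exact collinearity with ridge = 0 raises with advice to set ridge > 0.
    """
    y = np.asarray(fc_vec, dtype=float)
    names, x = _design(predictors)
    if y.size < 3 or x.shape[0] != y.size:
        raise ValueError("need ≥ 3 pairs and matching predictor lengths")
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    gram = xc.T @ xc
    lam = ridge * np.trace(gram) / max(len(names), 1)
    a = gram + lam * np.eye(len(names))
    if ridge == 0 and np.linalg.matrix_rank(gram) < len(names):
        raise np.linalg.LinAlgError(
            "predictors are exactly collinear; set ridge > 0 to regularize"
        )
    b = np.linalg.solve(a, xc.T @ yc)
    b0 = y.mean() - x.mean(axis=0) @ b
    pred = b0 + x @ b
    sst = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum((y - pred) ** 2) / sst if sst > 0 else 0.0
    return GLMFit(coefficients=np.concatenate([[b0], b]), predicted=pred, r_squared=float(r2), ridge=lam)


def _cv_r2(fc_vecs: np.ndarray, predictors: dict[str, np.ndarray], ridge: float) -> np.ndarray:
    """Leave-one-scan-out: fit on the mean FC of the others, score 1 − SSE/SST held out."""
    fc_vecs = np.atleast_2d(np.asarray(fc_vecs, dtype=float))
    s = fc_vecs.shape[0]
    if s < 2:
        raise ValueError("leave-one-out needs at least 2 scans")
    out = np.empty(s)
    total = fc_vecs.sum(axis=0)
    for i in range(s):
        train_mean = (total - fc_vecs[i]) / (s - 1)
        fit = fit_glm(train_mean, predictors, ridge=ridge)
        y = fc_vecs[i]
        sse = np.sum((y - fit.predicted) ** 2)
        sst = np.sum((y - y.mean()) ** 2)
        out[i] = 1.0 - sse / sst if sst > 0 else 0.0
    return out


def loo_cv(
    fc_vecs: np.ndarray, predictors: dict[str, np.ndarray], ridge: float = 1e-6
) -> dict[str, float | np.ndarray]:
    """Leave-one-scan-out cvR² (1 − SSE/SST per held-out scan; squared Pearson also reported)."""
    per_scan = _cv_r2(fc_vecs, predictors, ridge)
    fc_vecs = np.atleast_2d(np.asarray(fc_vecs, dtype=float))
    s = fc_vecs.shape[0]
    pear = np.empty(s)
    total = fc_vecs.sum(axis=0)
    for i in range(s):
        fit = fit_glm((total - fc_vecs[i]) / (s - 1), predictors, ridge=ridge)
        pear[i] = np.corrcoef(fit.predicted, fc_vecs[i])[0, 1] ** 2
    return {
        "per_scan": per_scan,
        "mean": float(per_scan.mean()),
        "sem": float(per_scan.std(ddof=1) / np.sqrt(s)) if s > 1 else 0.0,
        "pearson2_mean": float(pear.mean()),
    }


def single_variable(
    fc_vecs: np.ndarray, predictor: np.ndarray, name: str = "X", ridge: float = 1e-6
) -> dict[str, float | np.ndarray]:
    """Single-variable cvR² — the upper bound for one predictor's contribution."""
    return loo_cv(fc_vecs, {name: predictor}, ridge=ridge)


def _shuffle_predictor(vec: np.ndarray, n_regions: int, rng: np.random.Generator) -> np.ndarray:
    """Permute region identities of a pair-vector predictor (keeps it a valid similarity)."""
    mat = unvectorize_pairs(vec, n_regions)
    perm = rng.permutation(n_regions)
    return vectorize_pairs(mat[np.ix_(perm, perm)])


def reduced_delta(
    fc_vecs: np.ndarray,
    predictors: dict[str, np.ndarray],
    target_var: str,
    n_shuffles: int = 1000,
    seed: int = 0,
    ridge: float = 1e-6,
    shuffle: str = "regions",
) -> dict[str, float | np.ndarray]:
    """ΔR²: cvR²_full minus the mean cvR² with the target predictor shuffled.

    shuffle="regions" permutes region identities jointly (default);
    "pairs" permutes pair entries independently.
    """
    if target_var not in predictors:
        raise KeyError(f"{target_var!r} not among predictors {list(predictors)}")
    if n_shuffles < 2:
        raise ValueError("need at least 2 shuffles")
    full = _cv_r2(fc_vecs, predictors, ridge).mean()
    vec = np.asarray(predictors[target_var], dtype=float)
    n_regions = int(round((1 + np.sqrt(1 + 8 * vec.size)) / 2))
    rng = np.random.default_rng(seed)
    dist = np.empty(n_shuffles)
    for s in range(n_shuffles):
        if shuffle == "regions":
            shuffled = _shuffle_predictor(vec, n_regions, rng)
        elif shuffle == "pairs":
            shuffled = rng.permutation(vec)
        else:
            raise ValueError(f"unknown shuffle mode {shuffle!r}")
        p2 = dict(predictors)
        p2[target_var] = shuffled
        dist[s] = _cv_r2(fc_vecs, p2, ridge).mean()
    return {
        "delta_r2": float(full - dist.mean()),
        "full": float(full),
        "shuffled": dist,
        "seed": seed,
    }


def variance_partition(
    fc_vecs: np.ndarray,
    predictors: dict[str, np.ndarray],
    n_shuffles: int = 1000,
    seed: int = 0,
    ridge: float = 1e-6,
) -> VariancePartition:
    """Full / single-variable / reduced-model partition in one call."""
    full = loo_cv(fc_vecs, predictors, ridge=ridge)
    singles, deltas, dists = {}, {}, {}
    for i, name in enumerate(predictors):
        singles[name] = single_variable(fc_vecs, predictors[name], name, ridge=ridge)["mean"]
        red = reduced_delta(
            fc_vecs, predictors, name, n_shuffles=n_shuffles, seed=seed + i, ridge=ridge
        )
        deltas[name] = red["delta_r2"]
        dists[name] = red["shuffled"]
    return VariancePartition(
        cv_r2_full=full["mean"],
        cv_r2_full_per_scan=full["per_scan"],
        cv_r2_single=singles,
        delta_r2=deltas,
        delta_r2_distributions=dists,
        n_shuffles=n_shuffles,
        seed=seed,
    )


def framewise_glm(
    frames: np.ndarray, predictors: dict[str, np.ndarray], ridge: float = 1e-6
) -> dict[str, np.ndarray]:
    """Independent FC = b0 + b1·SC + b2·NS fit per dynamic-FC frame.

    frames: (T, N, N) correlation matrices or (T, P) pair vectors. Returns
    per-frame coefficients, R², predicted pair-vectors and a degenerate-frame
    flag (zero-variance frames get zero coefficients).
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 3:
        iu = np.triu_indices(frames.shape[1], k=1)
        fvec = frames[:, iu[0], iu[1]]
    else:
        fvec = frames
    t_len = fvec.shape[0]
    names, x = _design(predictors)
    coeffs = np.zeros((t_len, len(names) + 1))
    r2 = np.zeros(t_len)
    pred = np.zeros_like(fvec)
    flagged = np.zeros(t_len, dtype=bool)
    for t in range(t_len):
        y = fvec[t]
        if y.std() == 0:
            flagged[t] = True
            pred[t] = y
            continue
        fit = fit_glm(y, predictors, ridge=ridge)
        coeffs[t] = fit.coefficients
        r2[t] = fit.r_squared
        pred[t] = fit.predicted
    return {"coefficients": coeffs, "names": ["b0"] + names, "r_squared": r2,
            "predicted": pred, "flagged": flagged}


def binned_delta_r2(
    bin_matrices: list[ConnectivityMatrix],
    predictors: dict[str, np.ndarray],
    n_shuffles: int = 1000,
    seed: int = 0,
    ridge: float = 1e-6,
) -> dict[str, np.ndarray]:
    """Per-arousal-bin full R² and per-predictor ΔR² on bin-mean dynamic FC.

    For each bin the full model is fit in-sample; ΔR² per predictor is the
    mean R² drop over region-identity shuffles of that predictor. This is
    the per-bin reduced-model summary whose arousal trend distinguishes
    static (structural) from arousal-modulated (neuromodulatory) predictors.
    """
    rng = np.random.default_rng(seed)
    names = list(predictors)
    n_bins = len(bin_matrices)
    fvecs = [vectorize_pairs(c) for c in bin_matrices]
    n_regions = bin_matrices[0].values.shape[0]
    r2_full = np.array([fit_glm(v, predictors, ridge=ridge).r_squared for v in fvecs])
    delta = {k: np.empty(n_bins) for k in names}
    for name in names:
        vec = np.asarray(predictors[name], dtype=float)
        shuffled_vecs = [
            _shuffle_predictor(vec, n_regions, rng) for _ in range(n_shuffles)
        ]
        drops = np.empty((n_shuffles, n_bins))
        for s, sv in enumerate(shuffled_vecs):
            p2 = dict(predictors)
            p2[name] = sv
            for b, v in enumerate(fvecs):
                drops[s, b] = fit_glm(v, p2, ridge=ridge).r_squared
        delta[name] = r2_full - drops.mean(axis=0)
    return {"r2_full": r2_full, "delta_r2": delta, "n_shuffles": n_shuffles, "seed": seed}


def receptor_contribution(
    dfc_binned: list[ConnectivityMatrix],
    expression: ExpressionMatrix,
    receptor: str,
    sc: np.ndarray | SimilarityMatrix,
    n_shuffles: int = 1000,
    distance_matrix: np.ndarray | None = None,
    seed: int = 0,
    ridge: float = 1e-6,
    surrogate_maps: np.ndarray | None = None,
    extra_predictors: dict[str, np.ndarray] | None = None,
) -> dict[str, np.ndarray]:
    """Unique contribution of one receptor to the arousal-binned GLM.

    extra_predictors adds nuisance pair-vector regressors to every fit
    (e.g. the outer product of the estimated arousal template, whose rank-1
    covariance otherwise contaminates bin-mean FC).

    The receptor's expression map is replaced by surrogates (SA-preserving
    variogram-matched maps when a distance matrix is given, otherwise random
    permutations), the neuromodulatory similarity rebuilt, and the per-bin
    GLM refit. Returns per-bin ΔR² (full − mean surrogate R²), the full
    per-surrogate × bin R² table, the surrogate maps and each surrogate's
    Pearson similarity to the empirical map (inputs to
    surrogates.receptor_significance).
    """
    if receptor not in expression.receptor_labels:
        raise KeyError(f"receptor {receptor!r} not in expression matrix")
    if n_shuffles < 1:
        raise ValueError("need at least 1 shuffle")
    sc_vec = vectorize_pairs(sc) if isinstance(sc, SimilarityMatrix) else np.asarray(sc, float)
    emp_map = expression.values[expression.receptor_labels.index(receptor)]
    rng = np.random.default_rng(seed)
    if surrogate_maps is None:
        if distance_matrix is not None:
            from .surrogates import make_surrogates

            ens = make_surrogates(emp_map, distance_matrix, n_surrogates=n_shuffles, seed=seed)
            surrogate_maps = ens.maps
        else:
            surrogate_maps = np.array([rng.permutation(emp_map) for _ in range(n_shuffles)])
    surrogate_maps = np.asarray(surrogate_maps, dtype=float)
    m = surrogate_maps.shape[0]

    fvecs = [vectorize_pairs(c) for c in dfc_binned]
    extra = dict(extra_predictors or {})
    ns_full = vectorize_pairs(expression_similarity(expression))
    preds_full = {"SC": sc_vec, "NS": ns_full, **extra}
    r2_full = np.array([fit_glm(v, preds_full, ridge=ridge).r_squared for v in fvecs])

    r2_surr = np.empty((m, len(fvecs)))
    sim = np.empty(m)
    emp_c = emp_map - emp_map.mean()
    for s in range(m):
        smap = surrogate_maps[s]
        ns_s = vectorize_pairs(expression_similarity(expression, replace={receptor: smap}))
        preds = {"SC": sc_vec, "NS": ns_s, **extra}
        for b, v in enumerate(fvecs):
            r2_surr[s, b] = fit_glm(v, preds, ridge=ridge).r_squared
        sc_c = smap - smap.mean()
        denom = np.linalg.norm(emp_c) * np.linalg.norm(sc_c)
        sim[s] = float(emp_c @ sc_c / denom) if denom > 0 else 0.0
    delta_per_bin = r2_full - r2_surr.mean(axis=0)
    return {
        "r2_full_per_bin": r2_full,
        "r2_surrogate": r2_surr,
        "delta_per_bin": delta_per_bin,
        "delta_overall": float(delta_per_bin.mean()),
        "surrogate_maps": surrogate_maps,
        "similarity_to_empirical": sim,
        "seed": seed,
    }
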