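"""Frame-resolved dynamic connectivity and arousal-binned gradient dynamics.

Dynamic connectivity uses the two-stage dynamic conditional correlation
(DCC) estimator: per-region GARCH(1,1) volatilities by quasi-maximum
likelihood, then scalar DCC(1,1) parameters (a, b) by QMLE on the
standardized residuals with correlation targeting (the unconditional
correlation as the recursion intercept). The per-frame conditional
correlation matrices are binned by arousal, averaged, re-embedded into
dynamic gradients, and summarized as gradient-space flow, FC entropy and
quadratic (U / inverted-U) trends.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import minimize

from ._utils import nearest_correlation
from .containers import (
    ConnectivityMatrix,
    DCCParams,
    DynamicConnectivity,
    GradientSet,
    RegionTimeSeries,
    TrendFit,
)
from .gradients import gradients_from_connectivity, procrustes_align

__all__ = [
    "dcc_fit",
    "simulate_garch_dcc",
    "binned_mean_dfc",
    "dynamic_gradients",
    "gradient_flow",
    "flow_null",
    "fc_entropy",
    "quadratic_trend",
]

try:  # pragma: no cover - jit is an optimization, the fallback is identical
    from numba import njit as _njit

    def _jit(f):
        return _njit(cache=False)(f)

except Exception:  # pragma: no cover

    def _jit(f):
        return f


@_jit
def _garch_nll(params: np.ndarray, r: np.ndarray) -> float:
    omega, alpha, beta = params[0], params[1], params[2]
    t_len = r.shape[0]
    h = r.var() if r.var() > 1e-12 else 1e-12
    nll = 0.0
    for t in range(t_len):
        if t > 0:
            h = omega + alpha * r[t - 1] * r[t - 1] + beta * h
        if h < 1e-12:
            h = 1e-12
        nll += 0.5 * (np.log(h) + r[t] * r[t] / h)
    return nll


@_jit
def _garch_sigma2(params: np.ndarray, r: np.ndarray) -> np.ndarray:
    omega, alpha, beta = params[0], params[1], params[2]
    t_len = r.shape[0]
    h = np.empty(t_len)
    h[0] = r.var() if r.var() > 1e-12 else 1e-12
    for t in range(1, t_len):
        h[t] = omega + alpha * r[t - 1] * r[t - 1] + beta * h[t - 1]
        if h[t] < 1e-12:
            h[t] = 1e-12
    return h


@_jit
def _dcc_nll(ab: np.ndarray, z: np.ndarray, s: np.ndarray) -> float:
    a, b = ab[0], ab[1]
    t_len, n = z.shape
    q = s.copy()
    nll = 0.0
    for t in range(t_len):
        d = np.sqrt(np.diag(q))
        r = q / np.outer(d, d)
        chol = np.linalg.cholesky(r)
        logdet = 0.0
        for i in range(n):
            logdet += 2.0 * np.log(chol[i, i])
        zt = z[t]
        y = np.linalg.solve(r, np.ascontiguousarray(zt))
        quad = 0.0
        for i in range(n):
            quad += zt[i] * y[i] - zt[i] * zt[i]
        nll += 0.5 * (logdet + quad)
        q = (1.0 - a - b) * s + a * np.outer(zt, zt) + b * q
    return nll


@_jit
def _dcc_corr_path(ab: np.ndarray, z: np.ndarray, s: np.ndarray) -> np.ndarray:
    a, b = ab[0], ab[1]
    t_len, n = z.shape
    q = s.copy()
    out = np.empty((t_len, n, n))
    for t in range(t_len):
        d = np.sqrt(np.diag(q))
        out[t] = q / np.outer(d, d)
        zt = z[t]
        q = (1.0 - a - b) * s + a * np.outer(zt, zt) + b * q
    return out


def _fit_one_garch(r: np.ndarray) -> np.ndarray:
    var = float(r.var())
    best = None

    def obj(p):
        if p[1] + p[2] >= 0.999:
            return 1e10 + 1e10 * (p[1] + p[2])
        return _garch_nll(np.asarray(p, dtype=float), r)

    for a0, b0 in ((0.05, 0.90), (0.10, 0.80), (0.01, 0.50)):
        x0 = np.array([var * (1 - a0 - b0), a0, b0])
        res = minimize(
            obj,
            x0,
            method="L-BFGS-B",
            bounds=[(1e-10 * max(var, 1e-6), 10 * max(var, 1e-6)), (0.0, 0.995), (0.0, 0.998)],
            options={"ftol": 1e-12, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    p = best.x.copy()
    if p[1] + p[2] >= 0.999:
        scale = (1 - 1e-4) / (p[1] + p[2])
        p[1:] *= scale
        warnings.warn("GARCH persistence at boundary; alpha+beta clamped to 1-1e-4")
    p[0] = max(p[0], 1e-12)
    return p


def dcc_fit(ts: RegionTimeSeries, demean: bool = True) -> tuple[DCCParams, DynamicConnectivity]:
    """Two-stage DCC(1,1) fit; returns parameters and per-frame conditional correlations."""
    x = np.array(ts.data, dtype=float)
    if x.shape[0] < 100:
        raise ValueError("DCC needs at least 100 frames")
    if demean:
        x = x - x.mean(axis=0)
    t_len, n = x.shape
    garch = np.empty((n, 3))
    z = np.empty_like(x)
    for i in range(n):
        garch[i] = _fit_one_garch(x[:, i])
        z[:, i] = x[:, i] / np.sqrt(_garch_sigma2(garch[i], x[:, i]))
    s = np.corrcoef(z.T)
    s = nearest_correlation((s + s.T) / 2.0)

    def obj(ab):
        if ab[0] + ab[1] >= 0.999:
            return 1e10 + 1e10 * (ab[0] + ab[1])
        return _dcc_nll(np.asarray(ab, dtype=float), z, s)

    best = None
    for start in ((0.05, 0.90), (0.02, 0.95), (0.10, 0.80)):
        res = minimize(
            obj,
            np.asarray(start),
            method="L-BFGS-B",
            bounds=[(0.0, 0.5), (0.0, 0.998)],
            options={"ftol": 1e-12, "maxiter": 300},
        )
        if best is None or res.fun < best.fun:
            best = res
    a, b = best.x
    converged = bool(best.success)
    if a + b >= 0.999:
        scale = (1 - 1e-4) / (a + b)
        a, b = a * scale, b * scale
        warnings.warn("DCC persistence at boundary; a+b clamped to 1-1e-4")
    if not converged:
        warnings.warn(f"DCC optimizer did not report convergence: {best.message}")
    frames = _dcc_corr_path(np.array([a, b]), z, s)
    params = DCCParams(garch=garch, a=float(a), b=float(b), loglik=-float(best.fun), converged=converged)
    return params, DynamicConnectivity(frames=frames, tr=ts.tr)


def simulate_garch_dcc(
    t_len: int,
    garch: np.ndarray,
    a: float,
    b: float,
    s: np.ndarray,
    seed: int = 0,
) -> np.ndarray:
    """Simulate from a known GARCH(1,1)/DCC(1,1) generator (oracle for recovery tests)."""
    rng = np.random.default_rng(seed)
    garch = np.asarray(garch, dtype=float)
    n = garch.shape[0]
    s = np.asarray(s, dtype=float)
    q = s.copy()
    h = garch[:, 0] / (1.0 - garch[:, 1] - garch[:, 2])  # unconditional variance
    r_prev = np.zeros(n)
    z_prev = np.zeros(n)
    out = np.empty((t_len, n))
    for t in range(t_len):
        if t > 0:
            h = garch[:, 0] + garch[:, 1] * r_prev**2 + garch[:, 2] * h
            q = (1.0 - a - b) * s + a * np.outer(z_prev, z_prev) + b * q
        d = np.sqrt(np.diag(q))
        corr = q / np.outer(d, d)
        z = np.linalg.cholesky(corr) @ rng.standard_normal(n)
        r_prev = np.sqrt(h) * z
        z_prev = z
        out[t] = r_prev
    return out


def binned_mean_dfc(
    dfc: DynamicConnectivity | np.ndarray, assignment: np.ndarray, n_bins: int | None = None
) -> list[ConnectivityMatrix]:
    """Element-wise mean of frame correlation matrices per arousal bin.

    Bin means are re-projected to the nearest correlation matrix when the
    average (or thresholding downstream) leaves them slightly indefinite.
    """
    frames = dfc.frames if isinstance(dfc, DynamicConnectivity) else np.asarray(dfc)
    assignment = np.asarray(assignment)
    if assignment.size != frames.shape[0]:
        raise ValueError("assignment must cover all frames")
    labels = sorted(int(b) for b in np.unique(assignment) if b >= 0)
    if n_bins is not None:
        labels = list(range(n_bins))
    out = []
    for b in labels:
        members = assignment == b
        if not members.any():
            raise ValueError(f"bin {b} is empty")
        m = frames[members].mean(axis=0)
        out.append(ConnectivityMatrix(values=nearest_correlation(m), role="FC"))
    return out


def dynamic_gradients(
    bin_matrices: list[ConnectivityMatrix],
    reference: GradientSet,
    density: float = 0.10,
    alpha: float = 0.5,
) -> list[GradientSet]:
    """Per-bin gradients (threshold → affinity → embed), Procrustes-aligned to the reference."""
    out = []
    for c in bin_matrices:
        g = gradients_from_connectivity(
            c, n_components=reference.n_components, density=density, alpha=alpha
        )
        out.append(procrustes_align(g, reference))
    return out


def gradient_flow(
    bin_gradients: list[GradientSet], network_labels: np.ndarray | list
) -> dict[str, dict[str, np.ndarray | float]]:
    """Per-network trajectory of (G1, G2) centroids across ordered bins, with linear drift.

    The displacement is the least-squares linear drift of the centroid per
    bin step; its Euclidean norm is the flow magnitude.
    """
    labels = np.asarray(network_labels)
    n_bins = len(bin_gradients)
    if n_bins < 2:
        raise ValueError("need at least 2 bins for a flow")
    nets = {}
    xs = np.arange(n_bins, dtype=float)
    for net in np.unique(labels):
        members = labels == net
        traj = np.array(
            [g.components[members, :2].mean(axis=0) for g in bin_gradients]
        )  # (B, 2)
        drift = np.polyfit(xs, traj, 1)[0]  # slope per bin step, per coordinate
        nets[str(net)] = {
            "trajectory": traj,
            "drift": drift,
            "magnitude": float(np.linalg.norm(drift)),
        }
    return nets


def flow_null(
    dfc_by_scan: list[DynamicConnectivity | np.ndarray],
    arousal_by_scan: list[np.ndarray],
    reference: GradientSet,
    network_labels: np.ndarray | list,
    n_bins: int = 10,
    n_perm: int = 1000,
    seed: int = 0,
    density: float = 0.10,
) -> dict[str, object]:
    """Scan-level arousal-shuffle null for gradient flow.

    Arousal traces are permuted across scans, bins and flows recomputed per
    permutation; p = (1 + #{null ≥ observed}) / (1 + n_perm), right-tailed,
    per network.
    """
    if len(dfc_by_scan) < 2:
        raise ValueError("need ≥ 2 scans for a scan-level shuffle")
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse null distribution")
    from .arousal import bin_by_arousal

    frames = np.concatenate(
        [d.frames if isinstance(d, DynamicConnectivity) else np.asarray(d) for d in dfc_by_scan]
    )
    lengths = [np.asarray(a).size for a in arousal_by_scan]
    if len({*lengths}) != 1:
        raise ValueError("scan-level shuffle requires equal-length arousal traces")

    def flow_mags(arousals: list[np.ndarray]) -> dict[str, float]:
        idx = np.concatenate(arousals)
        assign = bin_by_arousal(idx, n_bins=n_bins)
        bins = binned_mean_dfc(frames, assign)
        grads = dynamic_gradients(bins, reference, density=density)
        return {k: v["magnitude"] for k, v in gradient_flow(grads, network_labels).items()}

    observed = flow_mags(list(arousal_by_scan))
    rng = np.random.default_rng(seed)
    null = {k: np.empty(n_perm) for k in observed}
    n_scans = len(arousal_by_scan)
    for p in range(n_perm):
        perm = rng.permutation(n_scans)
        mags = flow_mags([arousal_by_scan[i] for i in perm])
        for k in observed:
            null[k][p] = mags[k]
    pvals = {
        k: float((1 + np.sum(null[k] >= observed[k])) / (1 + n_perm)) for k in observed
    }
    return {"observed": observed, "null": null, "p": pvals, "n_perm": n_perm, "seed": seed}


def fc_entropy(c: ConnectivityMatrix | np.ndarray, n_hist_bins: int = 64) -> float:
    """Shannon entropy (bits) of the upper-triangle FC histogram over fixed bins in [−1, 1]."""
    v = c.values if isinstance(c, ConnectivityMatrix) else np.asarray(c)
    if v.shape[0] < 2:
        raise ValueError("need at least 2 regions")
    iu = np.triu_indices(v.shape[0], k=1)
    counts, _ = np.histogram(v[iu], bins=n_hist_bins, range=(-1.0, 1.0))
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def quadratic_trend(x: np.ndarray, y: np.ndarray) -> TrendFit:
    """OLS fit y = c2 x² + c1 x + c0 with 95% CIs; shape per the CI rule.

    inverted-U ⇔ c2 < 0 with CI excluding 0; U ⇔ c2 > 0 with CI excluding 0;
    otherwise monotone if the linear CI excludes 0, else flat.
    """
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 points for a quadratic trend")
    design = sm.add_constant(np.column_stack([x, x**2]))
    fit = sm.OLS(y, design).fit()
    c0, c1, c2 = fit.params
    ci = fit.conf_int(alpha=0.05)
    ci_c2, ci_c1, ci_c0 = ci[2], ci[1], ci[0]
    if ci_c2[0] > 0:
        shape = "U"
    elif ci_c2[1] < 0:
        shape = "inverted-U"
    elif ci_c1[0] > 0 or ci_c1[1] < 0:
        shape = "monotone"
    else:
        shape = "flat"
    return TrendFit(
        coefficients=np.array([c2, c1, c0]),
        conf_int=np.vstack([ci_c2, ci_c1, ci_c0]),
        shape=shape,
        r_squared=float(fit.rsquared),
    )
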