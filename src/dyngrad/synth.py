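"""Synthetic cohorts with planted ground truth.

The generator emulates, at region scale, the statistical structure the
analysis assumes: smooth spatial gradient maps on a 2-D region set, BOLD-like
time series whose frame-wise correlation is a convex combination of a
structural-connectivity-like similarity (static weight) and a
neuromodulatory-similarity-like matrix (weight modulated by a latent arousal
process), a noisy pupil observation of that arousal process, a directed
log-normal tracing matrix with distance decay, and receptor expression maps
that load on planted gradients (plus pure-noise null receptors).

Because the frame correlation model is the convex combination

    R(a_t) = w_static · SC + w_mod(a_t) · NS + (1 − w_static − w_mod(a_t)) · I

of correlation matrices, every frame target is a valid correlation matrix by
construction; a Higham projection is still applied as a safeguard. A global
amplitude term proportional to (a_t − mean a) scales a fixed template map so
the fMRI-based arousal index is recoverable downstream.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

from ._utils import nearest_correlation, spawn_seed
from .containers import (
    DirectedTracingMatrix,
    ExpressionMatrix,
    GroundTruth,
    RegionTimeSeries,
    SyntheticCohort,
)

__all__ = [
    "make_spatial_maps",
    "make_arousal_process",
    "make_timeseries",
    "make_pupil",
    "make_tracing",
    "make_expression",
    "make_ground_truth",
    "refine_gradient_maps",
    "modulation_weight",
    "make_cohort",
    "DEFAULTS",
]

# Study conditions of the default synthetic cohort. Region count and the
# tracing shape mirror the marmoset parcellation (116 sources, 55 targets);
# TR = 2 s and 6 fps pupil sampling match the acquisition the analysis
# targets; the remaining values are the generator's committed defaults
# (rationale in docs/methods.md).
DEFAULTS = dict(
    n_regions=116,
    n_targets=55,
    n_scans=10,
    n_frames=500,
    tr=2.0,
    fps=6,
    smoothness=0.3,
    persistence=0.95,
    w_static=0.45,
    mod_amplitude=0.35,
    mod_shape="u",
    ev_mod=0.0,
    template_gain=1.0,
    sigma_obs=0.2,
    n_receptors=16,
    n_null=4,
    expression_noise=0.5,
    pupil_noise=0.05,
    blink_rate=0.1,
    tracing_decay=1.0,
    sc_eigenweights=(0.48, 0.44),
)

_FAMILIES = ("dopaminergic", "noradrenergic", "serotonergic", "cholinergic", "other")


def make_spatial_maps(
    n_regions: int, n_maps: int, smoothness: float, seed: int, orthonormalize: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Sample orthonormal smooth spatial maps on random 2-D coordinates.

    Coordinates are uniform in the unit square; each map is a Gaussian random
    field with covariance exp(−d / smoothness) over pairwise distances d, and
    the maps are then Gram–Schmidt orthonormalized (columns of the returned
    (n_regions × n_maps) array have unit norm and mutual inner products
    below 1e-10).
    """
    if n_maps >= n_regions:
        raise ValueError(f"n_maps ({n_maps}) must be < n_regions ({n_regions}): rank deficient")
    if smoothness <= 0:
        raise ValueError("smoothness must be > 0")
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0.0, 1.0, size=(n_regions, 2))
    d = squareform(pdist(coords))
    cov = np.exp(-d / smoothness)
    # jitter keeps the Cholesky stable for very smooth fields
    chol = np.linalg.cholesky(cov + 1e-10 * np.eye(n_regions))
    raw = chol @ rng.standard_normal((n_regions, n_maps))
    if not orthonormalize:
        # independent fields (unit marginal variance), e.g. for null studies
        return raw, coords
    q, r = np.linalg.qr(raw)
    # fix sign so the map correlates positively with its raw field
    maps = q * np.sign(np.diag(r))
    return maps, coords


def make_arousal_process(n_frames: int, persistence: float, seed: int) -> np.ndarray:
    """Latent arousal: stationary AR(1) squashed to [0, 1] by a logistic transform."""
    if not 0 <= persistence < 1:
        raise ValueError("persistence must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    x = np.empty(n_frames)
    sd0 = 1.0 / np.sqrt(1.0 - persistence**2)
    x[0] = rng.standard_normal() * sd0
    eps = rng.standard_normal(n_frames)
    for t in range(1, n_frames):
        x[t] = persistence * x[t - 1] + eps[t]
    # scale to unit marginal SD before squashing so arousal spread is
    # persistence-independent
    return 1.0 / (1.0 + np.exp(-x / sd0))


def modulation_weight(arousal: np.ndarray, amplitude: float, shape: str = "u") -> np.ndarray:
    """Arousal-dependent weight on the neuromodulatory similarity.

    shape="u": w(a) = amplitude · 4(a − ½)², largest at the arousal extremes
    (the regime in which neuromodulatory structure dominates); shape
    "inverted_u" flips it: amplitude · (1 − 4(a − ½)²).
    """
    q = 4.0 * (np.asarray(arousal) - 0.5) ** 2
    if shape == "u":
        return amplitude * q
    if shape == "inverted_u":
        return amplitude * (1.0 - q)
    raise ValueError(f"unknown modulation shape {shape!r}")


def make_ground_truth(
    n_regions: int = DEFAULTS["n_regions"],
    n_gradients: int = 2,
    smoothness: float = DEFAULTS["smoothness"],
    w_static: float = DEFAULTS["w_static"],
    mod_amplitude: float = DEFAULTS["mod_amplitude"],
    mod_shape: str = DEFAULTS["mod_shape"],
    sc_eigenweights: tuple[float, ...] = DEFAULTS["sc_eigenweights"],
    seed: int = 0,
) -> GroundTruth:
    """Plant maps, the structural similarity, and model weights (no time series yet).

    The structural similarity is the nearest correlation matrix to
    Σ_k ρ_k z_k z_kᵀ + (1 − Σρ)·I, with z_k √N-scaled smooth random fields.
    The planted gradient maps are then *defined* as the connectivity
    gradients of that noiseless similarity (orthonormalized), i.e. the
    ground truth is chain-consistent: what a perfect estimate of the static
    connectivity would embed to. gradient_maps columns: [0, n_gradients)
    structural gradients, [n_gradients, 2·n_gradients) receptor-specific
    maps, last column the amplitude template — all mutually orthonormal.
    """
    from .containers import ConnectivityMatrix
    from .gradients import gradients_from_connectivity

    n_total = 2 * n_gradients + 1
    raw, coords = make_spatial_maps(n_regions, n_total, smoothness, seed)
    rho = np.asarray(sc_eigenweights[:n_gradients], dtype=float)
    z = raw[:, :n_gradients] * np.sqrt(n_regions)
    sc = (z * rho) @ z.T + (1.0 - rho.sum()) * np.eye(n_regions)
    sc = nearest_correlation(sc)
    g = gradients_from_connectivity(
        ConnectivityMatrix(sc), n_components=n_gradients, density=0.10
    )
    stacked = np.column_stack([g.components, raw[:, n_gradients:]])
    q, r = np.linalg.qr(stacked)
    maps = q * np.sign(np.diag(r))  # sign: positive correlation with the source fields
    template = maps[:, -1] * np.sqrt(n_regions)  # RMS 1 across regions
    # unstructured correlation matrix used by the explained-variance
    # modulation: gradient-free covariance "roughness"
    rng = np.random.default_rng(seed + 1)
    rough = np.corrcoef(rng.standard_normal((n_regions, 2 * n_regions)))
    rough = nearest_correlation(0.5 * rough + 0.5 * np.eye(n_regions))
    truth = GroundTruth(
        gradient_maps=maps,
        coords=coords,
        weights=(1.0 - w_static - mod_amplitude, w_static, mod_amplitude),
        sc_sim=sc,
        template=template,
        n_gradients=n_gradients,
        mod_shape=mod_shape,
        rough_sim=rough,
    )
    return truth


def _arousal_moments() -> tuple[float, float]:
    """Moments of a = logistic(z), z ~ N(0,1): (E[4(a−½)²], Var[a]).

    Deterministic quadrature; these are the stationary moments of the
    arousal process (unit-SD latent state before squashing).
    """
    z = np.linspace(-10, 10, 8001)
    pdf = np.exp(-0.5 * z**2) / np.sqrt(2 * np.pi)
    a = 1.0 / (1.0 + np.exp(-z))
    e_q = np.trapezoid(4.0 * (a - 0.5) ** 2 * pdf, z)
    e_a = np.trapezoid(a * pdf, z)
    var_a = np.trapezoid((a - e_a) ** 2 * pdf, z)
    return float(e_q), float(var_a)


def refine_gradient_maps(
    truth: GroundTruth,
    sigma_obs: float = DEFAULTS["sigma_obs"],
    template_gain: float = DEFAULTS["template_gain"],
) -> GroundTruth:
    """Redefine the planted gradient maps as the gradients of the full static model.

    The expected static FC of the generative model is
    w_static·SC + E[w_mod]·NS + (1 − w_static − E[w_mod])·I plus the
    template amplitude covariance and observation noise. Running the
    gradient chain on that population matrix (and re-orthonormalizing the
    receptor/template maps against the result) makes the ground truth the
    exact fixed point of the estimator on noiseless data, so recovery error
    measures sampling noise only. Requires ns_sim (call after
    make_expression). Receptor loadings refer to the generative fields and
    are left untouched.
    """
    from .containers import ConnectivityMatrix
    from .gradients import gradients_from_connectivity

    if truth.ns_sim is None:
        raise ValueError("refine_gradient_maps needs ns_sim: call make_expression first")
    e_q, var_a = _arousal_moments()
    _, w_static, mod_amp = truth.weights
    e_w = mod_amp * (e_q if truth.mod_shape == "u" else (1.0 - e_q))
    n = truth.n_regions
    eye = np.eye(n)
    cov = (
        w_static * truth.sc_sim
        + e_w * truth.ns_sim
        + (1.0 - w_static - e_w) * eye
        + template_gain**2 * var_a * np.outer(truth.template, truth.template)
        + sigma_obs**2 * eye
    )
    d = np.sqrt(np.diag(cov))
    fc = cov / np.outer(d, d)
    k = truth.n_gradients
    g = gradients_from_connectivity(ConnectivityMatrix(fc), n_components=k, density=0.10)
    old = truth.gradient_maps
    # Gradient maps: the chain components themselves, unit-normalized but NOT
    # mutually orthogonalized — diffusion-map components are orthogonal in
    # the stationary measure, not Euclidean, and forcing Euclidean
    # orthogonality would displace the planted truth from the estimator's
    # noiseless fixed point. Receptor/template maps are orthogonalized
    # against the gradient subspace (their roles require independence).
    grad = g.components / np.linalg.norm(g.components, axis=0)
    stacked = np.column_stack([grad, old[:, k:]])
    q, _ = np.linalg.qr(stacked)
    maps = np.column_stack([grad, q[:, k:]])
    signs = np.sign(np.sum(maps * old, axis=0))
    signs[signs == 0] = 1.0
    maps = maps * signs
    truth.gradient_maps = maps
    truth.template = maps[:, -1] * np.sqrt(n)
    return truth


def make_timeseries(
    truth: GroundTruth,
    n_frames: int,
    tr: float,
    sigma_obs: float,
    seed: int,
    arousal: np.ndarray | None = None,
    template_gain: float = DEFAULTS["template_gain"],
    ev_mod: float = 0.0,
) -> RegionTimeSeries:
    """Sample one scan from the planted frame-correlation model.

    Frame t is zero-mean Gaussian with correlation R(a_t) (see module
    docstring), plus template_gain · (a_t − mean a) times the amplitude
    template, plus N(0, sigma_obs²) observation noise. With ev_mod > 0 the
    frame correlation is additionally mixed toward the unstructured
    rough_sim matrix with weight ev_mod · 4(a_t − ½)², which plants an
    inverted-U dependence of gradient explained variance on arousal
    (gradient structure is genuinely weakest at the arousal extremes).
    Modulation weights are quantized to a 1/512 grid so Cholesky factors
    are cached per level.
    """
    if truth.sc_sim is None:
        raise ValueError("truth is incomplete: sc_sim missing")
    ns = truth.ns_sim if truth.ns_sim is not None else np.eye(truth.n_regions)
    if arousal is None:
        arousal = np.asarray(truth.arousal_signal)
    if arousal.ndim != 1 or arousal.size < n_frames:
        raise ValueError("arousal signal shorter than requested n_frames")
    arousal = arousal[:n_frames]
    _, w_static, mod_amp = truth.weights
    rng = np.random.default_rng(seed)
    n = truth.n_regions
    w_mod = modulation_weight(arousal, mod_amp, truth.mod_shape)
    w_q = np.round(w_mod * 512.0) / 512.0
    if ev_mod > 0:
        if truth.rough_sim is None:
            raise ValueError("ev_mod > 0 requires truth.rough_sim")
        u_q = np.round(modulation_weight(arousal, ev_mod, "u") * 512.0) / 512.0
    else:
        u_q = np.zeros(n_frames)
    eye = np.eye(n)
    chol_cache: dict[tuple[float, float], np.ndarray] = {}
    for w, u in set(zip(w_q, u_q)):
        r = w_static * truth.sc_sim + w * ns + (1.0 - w_static - w) * eye
        if u > 0:
            r = (1.0 - u) * r + u * truth.rough_sim
        r = nearest_correlation(r)  # no-op for the convex combination; safeguard
        chol_cache[(float(w), float(u))] = np.linalg.cholesky(r + 1e-12 * eye)
    eps = rng.standard_normal((n_frames, n))
    data = np.empty((n_frames, n))
    for t in range(n_frames):
        data[t] = chol_cache[(float(w_q[t]), float(u_q[t]))] @ eps[t]
    amp = template_gain * (arousal - arousal.mean())
    data += amp[:, None] * truth.template[None, :]
    if sigma_obs > 0:
        data += sigma_obs * rng.standard_normal((n_frames, n))
    return RegionTimeSeries(data=data, tr=tr)


def make_pupil(
    arousal_signal: np.ndarray,
    tr: float,
    fps: int,
    noise_sd: float,
    blink_rate: float,
    seed: int,
) -> np.ndarray:
    """Observe arousal through a pupil-like trace sampled at fps.

    Arousal is upsampled by sample-and-hold to fps·tr samples per frame,
    Gaussian noise added, and blink gaps (NaN runs shorter than 0.5 s,
    uniform length in [1, 0.5·fps] samples) inserted at Poisson rate
    blink_rate per second.
    """
    spf = fps * tr
    if abs(spf - round(spf)) > 1e-9:
        raise ValueError("fps × tr must be an integer number of samples per frame")
    spf = int(round(spf))
    rng = np.random.default_rng(seed)
    trace = np.repeat(np.asarray(arousal_signal, dtype=float), spf)
    if noise_sd > 0:
        trace = trace + noise_sd * rng.standard_normal(trace.size)
    duration = trace.size / fps
    n_blinks = rng.poisson(blink_rate * duration)
    max_gap = max(1, int(0.5 * fps))
    for _ in range(n_blinks):
        start = rng.integers(0, trace.size)
        gap = int(rng.integers(1, max_gap + 1))
        trace[start : start + gap] = np.nan
    return trace


def make_tracing(
    n_source: int,
    n_target: int,
    coords: np.ndarray,
    decay: float,
    seed: int,
    log_sd: float = 0.8,
) -> DirectedTracingMatrix:
    """Directed log-normal tracing weights with distance-decaying mean.

    Targets are a random subset of the source regions; log-weights are
    −decay·d(source, target) plus Gaussian noise, so weights are strictly
    positive and the matrix is generally asymmetric and non-square.
    """
    if n_target > n_source:
        raise ValueError("n_target must be ≤ n_source")
    coords = np.asarray(coords, dtype=float)
    rng = np.random.default_rng(seed)
    target_idx = np.sort(rng.choice(n_source, size=n_target, replace=False))
    d = cdist(coords[:n_source], coords[target_idx])
    logw = -decay * d + log_sd * rng.standard_normal(d.shape)
    return DirectedTracingMatrix(
        weights=np.exp(logw),
        source_labels=[f"R{i:03d}" for i in range(n_source)],
        target_labels=[f"R{i:03d}" for i in target_idx],
    )


def make_expression(
    truth: GroundTruth,
    n_receptors: int,
    n_null: int,
    noise_sd: float,
    seed: int,
    loadings: np.ndarray | None = None,
    noise_smoothness: float = DEFAULTS["smoothness"],
) -> ExpressionMatrix:
    """Receptor expression maps loading on planted gradients, plus null receptors.

    Non-null receptors cycle through three ground-truth groups — loading on
    gradient 1, on gradient 2, or on both — each with a secondary loading on
    its receptor-specific map so the neuromodulatory similarity carries
    structure the structural similarity does not. Null receptors are pure
    noise (exactly zero loading rows). Expression noise is spatially smooth
    (a Gaussian random field over the region coordinates), as histology-
    derived expression maps are; in particular a null receptor is a smooth
    map unrelated to the gradients, not white noise. Rows are shifted to be
    nonnegative (Pearson-invariant). Sets truth.receptor_loadings and
    truth.ns_sim.
    """
    if n_null > n_receptors:
        raise ValueError("n_null must be ≤ n_receptors")
    rng = np.random.default_rng(seed)
    n_grad = truth.n_gradients
    k_total = truth.gradient_maps.shape[1]
    n_sig = n_receptors - n_null
    if loadings is None:
        loadings = np.zeros((n_receptors, k_total))
        for r in range(n_sig):
            group = r % 3
            row = np.zeros(k_total)
            if group == 0:  # gradient-1 loaders
                row[0] = 1.0
                row[n_grad] = 0.7
            elif group == 1:  # gradient-2 loaders
                row[min(1, n_grad - 1)] = 1.0
                row[min(n_grad + 1, 2 * n_grad - 1)] = 0.7
            else:  # dual loaders
                row[0] = 0.7
                row[min(1, n_grad - 1)] = 0.7
                row[n_grad] = 0.35
                row[min(n_grad + 1, 2 * n_grad - 1)] = 0.35
            loadings[r] = row / np.linalg.norm(row)
    loadings = np.asarray(loadings, dtype=float)
    z_maps = truth.gradient_maps * np.sqrt(truth.n_regions)  # RMS-1 maps
    expr = loadings @ z_maps.T
    # spatially smooth noise field (unit marginal variance) over region coords
    d = squareform(pdist(truth.coords))
    noise_chol = np.linalg.cholesky(np.exp(-d / noise_smoothness) + 1e-10 * np.eye(truth.n_regions))
    smooth_noise = (noise_chol @ rng.standard_normal((truth.n_regions, n_receptors))).T
    if noise_sd > 0:
        expr = expr + noise_sd * smooth_noise
    else:
        # null receptors must not be constant rows
        expr[np.all(loadings == 0, axis=1)] += 1e-6 * smooth_noise[np.all(loadings == 0, axis=1)]
    expr = expr - expr.min(axis=1, keepdims=True)  # nonnegative expression levels
    groups = np.full(n_receptors, 4)
    groups[:n_sig] = np.arange(n_sig) % 3 + 1
    labels = [f"REC{i:02d}" for i in range(n_receptors)]
    families = [_FAMILIES[i % len(_FAMILIES)] for i in range(n_receptors)]
    em = ExpressionMatrix(
        values=expr, receptor_labels=labels, families=families, truth_groups=groups
    )
    truth.receptor_loadings = loadings
    # Generative neuromodulatory similarity: region-profile correlation over
    # the LOADED receptors only. Null receptors exist in the observed
    # expression matrix but are genuinely inert — their maps never enter the
    # covariance the scans are sampled from.
    loaded = ~np.all(loadings == 0, axis=1)
    # a region-pair correlation needs ≥ 2 profile entries; fall back to the
    # full matrix for tiny panels
    rows = expr[loaded] if loaded.sum() >= 2 else expr
    c = np.corrcoef(rows.T)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    truth.ns_sim = nearest_correlation(c)
    return em


def make_cohort(seed: int = 0, **overrides) -> SyntheticCohort:
    """Generate a full synthetic cohort under the committed study conditions.

    Any DEFAULTS key can be overridden by keyword. Per-scan arousal signals
    are stored in truth.arousal_signal as a list of per-scan arrays.
    """
    p = dict(DEFAULTS)
    unknown = set(overrides) - set(p)
    if unknown:
        raise TypeError(f"unknown cohort parameters: {sorted(unknown)}")
    p.update(overrides)
    truth = make_ground_truth(
        n_regions=p["n_regions"],
        smoothness=p["smoothness"],
        w_static=p["w_static"],
        mod_amplitude=p["mod_amplitude"],
        mod_shape=p["mod_shape"],
        sc_eigenweights=p["sc_eigenweights"],
        seed=spawn_seed(seed, "maps"),
    )
    expression = make_expression(
        truth,
        n_receptors=p["n_receptors"],
        n_null=p["n_null"],
        noise_sd=p["expression_noise"],
        seed=spawn_seed(seed, "expression"),
    )
    refine_gradient_maps(truth, sigma_obs=p["sigma_obs"], template_gain=p["template_gain"])
    tracing = make_tracing(
        p["n_regions"],
        p["n_targets"],
        truth.coords,
        decay=p["tracing_decay"],
        seed=spawn_seed(seed, "tracing"),
    )
    scans, pupils, arousals = [], [], []
    for s in range(p["n_scans"]):
        a = make_arousal_process(p["n_frames"], p["persistence"], spawn_seed(seed, "arousal", s))
        ts = make_timeseries(
            truth,
            p["n_frames"],
            p["tr"],
            p["sigma_obs"],
            spawn_seed(seed, "scan", s),
            arousal=a,
            template_gain=p["template_gain"],
            ev_mod=p["ev_mod"],
        )
        pupil = make_pupil(
            a,
            p["tr"],
            p["fps"],
            p["pupil_noise"],
            p["blink_rate"],
            spawn_seed(seed, "pupil", s),
        )
        scans.append(ts)
        pupils.append(pupil)
        arousals.append(a)
    truth.arousal_signal = arousals
    return SyntheticCohort(
        scans=scans,
        pupil_traces=pupils,
        tracing=tracing,
        expression=expression,
        truth=truth,
        tr=p["tr"],
        fps=p["fps"],
    )
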