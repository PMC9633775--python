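"""Lightweight containers for the objects the pipeline passes between stages.

Everything is a thin dataclass over numpy arrays: region×time BOLD blocks,
gradient embeddings, arousal traces, similarity matrices, tracing and
expression tables, and the ground-truth record attached to synthetic cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RegionTimeSeries",
    "GradientSet",
    "ArousalTrace",
    "ArousalTemplate",
    "SimilarityMatrix",
    "ConnectivityMatrix",
    "AffinityMatrix",
    "DirectedTracingMatrix",
    "ExpressionMatrix",
    "GroundTruth",
    "SyntheticCohort",
    "DCCParams",
    "DynamicConnectivity",
    "TrendFit",
    "GLMFit",
    "VariancePartition",
    "SurrogateEnsemble",
]


@dataclass
class RegionTimeSeries:
    """One scan: T frames × N regions of BOLD signal, with repetition time in seconds."""

    data: np.ndarray  # (T, N)
    tr: float
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("RegionTimeSeries.data must be 2-D (frames × regions)")
        if self.labels is None:
            self.labels = [f"R{i:03d}" for i in range(self.data.shape[1])]

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


@dataclass
class GradientSet:
    """N×K gradient components with diffusion eigenvalues and explained-variance fractions."""

    components: np.ndarray  # (N, K)
    eigenvalues: np.ndarray  # (K,)
    explained_variance: np.ndarray  # (K,), nonincreasing, in [0, 1]
    reference_aligned: bool = False

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.explained_variance = np.asarray(self.explained_variance, dtype=float)
        if not np.all(np.isfinite(self.components)):
            raise ValueError("gradient components must be finite")
        ev = self.explained_variance
        if ev.size and (np.any(ev < -1e-12) or np.any(ev > 1 + 1e-12)):
            raise ValueError("explained_variance entries must lie in [0, 1]")
        if ev.size > 1 and np.any(np.diff(ev) > 1e-10):
            raise ValueError("explained_variance must be nonincreasing")

    @property
    def n_components(self) -> int:
        return self.components.shape[1]


@dataclass
class ArousalTrace:
    """Per-frame arousal index; behavioral (pupil, in [0,1]) or fMRI template projection (in [-1,1])."""

    index: np.ndarray
    kind: str  # "behavioral" | "fmri_template"
    eye_open_ratio: float = float("nan")
    flagged: np.ndarray | None = None  # frames imputed/degenerate

    def __post_init__(self) -> None:
        self.index = np.asarray(self.index, dtype=float)
        if self.kind not in ("behavioral", "fmri_template"):
            raise ValueError(f"unknown arousal trace kind {self.kind!r}")
        if self.flagged is None:
            self.flagged = np.zeros(self.index.size, dtype=bool)


@dataclass
class ArousalTemplate:
    """Per-region correlation of BOLD with the convolved behavioral arousal index."""

    map: np.ndarray

    def __post_init__(self) -> None:
        self.map = np.asarray(self.map, dtype=float)
        if not np.all(np.isfinite(self.map)):
            raise ValueError("arousal template must be finite")


@dataclass
class SimilarityMatrix:
    """Symmetric N×N Pearson-similarity matrix. role ∈ {FC, SC, NS}."""

    values: np.ndarray
    role: str = "FC"
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("similarity matrix must be symmetric")
        if not np.all(np.isfinite(v)):
            raise ValueError("similarity matrix must be finite")
        self.values = (v + v.T) / 2.0
        if self.labels is None:
            self.labels = [f"R{i:03d}" for i in range(v.shape[0])]

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


# An FC matrix is structurally a similarity matrix with role "FC".
ConnectivityMatrix = SimilarityMatrix


@dataclass
class AffinityMatrix:
    """Nonnegative normalized-angle affinity in [0, 1]; density records the retained fraction."""

    values: np.ndarray
    density: float = 1.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise ValueError("affinity values must lie in [0, 1]")
        self.values = np.clip((v + v.T) / 2.0, 0.0, 1.0)


@dataclass
class DirectedTracingMatrix:
    """Directed tracing weights, sources × targets; strictly positive, generally non-square."""

    weights: np.ndarray  # (S, T)
    source_labels: list[str] | None = None
    target_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.source_labels is None:
            self.source_labels = [f"S{i:03d}" for i in range(self.weights.shape[0])]
        if self.target_labels is None:
            self.target_labels = [f"T{i:03d}" for i in range(self.weights.shape[1])]


@dataclass
class ExpressionMatrix:
    """Receptor × region nonnegative expression levels with family tags."""

    values: np.ndarray  # (G, N)
    receptor_labels: list[str]
    families: list[str] | None = None
    truth_groups: np.ndarray | None = None  # generator's ground-truth group per receptor

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.receptor_labels) != self.values.shape[0]:
            raise ValueError("one label per receptor required")
        if self.families is None:
            self.families = ["other"] * self.values.shape[0]

    @property
    def n_receptors(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort.

    gradient_maps holds all planted orthonormal maps: columns 0..n_gradients-1
    drive the structural similarity (the recoverable functional gradients),
    the following columns are receptor-specific spatial structure, and the
    last column is the global-amplitude template used for the fMRI arousal
    index. weights = (w_identity, w_static, w_mod_amplitude) of the frame
    correlation model.
    """

    gradient_maps: np.ndarray  # (N, K_total), orthonormal columns
    coords: np.ndarray  # (N, 2)
    weights: tuple[float, float, float]
    arousal_signal: np.ndarray | list[np.ndarray] = field(default_factory=lambda: np.empty(0))
    receptor_loadings: np.ndarray | None = None  # (G, K_total); zero rows = null receptors
    sc_sim: np.ndarray | None = None
    ns_sim: np.ndarray | None = None
    rough_sim: np.ndarray | None = None  # unstructured correlation for EV modulation
    template: np.ndarray | None = None  # amplitude map, RMS 1 over regions
    n_gradients: int = 2
    mod_shape: str = "u"

    @property
    def n_regions(self) -> int:
        return self.gradient_maps.shape[0]


@dataclass
class SyntheticCohort:
    scans: list[RegionTimeSeries]
    pupil_traces: list[np.ndarray]
    tracing: DirectedTracingMatrix
    expression: ExpressionMatrix
    truth: GroundTruth
    tr: float = 2.0
    fps: int = 6


@dataclass
class DCCParams:
    """Two-stage QMLE estimates: per-series GARCH(1,1) and scalar DCC(1,1)."""

    garch: np.ndarray  # (N, 3): omega, alpha, beta per series
    a: float
    b: float
    loglik: float
    converged: bool = True

    def __post_init__(self) -> None:
        g = np.asarray(self.garch, dtype=float)
        if np.any(g[:, 0] <= 0) or np.any(g[:, 1] < 0) or np.any(g[:, 2] < 0):
            raise ValueError("GARCH parameters violate positivity")
        if np.any(g[:, 1] + g[:, 2] >= 1):
            raise ValueError("GARCH stationarity violated (alpha + beta >= 1)")
        if self.a < 0 or self.b < 0 or self.a + self.b >= 1:
            raise ValueError("DCC stationarity violated (a + b >= 1)")
        self.garch = g


@dataclass
class DynamicConnectivity:
    """Per-frame conditional correlation matrices R_t, (T, N, N)."""

    frames: np.ndarray
    tr: float = 2.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1] != self.frames.shape[2]:
            raise ValueError("frames must be (T, N, N)")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_regions(self) -> int:
        return self.frames.shape[1]


@dataclass
class TrendFit:
    """Quadratic trend y = c2 x² + c1 x + c0 with 95% CIs and a shape label."""

    coefficients: np.ndarray  # (c2, c1, c0)
    conf_int: np.ndarray  # (3, 2) rows match coefficients
    shape: str  # inverted-U | U | monotone | flat
    r_squared: float


@dataclass
class GLMFit:
    """FC = b0 + b1·SC + b2·NS fitted on region-pair vectors (slope-ridge optional)."""

    coefficients: np.ndarray  # (b0, b1, ..., bk)
    predicted: np.ndarray
    r_squared: float
    ridge: float = 0.0


@dataclass
class VariancePartition:
    """Full-model cvR² with per-predictor single-variable (upper) and ΔR² (lower) bounds."""

    cv_r2_full: float
    cv_r2_full_per_scan: np.ndarray
    cv_r2_single: dict[str, float]
    delta_r2: dict[str, float]
    delta_r2_distributions: dict[str, np.ndarray]
    n_shuffles: int = 0
    seed: int | None = None


@dataclass
class SurrogateEnsemble:
    """Spatial-autocorrelation-preserving surrogate maps (M × N) for one source map."""

    maps: np.ndarray
    target_variogram: np.ndarray
    lag_centers: np.ndarray
    fit_error: np.ndarray  # per-surrogate variogram mismatch
    seed: int | None = None
    k_neighbors: np.ndarray | None = None  # smoothing neighborhood chosen per surrogate

    @property
    def n_surrogates(self) -> int:
        return self.maps.shape[0]
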