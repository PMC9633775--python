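"""Shared numerical helpers: correlation-matrix projection, seeding, small linear algebra."""

from __future__ import annotations

import zlib

import numpy as np


def spawn_seed(seed: int, *tags: object) -> int:
    """Derive a child seed (< 2**31) from a parent seed and a tag sequence.

    Deterministic fan-out (stable across processes: crc32, not the salted
    built-in hash) so one global seed reproduces every stage.
    """
    ss = np.random.SeedSequence(
        [int(seed) & 0x7FFFFFFF, *(zlib.crc32(str(t).encode()) % (2**31) for t in tags)]
    )
    return int(ss.generate_state(1)[0] % (2**31))


def is_psd(a: np.ndarray, tol: float = 1e-10) -> bool:
    return float(np.linalg.eigvalsh((a + a.T) / 2).min()) >= -tol


def nearest_correlation(a: np.ndarray, tol: float = 1e-8, max_iter: int = 200) -> np.ndarray:
    """Project a symmetric matrix to the nearest correlation matrix.

    Higham's alternating-projection method (PSD cone / unit-diagonal affine
    set, with Dykstra correction). Returns the input unchanged (diagonal
    forced to 1) when it is already a valid correlation matrix.
    """
    a = np.asarray(a, dtype=float)
    x = (a + a.T) / 2.0
    np.fill_diagonal(x, 1.0)
    if is_psd(x):
        return x
    ds = np.zeros_like(x)
    y = x.copy()
    for _ in range(max_iter):
        r = y - ds
        w, v = np.linalg.eigh((r + r.T) / 2.0)
        x_new = (v * np.clip(w, 0.0, None)) @ v.T
        ds = x_new - r
        y_new = x_new.copy()
        np.fill_diagonal(y_new, 1.0)
        if np.linalg.norm(y_new - y, "fro") <= tol * max(1.0, np.linalg.norm(y, "fro")):
            y = y_new
            break
        y = y_new
    # final symmetrization + tiny eigenvalue clip so downstream Cholesky succeeds
    y = (y + y.T) / 2.0
    w, v = np.linalg.eigh(y)
    if w.min() < 0:
        y = (v * np.clip(w, 0.0, None)) @ v.T
        d = np.sqrt(np.clip(np.diag(y), 1e-12, None))
        y = y / np.outer(d, d)
    np.fill_diagonal(y, 1.0)
    return (y + y.T) / 2.0


def pearson_rows(x: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation matrix with exact unit diagonal."""
    c = np.corrcoef(x)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return c


def upper_triangle(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Row-major upper-triangle (i<j) index pair, the pair-vector ordering used throughout."""
    return np.triu_indices(n, k=1)
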