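"""Tapered sliding-window functional network connectivity.

The window taper is a rectangle (20 samples by default, spanning 47.2 s at
TR = 2.36 s) convolved with a Gaussian (sigma = 3 samples), normalized to unit
mass.  Within each window position the Pearson correlation between every pair
of components is computed with the taper as observation weights, and the upper
triangle is vectorized in row-major (i < j) order — for C = 53 components that
is P = 53*52/2 = 1378 connectivity values per window.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .timecourses import ComponentTimecourses


@dataclass(frozen=True)
class TaperSpec:
    """Sliding-window taper: rectangle width, Gaussian sigma, and step, all in
    units of TR (samples)."""

    rect_width: int = 20
    gaussian_sigma: float = 3.0
    step: int = 1

    def __post_init__(self) -> None:
        if self.rect_width < 2:
            raise ValueError("rect_width must be >= 2")
        if not self.gaussian_sigma > 0:
            raise ValueError("gaussian_sigma must be positive")
        if self.step < 1:
            raise ValueError("step must be >= 1")


def make_taper(spec: TaperSpec | None = None) -> np.ndarray:
    """Taper weights: unit rectangle convolved with a +-3 sigma Gaussian.

    Weights below 1e-8 of the maximum are trimmed from the ends; the result is
    symmetric, nonnegative and sums to 1.  In the sigma -> 0 limit the kernel
    is a delta and the taper tends to a uniform window of length rect_width.
    """
    spec = spec or TaperSpec()
    radius = math.ceil(3.0 * spec.gaussian_sigma)
    x = np.arange(-radius, radius + 1, dtype=float)
    kernel = np.exp(-0.5 * (x / spec.gaussian_sigma) ** 2)
    kernel /= kernel.sum()
    w = np.convolve(np.ones(spec.rect_width), kernel, mode="full")
    keep = np.flatnonzero(w > 1e-8 * w.max())
    w = w[keep[0]: keep[-1] + 1]
    return w / w.sum()


def pair_index(C: int) -> list[tuple[int, int]]:
    """Ordered (i, j) component pairs, row-major upper triangle, 0-based."""
    return [(i, j) for i in range(C) for j in range(i + 1, C)]


def vectorize_fnc(matrix: np.ndarray) -> np.ndarray:
    """Upper triangle (excluding the diagonal) of a symmetric C x C matrix,
    in row-major order."""
    M = np.asarray(matrix)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("expected a square matrix")
    if not np.allclose(M, M.T, atol=1e-10, equal_nan=True):
        raise ValueError("expected a symmetric matrix")
    iu = np.triu_indices(M.shape[0], k=1)
    return M[iu]


def devectorize_fnc(vector: np.ndarray, C: int) -> np.ndarray:
    """Inverse of :func:`vectorize_fnc`: rebuild the symmetric matrix with a
    unit diagonal."""
    v = np.asarray(vector, dtype=float)
    P = C * (C - 1) // 2
    if v.shape != (P,):
        raise ValueError(f"expected length {P} for C={C}, got {v.shape}")
    M = np.eye(C)
    iu = np.triu_indices(C, k=1)
    M[iu] = v
    M[(iu[1], iu[0])] = v
    return M


@dataclass
class DfncWindows:
    """One subject's windowed connectivity: a W x P matrix plus bookkeeping."""

    subject_id: str
    matrix: np.ndarray
    window_starts: np.ndarray
    n_components: int
    taper: TaperSpec = field(default_factory=TaperSpec)

    @property
    def n_windows(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.matrix.shape[1]

    def pair_index(self) -> list[tuple[int, int]]:
        return pair_index(self.n_components)


def _weighted_correlations(windows: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Batch taper-weighted correlation matrices.

    windows: (W, L, C) stacked window slices; w: length-L weights summing
    to 1.  Returns (W, C, C) correlation arrays; zero-variance pairs get 0.
    """
    mu = np.einsum("wlc,l->wc", windows, w)
    Xc = windows - mu[:, None, :]
    cov = np.matmul(np.transpose(Xc, (0, 2, 1)) * w[None, None, :], Xc)
    var = np.einsum("wcc->wc", cov)
    sd = np.sqrt(np.clip(var, 0.0, None))
    # a column is degenerate when its windowed sd is at rounding level
    # relative to the signal's root-mean-square
    rms = np.sqrt(np.einsum("wlc,l->wc", windows**2, w))
    degenerate = sd <= 1e-12 * np.maximum(rms, 1e-300)
    denom = sd[:, :, None] * sd[:, None, :]
    bad = degenerate[:, :, None] | degenerate[:, None, :] | (denom <= 0)
    if bad.any():
        warnings.warn("zero weighted variance in some windows; correlations set to 0",
                      stacklevel=3)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(bad, 0.0, cov / np.where(bad, 1.0, denom))
    return np.clip(corr, -1.0, 1.0)


def compute_dfnc(tc: ComponentTimecourses, spec: TaperSpec | None = None) -> DfncWindows:
    """Tapered sliding-window Pearson connectivity for one subject.

    With step 1 the number of windows is W = T - L + 1 where L is the
    effective taper length.
    """
    spec = spec or TaperSpec()
    w = make_taper(spec)
    L = len(w)
    T, C = tc.data.shape
    if T < L:
        raise ValueError(f"T={T} shorter than taper length L={L}")
    slices = sliding_window_view(tc.data, L, axis=0)  # (T-L+1, C, L)
    starts = np.arange(0, T - L + 1, spec.step)
    windows = np.transpose(slices[starts], (0, 2, 1))  # (W, L, C)
    corr = _weighted_correlations(windows, w)
    iu = np.triu_indices(C, k=1)
    return DfncWindows(
        subject_id=tc.subject_id,
        matrix=corr[:, iu[0], iu[1]],
        window_starts=starts,
        n_components=C,
        taper=spec,
    )


def compute_sfnc(tc: ComponentTimecourses) -> np.ndarray:
    """Static connectivity: plain Pearson over the entire recording,
    vectorized like the windowed version.

    Note this is only approximately the mean of the windowed correlations;
    the two are distinct summaries.
    """
    if tc.n_timepoints < 3:
        raise ValueError("need at least 3 timepoints")
    data = tc.data
    sd = data.std(axis=0)
    if (sd == 0).any():
        warnings.warn("zero-variance component; its pairs set to 0", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(data, rowvar=False)
    corr = np.where(np.isfinite(corr), corr, 0.0)
    return np.clip(vectorize_fnc(corr), -1.0, 1.0)
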