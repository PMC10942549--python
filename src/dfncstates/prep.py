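"""Post-ICA timecourse cleaning.

Four per-column stages, applied in order: polynomial detrending (cubic by
default), nuisance regression against realignment-parameter regressors,
MAD-based despiking with linear interpolation, and a zero-phase low-pass
Butterworth filter (0.15 Hz cut-off by default).  Every stage preserves the
matrix shape and operates column-wise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .timecourses import ComponentTimecourses


@dataclass(frozen=True)
class PrepConfig:
    """Cleaning parameters.

    nuisance is an optional T x R regressor matrix (e.g. six realignment
    parameters and their temporal derivatives, R = 12); when None — as for
    synthetic data without a motion model — the regression stage is skipped.
    """

    detrend_order: int = 3
    lowpass_hz: float = 0.15
    despike_mad_k: float = 4.0
    nuisance: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.detrend_order < 0:
            raise ValueError("detrend_order must be >= 0")
        if not self.lowpass_hz > 0:
            raise ValueError("lowpass_hz must be positive")
        if not self.despike_mad_k > 0:
            raise ValueError("despike_mad_k must be positive")


def detrend_poly(tc: ComponentTimecourses, order: int = 3) -> ComponentTimecourses:
    """Remove a least-squares polynomial trend (degrees 0..order) per column.

    The residual of the fit is returned, so column means are zero.
    """
    T = tc.n_timepoints
    if order >= T:
        raise ValueError("polynomial order must be smaller than T")
    # Chebyshev-style normalized time for a well-conditioned basis
    t = np.linspace(-1.0, 1.0, T) if T > 1 else np.zeros(1)
    basis = np.polynomial.polynomial.polyvander(t, order)
    coef, *_ = np.linalg.lstsq(basis, tc.data, rcond=None)
    return tc.with_data(tc.data - basis @ coef)


def regress_nuisance(tc: ComponentTimecourses, regressors: np.ndarray) -> ComponentTimecourses:
    """Project out the column space of ``regressors`` (plus an intercept).

    Rank-deficient regressor sets are reduced to an independent subset with a
    warning.  The residual is orthogonal to every retained regressor.
    """
    X = np.asarray(regressors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    T = tc.n_timepoints
    if X.shape[0] != T:
        raise ValueError("regressors must have T rows")
    if X.shape[1] >= T:
        raise ValueError("need fewer regressors than timepoints")
    if not np.isfinite(X).all():
        raise ValueError("regressors must be finite")

    # standardize for conditioning; constant columns become zero and are dropped
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    keep = sd > 0
    Xs = Xc[:, keep] / sd[keep]
    if Xs.shape[1] < X.shape[1]:
        warnings.warn("dropped constant nuisance regressors", stacklevel=2)
    if Xs.shape[1] == 0:
        return tc.with_data(tc.data.copy())

    Q, R = np.linalg.qr(Xs, mode="reduced")
    diag = np.abs(np.diag(R))
    rank_mask = diag > 1e-10 * diag.max()
    if not rank_mask.all():
        warnings.warn("dropped collinear nuisance regressors", stacklevel=2)
        Q = Q[:, rank_mask]

    data = tc.data - tc.data.mean(axis=0)
    resid = data - Q @ (Q.T @ data)
    return tc.with_data(resid)


def despike(tc: ComponentTimecourses, mad_k: float = 4.0) -> ComponentTimecourses:
    """Replace MAD outliers by linear interpolation of neighbouring samples.

    A sample is an outlier when |x - median| > mad_k * 1.4826 * MAD.  Ends are
    clamped to the nearest non-outlier value.  Columns with zero MAD, or where
    every sample would be flagged, are left untouched (with a warning in the
    all-outlier case).
    """
    T = tc.n_timepoints
    if T < 3:
        raise ValueError("need at least 3 timepoints to despike")
    out = tc.data.copy()
    t = np.arange(T)
    for j in range(tc.n_components):
        x = out[:, j]
        med = np.median(x)
        mad = np.median(np.abs(x - med))
        if mad == 0:
            continue
        bad = np.abs(x - med) > mad_k * 1.4826 * mad
        if not bad.any():
            continue
        if bad.all():
            warnings.warn(f"column {j}: every sample flagged; left unchanged",
                          stacklevel=2)
            continue
        out[bad, j] = np.interp(t[bad], t[~bad], x[~bad])
    return tc.with_data(out)


def lowpass(tc: ComponentTimecourses, cutoff_hz: float = 0.15) -> ComponentTimecourses:
    """Zero-phase 5th-order Butterworth low-pass filter, per column."""
    nyquist = 0.5 / tc.tr
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(f"cutoff must lie in (0, {nyquist}) Hz for TR={tc.tr}")
    sos = signal.butter(5, cutoff_hz, btype="low", fs=1.0 / tc.tr, output="sos")
    return tc.with_data(signal.sosfiltfilt(sos, tc.data, axis=0))


def preprocess(
    tc: ComponentTimecourses, config: PrepConfig | None = None
) -> ComponentTimecourses:
    """Run the full cleaning chain: detrend -> nuisance -> despike -> lowpass."""
    cfg = config or PrepConfig()
    out = detrend_poly(tc, cfg.detrend_order)
    if cfg.nuisance is not None:
        out = regress_nuisance(out, cfg.nuisance)
    out = despike(out, cfg.despike_mad_k)
    out = lowpass(out, cfg.lowpass_hz)
    if not np.isfinite(out.data).all():
        raise RuntimeError("non-finite values after cleaning")
    return out
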