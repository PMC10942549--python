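"""Group brain-state estimation from windowed connectivity.

All subjects' window vectors are pooled and clustered with k-means (Euclidean
distance, k-means++ initialization, best of several restarts).  The number of
states can be chosen by an elbow criterion on the ratio of within- to
between-cluster distance swept over k = 2..9.  Cluster centroids are the
"brain states"; states are relabeled in descending pooled occupancy so state 1
is always the most visited.  Each subject gets a state vector (one label per
window) and a K-vector of occupancy rates (OCRs) summing to 1.

The public surface follows the model/results idiom: build a
:class:`DfncStateModel` from per-subject windows, call ``fit`` and read the
estimates off the returned :class:`DfncStateResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .windows import DfncWindows


@dataclass
class StateModel:
    """K centroids in connectivity (P) space plus clustering metadata."""

    K: int
    centroids: np.ndarray  # (K, P), row k is state k+1
    inertia: float
    n_init: int
    max_iter: int
    seed: int | None
    distance: str = "euclidean"
    converged: bool = True
    k_sweep: dict[int, float] | None = None


@dataclass
class StateVector:
    """Per-subject sequence of 1-based state labels, one per window."""

    subject_id: str
    labels: np.ndarray

    def __len__(self) -> int:
        return len(self.labels)


# ---------------------------------------------------------------------------
# low-level operations
# ---------------------------------------------------------------------------


def _pool(windows: Sequence[DfncWindows]) -> tuple[np.ndarray, list[tuple[str, int]]]:
    mats = [w.matrix for w in windows]
    sizes = [(w.subject_id, w.n_windows) for w in windows]
    return np.vstack(mats), sizes


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _fit_kmeans(X: np.ndarray, k: int, n_init: int, max_iter: int,
                seed: int | None) -> KMeans:
    # single precision + Elkan bounds: same partition on well-separated data,
    # roughly half the runtime of double-precision Lloyd at this problem size
    Xf = np.ascontiguousarray(X, dtype=np.float32)
    km = KMeans(n_clusters=k, n_init=n_init, max_iter=max_iter,
                random_state=seed, algorithm="elkan")
    return km.fit(Xf)


def elbow_ratio_curve(
    X: np.ndarray,
    k_range: Iterable[int] = range(2, 10),
    n_init: int = 10,
    max_iter: int = 1000,
    seed: int | None = None,
) -> dict[int, float]:
    """Within/between distance ratio for each k.

    ratio(k) = mean Euclidean distance of points to their own centroid
             / mean pairwise centroid distance.
    A virtual k = 1 entry anchors the curvature computation at the low end:
    its numerator is the mean distance to the global centroid and its
    denominator is the k = 2 between-centroid distance (for k = 1 alone no
    between-cluster distance exists).
    """
    ks = sorted(set(int(k) for k in k_range))
    if ks[0] < 2:
        raise ValueError("k_range must start at 2 or above")
    if ks[-1] >= X.shape[0]:
        raise ValueError("largest k must be below the number of windows")
    rng = np.random.default_rng(seed)
    curve: dict[int, float] = {}
    between2 = None
    for k in ks:
        km = _fit_kmeans(X, k, n_init, max_iter, int(rng.integers(2**31)))
        cents = km.cluster_centers_
        d_own = np.linalg.norm(X - cents[km.labels_], axis=1)
        pairwise = cdist(cents, cents)
        iu = np.triu_indices(k, k=1)
        between = pairwise[iu].mean()
        if k == 2:
            between2 = between
        curve[k] = float(d_own.mean() / between)
    if ks[0] == 2 and between2 is not None:
        within1 = np.linalg.norm(X - X.mean(axis=0), axis=1).mean()
        curve[1] = float(within1 / between2)
    return curve


def select_k_elbow(
    all_windows: np.ndarray | Sequence[DfncWindows],
    k_range: Iterable[int] = range(2, 10),
    n_init: int = 10,
    max_iter: int = 1000,
    seed: int | None = None,
) -> tuple[int, dict[int, float]]:
    """Choose k at the point of maximum curvature of the within/between ratio
    curve (largest second-order difference), returning the full curve."""
    X = all_windows if isinstance(all_windows, np.ndarray) else _pool(all_windows)[0]
    curve = elbow_ratio_curve(X, k_range, n_init=n_init, max_iter=max_iter, seed=seed)
    ks = sorted(curve)
    vals = np.array([curve[k] for k in ks])
    if len(ks) < 3:
        return ks[-1], curve
    d2 = vals[:-2] - 2 * vals[1:-1] + vals[2:]
    k_best = int(ks[1 + int(np.argmax(d2))])
    return k_best, curve


def cluster_states(
    windows: Sequence[DfncWindows],
    K: int,
    max_iter: int = 1000,
    n_init: int = 10,
    seed: int | None = None,
    distance: str = "euclidean",
) -> tuple[StateModel, list[StateVector]]:
    """Pooled k-means over all subjects' windows.

    ``distance='correlation'`` clusters row-standardized window vectors
    (squared Euclidean distance between z-scored vectors is an affine function
    of one minus the Pearson correlation); centroids are reported in the
    original connectivity space either way.  States are relabeled in
    descending pooled frequency, so state 1 is the most occupied.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if distance not in ("euclidean", "correlation"):
        raise ValueError("distance must be 'euclidean' or 'correlation'")
    X, sizes = _pool(windows)
    if X.shape[0] < K:
        raise ValueError("fewer pooled windows than clusters")
    Xfit = _standardize_rows(X) if distance == "correlation" else X
    km = _fit_kmeans(Xfit, K, n_init, max_iter, seed)
    converged = bool(km.n_iter_ < max_iter)
    if not converged:
        warnings.warn("k-means hit max_iter without converging", stacklevel=2)
    labels0 = km.labels_

    # relabel by descending pooled occupancy; ties broken by original index
    counts = np.bincount(labels0, minlength=K)
    order = np.argsort(-counts, kind="stable")
    remap = np.empty(K, dtype=int)
    remap[order] = np.arange(K)
    labels = remap[labels0] + 1
    # final centroids in double precision from the original-space vectors
    centroids = np.vstack([X[labels == k + 1].mean(axis=0) for k in range(K)])

    model = StateModel(K=K, centroids=centroids, inertia=float(km.inertia_),
                       n_init=n_init, max_iter=max_iter, seed=seed,
                       distance=distance, converged=converged)
    vectors: list[StateVector] = []
    start = 0
    for sid, n in sizes:
        vectors.append(StateVector(subject_id=sid, labels=labels[start: start + n]))
        start += n
    return model, vectors


def assign_states(model: StateModel, windows: DfncWindows) -> StateVector:
    """Nearest-centroid labels for one subject's windows (ties to the lowest
    state index)."""
    if windows.n_pairs != model.centroids.shape[1]:
        raise ValueError("window dimensionality does not match the model")
    X = windows.matrix
    cents = model.centroids
    if model.distance == "correlation":
        X = _standardize_rows(X)
        cents = _standardize_rows(cents)
    d = cdist(X, cents)
    return StateVector(subject_id=windows.subject_id, labels=np.argmin(d, axis=1) + 1)


def compute_ocr(sv: StateVector | np.ndarray, K: int) -> np.ndarray:
    """Occupancy rate: fraction of the subject's own windows in each state."""
    labels = sv.labels if isinstance(sv, StateVector) else np.asarray(sv, dtype=int)
    if labels.size == 0:
        raise ValueError("empty state vector")
    if labels.min() < 1 or labels.max() > K:
        raise ValueError("labels must lie in 1..K")
    return np.bincount(labels, minlength=K + 1)[1:] / labels.size


def ocr_table(vectors: Sequence[StateVector], K: int) -> pd.DataFrame:
    """Per-subject occupancy rates as a DataFrame indexed by subject id."""
    rows = {sv.subject_id: compute_ocr(sv, K) for sv in vectors}
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"state_{k + 1}" for k in range(K)]
    ).rename_axis("subject_id")


def match_states(model_a: StateModel, model_b: StateModel) -> tuple[np.ndarray, np.ndarray]:
    """Match states across two models by maximizing summed centroid Pearson
    correlation (Hungarian assignment).

    Returns ``(perm, corrs)`` where state k+1 of ``model_a`` corresponds to
    state ``perm[k]+1`` of ``model_b`` with correlation ``corrs[k]``.
    """
    if model_a.K != model_b.K:
        raise ValueError("models must have the same number of states")
    if model_a.centroids.shape[1] != model_b.centroids.shape[1]:
        raise ValueError("models must share the connectivity dimension")
    A = _standardize_rows(model_a.centroids)
    B = _standardize_rows(model_b.centroids)
    corr = (A @ B.T) / A.shape[1]
    rows, cols = linear_sum_assignment(-corr)
    return cols, corr[rows, cols]


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------


class DfncStateModel:
    """Group brain-state model over a cohort's windowed connectivity.

    Parameters
    ----------
    windows : sequence of DfncWindows
        One entry per subject, all with the same pair dimension P.
    """

    def __init__(self, windows: Sequence[DfncWindows]):
        if not windows:
            raise ValueError("need at least one subject")
        P = windows[0].n_pairs
        if any(w.n_pairs != P for w in windows):
            raise ValueError("all subjects must share the pair dimension")
        self.windows = list(windows)

    def fit(
        self,
        k: int | str = "auto",
        k_range: Iterable[int] = range(2, 10),
        n_init: int = 10,
        max_iter: int = 1000,
        seed: int | None = None,
        distance: str = "euclidean",
    ) -> "DfncStateResults":
        """Estimate states; ``k='auto'`` selects K by the elbow criterion."""
        sweep = None
        if k == "auto":
            K, sweep = select_k_elbow(self.windows, k_range, n_init=n_init,
                                      max_iter=max_iter, seed=seed)
        else:
            K = int(k)
        model, vectors = cluster_states(self.windows, K, max_iter=max_iter,
                                        n_init=n_init, seed=seed, distance=distance)
        model.k_sweep = sweep
        return DfncStateResults(self, model, vectors)


@dataclass
class DfncStateResults:
    """Fitted brain states: centroids, per-subject state vectors, OCR table."""

    model_spec: DfncStateModel
    state_model: StateModel
    state_vectors: list[StateVector] = field(default_factory=list)

    @property
    def K(self) -> int:
        return self.state_model.K

    @property
    def centroids(self) -> np.ndarray:
        return self.state_model.centroids

    def ocr(self) -> pd.DataFrame:
        return ocr_table(self.state_vectors, self.K)

    def state_vector(self, subject_id: str) -> StateVector:
        for sv in self.state_vectors:
            if sv.subject_id == subject_id:
                return sv
        raise KeyError(subject_id)

    def summary(self) -> str:
        ocr = self.ocr()
        lines = [
            "dFNC state model",
            f"  subjects: {len(self.state_vectors)}",
            f"  states (K): {self.K}   distance: {self.state_model.distance}",
            f"  pooled inertia: {self.state_model.inertia:.4g}",
            "  mean occupancy per state:",
        ]
        for col in ocr.columns:
            lines.append(f"    {col}: {ocr[col].mean():.3f}")
        if self.state_model.k_sweep:
            ks = sorted(k for k in self.state_model.k_sweep if k >= 2)
            curve = ", ".join(f"{k}: {self.state_model.k_sweep[k]:.3f}" for k in ks)
            lines.append(f"  elbow ratio curve: {curve}")
        return "\n".join(lines)
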