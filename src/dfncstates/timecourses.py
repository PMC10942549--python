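"""Core container for post-ICA component timecourses.

A subject's data enters the pipeline as a T x C matrix of independent-component
activity sampled every TR seconds.  Everything downstream (cleaning, windowed
connectivity, state clustering) operates on this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass(frozen=True)
class ComponentTimecourses:
    """One subject's component timecourse matrix.

    Parameters
    ----------
    subject_id : str
        Unique subject identifier.
    data : ndarray of shape (T, C)
        Component activity, one column per independent component.
    tr : float
        Repetition time in seconds (sampling interval).
    component_ids : tuple of str, optional
        Column labels; defaults to ``IC01 .. ICxx``.
    """

    subject_id: str
    data: np.ndarray
    tr: float
    component_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2 or data.shape[0] < 1 or data.shape[1] < 1:
            raise ValueError("data must be a T x C matrix with T, C >= 1")
        if not self.tr > 0:
            raise ValueError("tr must be positive")
        object.__setattr__(self, "data", data)
        if not self.component_ids:
            width = max(2, len(str(data.shape[1])))
            ids = tuple(f"IC{i + 1:0{width}d}" for i in range(data.shape[1]))
            object.__setattr__(self, "component_ids", ids)
        elif len(self.component_ids) != data.shape[1]:
            raise ValueError("component_ids length must equal number of columns")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_components(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "ComponentTimecourses":
        """Return a copy with the data matrix replaced (shape must be preserved)."""
        data = np.asarray(data, dtype=float)
        if data.shape != self.data.shape:
            raise ValueError("stage must preserve the matrix shape")
        return replace(self, data=data)
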