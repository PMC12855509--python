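"""Core container for regional activity time series.

A :class:`RegionalTimeSeries` holds a regions x timepoints signal matrix
together with its sampling interval (TR, in seconds). It is the raw input
of the whole pipeline: windowed connectivity, surrogate generation and the
synthetic generator all produce or consume this type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RegionalTimeSeries"]


@dataclass
class RegionalTimeSeries:
    """Multivariate signal: one row per region, one column per timepoint.

    Parameters
    ----------
    values
        Real matrix of shape ``(n_regions, n_timepoints)``. Must be finite.
    tr_seconds
        Sampling interval (repetition time) in seconds; must be positive.
    region_labels
        Optional region names; defaults to ``r000, r001, ...``.
    """

    values: np.ndarray
    tr_seconds: float
    region_labels: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(
                f"values must be 2-D (regions x timepoints), got ndim={self.values.ndim}"
            )
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 timepoints")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(f"non-finite value at region {bad[0]}, timepoint {bad[1]}")
        if not self.tr_seconds > 0:
            raise ValueError(f"tr_seconds must be positive, got {self.tr_seconds}")
        if self.region_labels is None:
            self.region_labels = [f"r{i:03d}" for i in range(self.values.shape[0])]
        if len(self.region_labels) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.region_labels)} labels for {self.values.shape[0]} regions"
            )

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    @property
    def duration_seconds(self) -> float:
        """Total scan duration, ``n_timepoints * tr_seconds``."""
        return self.n_timepoints * self.tr_seconds
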