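"""Sliding-window signed connectivity.

Builds the time-resolved signed network from a regional time series:
within each window of ``window_length`` timepoints (advancing by ``step``),
the n x n Pearson correlation matrix of the windowed segments, with both
positive and negative correlations preserved and the diagonal stored as
zero (self-edges are not triad edges). Concatenated runs can optionally be
windowed separately via ``run_boundaries``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .timeseries import RegionalTimeSeries

__all__ = [
    "WindowParams",
    "DynamicNetwork",
    "window_count",
    "sliding_window_connectivity",
]


@dataclass(frozen=True)
class WindowParams:
    """Sliding-window geometry.

    ``run_boundaries``, when given, lists the start index of each
    concatenated run (first entry 0, strictly increasing); windows are then
    confined within runs instead of spanning their joints.
    """

    window_length: int
    step: int = 1
    run_boundaries: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.window_length < 3:
            raise ValueError("window_length must be >= 3")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.run_boundaries is not None:
            b = tuple(int(x) for x in self.run_boundaries)
            if not b or b[0] != 0:
                raise ValueError("run_boundaries must start at 0")
            if any(y <= x for x, y in zip(b, b[1:])):
                raise ValueError("run_boundaries must be strictly increasing")
            object.__setattr__(self, "run_boundaries", b)

    def duration_seconds(self, tr_seconds: float) -> float:
        """Window span in seconds (e.g. 50 timepoints at TR 0.72 s = 36 s)."""
        return self.window_length * tr_seconds


@dataclass
class DynamicNetwork:
    """Time-ordered sequence of symmetric signed weight matrices."""

    weights: np.ndarray  # (T, n, n), zero diagonal
    window_starts: np.ndarray
    params: WindowParams
    tr_seconds: float
    region_labels: list[str] | None = None
    degenerate_entries: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_windows(self) -> int:
        return self.weights.shape[0]

    @property
    def n_regions(self) -> int:
        return self.weights.shape[1]


def _run_spans(n_timepoints: int, params: WindowParams) -> list[tuple[int, int]]:
    if params.run_boundaries is None:
        return [(0, n_timepoints)]
    b = list(params.run_boundaries)
    if b[-1] >= n_timepoints:
        raise ValueError("run boundary beyond series length")
    return list(zip(b, b[1:] + [n_timepoints]))


def window_count(n_timepoints: int, params: WindowParams) -> int:
    """Number of windows: ``floor((N - w)/step) + 1`` per run, summed."""
    if n_timepoints < params.window_length:
        raise ValueError(
            f"series of {n_timepoints} timepoints shorter than window "
            f"({params.window_length})"
        )
    total = 0
    for a, b in _run_spans(n_timepoints, params):
        length = b - a
        if length < params.window_length:
            raise ValueError(
                f"run [{a}, {b}) shorter than window ({params.window_length})"
            )
        total += (length - params.window_length) // params.step + 1
    return total


def _window_starts(n_timepoints: int, params: WindowParams) -> np.ndarray:
    starts = []
    for a, b in _run_spans(n_timepoints, params):
        if b - a < params.window_length:
            raise ValueError(
                f"run [{a}, {b}) shorter than window ({params.window_length})"
            )
        starts.extend(range(a, b - params.window_length + 1, params.step))
    return np.asarray(starts, dtype=np.int64)


def sliding_window_connectivity(
    ts: RegionalTimeSeries,
    params: WindowParams,
    on_degenerate: str = "error",
) -> DynamicNetwork:
    """Windowed Pearson correlation network.

    A region that is constant within some window has an undefined
    correlation there; by default this fails with an error naming the
    window and region. With ``on_degenerate='zero'`` the affected entries
    are set to 0 and flagged in ``DynamicNetwork.degenerate_entries``.
    """
    if on_degenerate not in ("error", "zero"):
        raise ValueError("on_degenerate must be 'error' or 'zero'")
    if ts.n_timepoints < params.window_length:
        raise ValueError(
            f"series of {ts.n_timepoints} timepoints shorter than window "
            f"({params.window_length})"
        )
    starts = _window_starts(ts.n_timepoints, params)
    n = ts.n_regions
    w = params.window_length
    weights = np.empty((starts.size, n, n))
    degenerate: list[tuple[int, int]] = []

    for t, s in enumerate(starts):
        seg = ts.values[:, s : s + w]
        sd = seg.std(axis=1)
        bad = np.flatnonzero(sd == 0.0)
        if bad.size:
            if on_degenerate == "error":
                raise ValueError(
                    f"zero-variance region {bad[0]} in window {t} "
                    f"(timepoints {s}..{s + w - 1}); correlation undefined"
                )
            degenerate.extend((t, int(r)) for r in bad)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.corrcoef(seg)
        if bad.size:
            c[bad, :] = 0.0
            c[:, bad] = 0.0
        np.clip(c, -1.0, 1.0, out=c)
        c = (c + c.T) / 2.0
        np.fill_diagonal(c, 0.0)
        weights[t] = c

    return DynamicNetwork(
        weights=weights,
        window_starts=starts,
        params=params,
        tr_seconds=ts.tr_seconds,
        region_labels=list(ts.region_labels),
        degenerate_entries=degenerate,
    )
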