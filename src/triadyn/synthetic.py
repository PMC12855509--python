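"""Synthetic signed-network time series with known ground truth.

The generator emulates the statistical features of regional resting-state
signals that the downstream analysis depends on: temporal autocorrelation
(first-order autoregressive filtering), a signed cross-correlation structure
(positively correlated blocks of regions, anti-correlated across blocks), and
piecewise-stationary covariance regimes whose switches produce triad-state
transitions. It does not attempt hemodynamic realism; see docs/methods.md.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .timeseries import RegionalTimeSeries
from .triads import TriadState

__all__ = [
    "RegimeSpec",
    "SyntheticConfig",
    "StateTrack",
    "make_block_covariance",
    "generate_series",
    "make_state_fixture",
]

_SYM_TOL = 1e-10
_EIG_TOL = -1e-10


@dataclass
class RegimeSpec:
    """One stationary segment: duration plus a correlation matrix.

    The covariance must be a valid correlation matrix (symmetric, unit
    diagonal, PSD up to ``-1e-10`` before repair).
    """

    duration_timepoints: int
    covariance: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        if self.duration_timepoints < 1:
            raise ValueError("duration_timepoints must be >= 1")
        c = np.asarray(self.covariance, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("covariance must be square")
        if np.max(np.abs(c - c.T)) > _SYM_TOL:
            raise ValueError("covariance not symmetric within 1e-10")
        if np.max(np.abs(np.diag(c) - 1.0)) > _SYM_TOL:
            raise ValueError("covariance diagonal must be 1")
        if np.linalg.eigvalsh(c).min() < _EIG_TOL:
            raise ValueError("covariance not PSD (min eigenvalue < -1e-10)")
        self.covariance = c

    @property
    def n_regions(self) -> int:
        return self.covariance.shape[0]


@dataclass
class SyntheticConfig:
    """Full recipe for one synthetic subject."""

    n_regions: int
    regimes: list[RegimeSpec]
    ar_coefficient: float = 0.0
    tr_seconds: float = 0.72
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 1:
            raise ValueError("n_regions must be positive")
        if not self.regimes:
            raise ValueError("need at least one regime")
        for r in self.regimes:
            if r.n_regions != self.n_regions:
                raise ValueError(
                    f"regime '{r.label}' has {r.n_regions} regions, expected {self.n_regions}"
                )
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise ValueError("ar_coefficient must lie in [0, 1)")
        if not self.tr_seconds > 0:
            raise ValueError("tr_seconds must be positive")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")

    @property
    def total_timepoints(self) -> int:
        return sum(r.duration_timepoints for r in self.regimes)


def make_block_covariance(
    n_regions: int,
    block_sizes: list[int],
    within_r: float,
    between_r: float = 0.0,
    full_output: bool = False,
):
    """Block correlation matrix: ``within_r`` inside blocks, ``between_r`` across.

    The raw matrix is repaired to positive semidefiniteness by clipping
    negative eigenvalues at zero and re-normalizing to unit diagonal.

    Returns the matrix, or ``(matrix, info)`` with ``info['repaired']`` /
    ``info['max_change']`` when ``full_output`` is true.
    """
    if sum(block_sizes) != n_regions:
        raise ValueError(f"block sizes {block_sizes} do not sum to {n_regions}")
    if any(b < 1 for b in block_sizes):
        raise ValueError("block sizes must be positive")
    if not abs(within_r) < 1 or not abs(between_r) < 1:
        raise ValueError("within_r and between_r must lie strictly inside (-1, 1)")

    block_of = np.repeat(np.arange(len(block_sizes)), block_sizes)
    same = block_of[:, None] == block_of[None, :]
    raw = np.where(same, within_r, between_r).astype(float)
    np.fill_diagonal(raw, 1.0)

    w, v = np.linalg.eigh(raw)
    cov = (v * np.clip(w, 0.0, None)) @ v.T
    d = np.sqrt(np.clip(np.diag(cov), np.finfo(float).tiny, None))
    cov = cov / np.outer(d, d)
    cov = (cov + cov.T) / 2.0
    np.fill_diagonal(cov, 1.0)

    max_change = float(np.max(np.abs(cov - raw)))
    info = {"repaired": max_change > 1e-6, "max_change": max_change}
    if full_output:
        return cov, info
    return cov


def generate_series(config: SyntheticConfig) -> RegionalTimeSeries:
    """Draw a piecewise-stationary Gaussian AR(1) series.

    Within each regime, innovations are mixed through the symmetric square
    root of the regime correlation matrix; the AR(1) filter then runs over
    the whole concatenated series (state carried across regime boundaries),
    so regime switches change covariance, not variance. The output is
    standardized per region to mean 0, unit sample variance over the full
    series. Deterministic given ``config.seed``: each region draws its
    innovations from its own spawned substream.
    """
    T = config.total_timepoints
    if T < 2:
        raise ValueError("total duration must be at least 2 timepoints")
    if T < 100:
        warnings.warn(
            f"total duration {T} is short (< 2x a typical 50-timepoint window); "
            "windowed analyses may be unreliable",
            stacklevel=2,
        )

    children = np.random.SeedSequence(config.seed).spawn(config.n_regions)
    z = np.vstack(
        [np.random.default_rng(c).standard_normal(T) for c in children]
    )

    x = np.empty_like(z)
    t0 = 0
    for regime in config.regimes:
        t1 = t0 + regime.duration_timepoints
        w, v = np.linalg.eigh(regime.covariance)
        root = (v * np.sqrt(np.clip(w, 0.0, None))) @ v.T
        x[:, t0:t1] = root @ z[:, t0:t1]
        t0 = t1

    a = config.ar_coefficient
    if a > 0.0:
        x = lfilter([1.0], [1.0, -a], x, axis=1)

    x = x - x.mean(axis=1, keepdims=True)
    x = x / x.std(axis=1, ddof=1, keepdims=True)
    return RegionalTimeSeries(values=x, tr_seconds=config.tr_seconds)


@dataclass
class StateTrack:
    """Prefabricated per-window (state, energy) track for a single triangle.

    An oracle input for episode extraction that bypasses the connectivity
    stage entirely.
    """

    states: list[TriadState]
    energies: np.ndarray

    @property
    def n_windows(self) -> int:
        return len(self.states)


def make_state_fixture(
    state_sequence: list[TriadState | str], energies: list[float]
) -> StateTrack:
    """Build a :class:`StateTrack`, enforcing sign consistency.

    Balanced states must carry energy <= 0, imbalanced states energy >= 0
    (the energy sign convention: negative = balanced).
    """
    if len(state_sequence) == 0:
        raise ValueError("empty state sequence")
    if len(state_sequence) != len(energies):
        raise ValueError(
            f"{len(state_sequence)} states but {len(energies)} energies"
        )
    states = [
        s if isinstance(s, TriadState) else TriadState.from_symbol(s)
        for s in state_sequence
    ]
    e = np.asarray(energies, dtype=float)
    for t, (s, ei) in enumerate(zip(states, e)):
        if s.is_balanced and ei > 0:
            raise ValueError(
                f"window {t}: balanced state {s.symbol} with positive energy {ei}"
            )
        if not s.is_balanced and ei < 0:
            raise ValueError(
                f"window {t}: imbalanced state {s.symbol} with negative energy {ei}"
            )
    return StateTrack(states=states, energies=e)
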