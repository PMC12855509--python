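"""Signed triads: classification, energy, and lifetime/peak-energy episodes.

Every triangle of regions carries three signed edge weights. The sign
pattern assigns one of four configurations — +++, +-+, -+-, --- — grouped
by (strong) structural balance into balanced (+++, -+-; sign product
positive) and imbalanced (+-+, ---) classes. The triad energy

    E = -cbrt(w_ij * w_ik * w_jk)

is negative for balanced and positive for imbalanced triads, bounded in
[-1, 1] for correlation weights; the signed cube root keeps it dimensionless
and comparable across triangles. Tracking each triangle across sliding
windows yields *episodes*: maximal runs in one configuration, summarized by
their lifetime (windows) and absolute peak energy (max |E| during the run).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum
from typing import Iterator, Sequence

import numpy as np

from .windows import DynamicNetwork

__all__ = [
    "TriadState",
    "EpisodeRecord",
    "SubjectSummary",
    "enumerate_triangles",
    "classify_triad",
    "triad_energy",
    "extract_episodes",
    "iter_triangle_episodes",
    "subject_summary",
]


class TriadState(Enum):
    """One of the four signed triadic configurations.

    The code names encode the sorted sign multiset: ``PPP`` = +++,
    ``PNP`` = +-+ (one negative), ``NPN`` = -+- (two negatives),
    ``NNN`` = ---. Balanced states (positive sign product) are ``PPP``
    and ``NPN``; under strong balance, ``NNN`` counts as imbalanced.
    """

    PPP = ("+++", 0)
    PNP = ("+-+", 1)
    NPN = ("-+-", 2)
    NNN = ("---", 3)

    def __init__(self, symbol: str, index: int) -> None:
        self.symbol = symbol
        self.index = index

    @property
    def n_negative(self) -> int:
        return self.index

    @property
    def is_balanced(self) -> bool:
        return self.index % 2 == 0

    @classmethod
    def from_symbol(cls, symbol: str) -> "TriadState":
        for s in cls:
            if s.symbol == symbol:
                return s
        raise ValueError(f"unknown triad state symbol {symbol!r}")

    @classmethod
    def from_n_negative(cls, n: int) -> "TriadState":
        return _STATES[n]


_STATES = (TriadState.PPP, TriadState.PNP, TriadState.NPN, TriadState.NNN)

#: Canonical state ordering used for 4x4 matrices throughout the package.
STATE_ORDER = _STATES


@dataclass
class EpisodeRecord:
    """One maximal run of a triangle in a single triadic configuration."""

    triangle: tuple[int, int, int]
    state: TriadState
    start_window: int
    lifetime: int
    abs_peak_energy: float
    left_censored: bool
    right_censored: bool


@dataclass
class SubjectSummary:
    """Per-subject aggregate over all triangles and windows.

    ``mean_lifetime`` and ``mean_abs_peak_energy`` are episode-weighted
    means per state (``None`` when a state produced no episodes).
    ``occurrence`` counts (triangle, window) pairs per state; these always
    partition ``n_triangles * n_windows``. ``transition_counts`` is a 4x4
    matrix in :data:`STATE_ORDER` (rows = from, zero diagonal).
    """

    mean_lifetime: dict[TriadState, float | None]
    mean_abs_peak_energy: dict[TriadState, float | None]
    episode_counts: dict[TriadState, int]
    occurrence: dict[TriadState, float]
    transition_counts: np.ndarray
    n_triangles: int
    n_windows: int
    subject_id: str | None = None
    realization_counts: dict[TriadState, int] | None = None

    def balance_gap(self, metric: str = "mean_lifetime") -> float:
        """mean(balanced-state means) - mean(imbalanced-state means).

        Raises if any of the four states is missing.
        """
        values = getattr(self, metric)
        for s in STATE_ORDER:
            if values[s] is None:
                raise ValueError(f"state {s.symbol} has no episodes; gap undefined")
        bal = np.mean([values[s] for s in STATE_ORDER if s.is_balanced])
        imb = np.mean([values[s] for s in STATE_ORDER if not s.is_balanced])
        return float(bal - imb)


def enumerate_triangles(n_regions: int) -> list[tuple[int, int, int]]:
    """All C(n, 3) node triples (i < j < k), lexicographically ordered."""
    if n_regions < 3:
        raise ValueError(f"need at least 3 regions, got {n_regions}")
    return list(itertools.combinations(range(n_regions), 3))


def classify_triad(w_ij: float, w_ik: float, w_jk: float) -> TriadState:
    """Classify a triangle by the multiset of its edge signs.

    Exact zeros are treated as positive (a measure-zero event for
    continuous correlation weights; documented convention).
    """
    w = np.asarray([w_ij, w_ik, w_jk], dtype=float)
    if not np.all(np.isfinite(w)):
        raise ValueError(f"non-finite edge weight in {w}")
    return _STATES[int(np.sum(w < 0))]


_W_TOL = 1e-9  # slack for correlation round-off at +/-1


def triad_energy(w_ij: float, w_ik: float, w_jk: float) -> float:
    """Triad energy ``-cbrt(w_ij * w_ik * w_jk)`` with a signed cube root.

    Weights must be correlations in [-1, 1]. Negative energy marks balanced
    configurations, positive marks imbalanced ones; zero occurs iff an edge
    weight is exactly zero.
    """
    w = np.asarray([w_ij, w_ik, w_jk], dtype=float)
    if not np.all(np.isfinite(w)):
        raise ValueError(f"non-finite edge weight in {w}")
    if np.any(np.abs(w) > 1.0 + _W_TOL):
        raise ValueError(f"edge weights must lie in [-1, 1], got {w}")
    return float(-np.cbrt(w[0] * w[1] * w[2]))


def extract_episodes(
    state_track: Sequence[TriadState],
    energy_track: Sequence[float],
    triangle: tuple[int, int, int] = (0, 1, 2),
) -> list[EpisodeRecord]:
    """Split per-window tracks into maximal same-state runs.

    Lifetimes sum to the track length; each episode's ``abs_peak_energy``
    is the max |energy| over its windows. The first episode is flagged
    left-censored and the last right-censored (their true lifetimes are
    truncated by the observation window).
    """
    states = list(state_track)
    energies = np.asarray(energy_track, dtype=float)
    if len(states) == 0:
        raise ValueError("empty state track")
    if len(states) != energies.shape[0]:
        raise ValueError(
            f"{len(states)} states but {energies.shape[0]} energies"
        )
    codes = np.fromiter((s.index for s in states), dtype=np.int8, count=len(states))
    return _episodes_from_codes(codes, energies, triangle)


def _episodes_from_codes(
    codes: np.ndarray, energies: np.ndarray, triangle: tuple[int, int, int]
) -> list[EpisodeRecord]:
    T = codes.shape[0]
    starts = np.concatenate(([0], np.flatnonzero(codes[1:] != codes[:-1]) + 1))
    ends = np.concatenate((starts[1:], [T]))
    peaks = np.maximum.reduceat(np.abs(energies), starts)
    records = []
    for idx, (a, b) in enumerate(zip(starts, ends)):
        records.append(
            EpisodeRecord(
                triangle=triangle,
                state=_STATES[codes[a]],
                start_window=int(a),
                lifetime=int(b - a),
                abs_peak_energy=float(peaks[idx]),
                left_censored=idx == 0,
                right_censored=idx == len(starts) - 1,
            )
        )
    return records


def _triangle_tracks(
    weights: np.ndarray, i: int, j: int, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window (state codes, energies) for one triangle, vectorized over windows."""
    wij = weights[:, i, j]
    wik = weights[:, i, k]
    wjk = weights[:, j, k]
    codes = ((wij < 0).astype(np.int8) + (wik < 0) + (wjk < 0)).astype(np.int8)
    energies = -np.cbrt(wij * wik * wjk)
    return codes, energies


def iter_triangle_episodes(
    dyn: DynamicNetwork,
) -> Iterator[tuple[tuple[int, int, int], list[EpisodeRecord]]]:
    """Yield ``(triangle, episodes)`` for every triangle, one at a time.

    Streams triangle-by-triangle so no more than one triangle's tracks are
    ever materialized (the full census of a 50-region network is 19,600
    triangles; holding all tracks at once would be needlessly large).
    """
    n = dyn.n_regions
    for tri in enumerate_triangles(n):
        codes, energies = _triangle_tracks(dyn.weights, *tri)
        yield tri, _episodes_from_codes(codes, energies, tri)


def subject_summary(
    dyn: DynamicNetwork,
    include_censored: bool = True,
    subject_id: str | None = None,
) -> SubjectSummary:
    """Aggregate episodes over all triangles into a :class:`SubjectSummary`.

    Means are episode-weighted (each episode counts once, regardless of
    which triangle produced it). When ``include_censored`` is false,
    boundary-truncated episodes are excluded from the lifetime and
    peak-energy means; occurrence and transition counts always use the
    complete partition of (triangle, window) pairs.
    """
    from .dynamics import count_transitions  # local import avoids a cycle

    life_sum = np.zeros(4)
    life_n = np.zeros(4, dtype=np.int64)
    peak_sum = np.zeros(4)
    occ = np.zeros(4, dtype=np.int64)
    ep_counts = np.zeros(4, dtype=np.int64)
    seqs: list[np.ndarray] = []

    for _tri, episodes in iter_triangle_episodes(dyn):
        seq = np.fromiter((e.state.index for e in episodes), dtype=np.int8)
        seqs.append(seq)
        for e in episodes:
            s = e.state.index
            occ[s] += e.lifetime
            ep_counts[s] += 1
            if include_censored or not (e.left_censored or e.right_censored):
                life_sum[s] += e.lifetime
                peak_sum[s] += e.abs_peak_energy
                life_n[s] += 1

    trans = count_transitions(seqs)
    mean_life: dict[TriadState, float | None] = {}
    mean_peak: dict[TriadState, float | None] = {}
    for s in _STATES:
        idx = s.index
        if life_n[idx] > 0:
            mean_life[s] = float(life_sum[idx] / life_n[idx])
            mean_peak[s] = float(peak_sum[idx] / life_n[idx])
        else:
            mean_life[s] = None
            mean_peak[s] = None

    return SubjectSummary(
        mean_lifetime=mean_life,
        mean_abs_peak_energy=mean_peak,
        episode_counts={s: int(ep_counts[s.index]) for s in _STATES},
        occurrence={s: int(occ[s.index]) for s in _STATES},
        transition_counts=trans,
        n_triangles=len(enumerate_triangles(dyn.n_regions)),
        n_windows=dyn.n_windows,
        subject_id=subject_id,
    )
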