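"""Occurrence distribution and transition dynamics of triadic states.

A triangle that leaves one configuration enters another; counting these
adjacent-episode pairs over all triangles yields a 4x4 directed transition
count matrix (zero diagonal by construction, since episodes are maximal
runs). Occurrence — how often each state appears over all (triangle,
window) pairs — decomposes exactly as the sum of episode lifetimes, which
ties prevalence to the interplay of dwell time and transition inflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .triads import STATE_ORDER, EpisodeRecord, SubjectSummary, TriadState

__all__ = [
    "TransitionMatrix",
    "count_transitions",
    "transition_matrix",
    "occurrence_distribution",
    "inflow_outflow",
    "group_occurrence",
    "group_transition_proportions",
]


@dataclass
class TransitionMatrix:
    """Directed state-change counts in :data:`STATE_ORDER` (rows = from)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (4, 4):
            raise ValueError("transition matrix must be 4x4")
        if np.any(c < 0):
            raise ValueError("negative transition count")
        if np.any(np.diag(c) != 0):
            raise ValueError("transition matrix diagonal must be zero")
        self.counts = c.astype(np.int64)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def proportions(self) -> np.ndarray:
        """Globally normalized: all entries sum to 1 (zeros if no transitions)."""
        t = self.total
        return self.counts / t if t > 0 else np.zeros((4, 4))

    @property
    def row_proportions(self) -> np.ndarray:
        """Outflow-normalized: each row sums to 1 (zero rows stay zero)."""
        rows = self.counts.sum(axis=1, keepdims=True).astype(float)
        out = np.divide(
            self.counts, rows, out=np.zeros((4, 4)), where=rows > 0
        )
        return out


def count_transitions(state_sequences: Iterable[Sequence[int]]) -> np.ndarray:
    """4x4 counts of adjacent state pairs over many per-triangle sequences.

    Each sequence lists the episode state indices of one triangle in
    temporal order (consecutive entries always differ, since episodes are
    maximal runs).
    """
    counts = np.zeros((4, 4), dtype=np.int64)
    for seq in state_sequences:
        s = np.asarray(seq, dtype=np.int64)
        if s.size < 2:
            continue
        np.add.at(counts, (s[:-1], s[1:]), 1)
    if np.any(np.diag(counts) != 0):
        raise ValueError("self-transition found: episodes were not maximal runs")
    return counts


def transition_matrix(
    episode_lists: Iterable[Sequence[EpisodeRecord]],
) -> TransitionMatrix:
    """Build the transition matrix from per-triangle episode lists.

    Episodes must be in temporal order within each triangle; the total
    count equals the sum over triangles of (n_episodes - 1).
    """
    seqs = []
    for episodes in episode_lists:
        starts = [e.start_window for e in episodes]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("episodes out of temporal order")
        seqs.append([e.state.index for e in episodes])
    return TransitionMatrix(counts=count_transitions(seqs))


def occurrence_distribution(summary: SubjectSummary) -> dict[TriadState, float]:
    """Occurrence counts normalized to proportions summing to 1."""
    total = sum(summary.occurrence[s] for s in STATE_ORDER)
    if total <= 0:
        raise ValueError("summary has no occurrences")
    return {s: summary.occurrence[s] / total for s in STATE_ORDER}


def inflow_outflow(
    tm: TransitionMatrix,
) -> tuple[dict[TriadState, int], dict[TriadState, int]]:
    """Per-state (inflow, outflow) totals: column sums and row sums."""
    inflow = tm.counts.sum(axis=0)
    outflow = tm.counts.sum(axis=1)
    return (
        {s: int(inflow[s.index]) for s in STATE_ORDER},
        {s: int(outflow[s.index]) for s in STATE_ORDER},
    )


def group_occurrence(
    summaries: Sequence[SubjectSummary],
) -> dict[TriadState, float]:
    """Mean of per-subject occurrence proportions (subjects weigh equally)."""
    if not summaries:
        raise ValueError("no summaries")
    props = np.array(
        [[occurrence_distribution(sm)[s] for s in STATE_ORDER] for sm in summaries]
    )
    mean = props.mean(axis=0)
    return {s: float(mean[s.index]) for s in STATE_ORDER}


def group_transition_proportions(
    summaries: Sequence[SubjectSummary], row_normalized: bool = False
) -> np.ndarray:
    """Mean of per-subject transition proportion matrices.

    Averaging proportions rather than pooling counts keeps subjects with
    many transitions from dominating the group matrix.
    """
    if not summaries:
        raise ValueError("no summaries")
    mats = []
    for sm in summaries:
        tm = TransitionMatrix(counts=sm.transition_counts)
        mats.append(tm.row_proportions if row_normalized else tm.proportions)
    return np.mean(mats, axis=0)
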