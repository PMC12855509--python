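"""Phase-randomized surrogate time series and surrogate-based null summaries.

Classic Theiler-style phase randomization: each region's signal is taken to
the frequency domain, the amplitude spectrum is kept (hence power spectrum,
autocorrelation and variance are preserved, by Wiener-Khinchin/Parseval),
and the phases of the positive-frequency components are replaced by i.i.d.
uniform draws, with conjugate symmetry enforced so the inverse transform is
real. Drawing phases independently per region destroys cross-regional
coupling, which is exactly what the null model must remove while leaving
each signal's own temporal structure intact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .timeseries import RegionalTimeSeries
from .triads import SubjectSummary, TriadState, subject_summary, STATE_ORDER
from .windows import WindowParams, sliding_window_connectivity

__all__ = ["SurrogateSpec", "phase_randomize", "surrogate_null_summary"]


@dataclass(frozen=True)
class SurrogateSpec:
    """Null-model settings: number of realizations, seed, phase coupling."""

    n_realizations: int = 10
    seed: int = 0
    independent_phases_across_regions: bool = True

    def __post_init__(self) -> None:
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")


def phase_randomize(
    ts: RegionalTimeSeries, spec: SurrogateSpec, realization_index: int = 0
) -> RegionalTimeSeries:
    """One phase-randomized surrogate of every region's signal.

    The zero-frequency component is kept unchanged; at even length the
    Nyquist component stays real, its sign flipped at random (phase 0 or
    pi). Realization ``r`` uses the deterministic substream
    ``(spec.seed, r)``, so individual realizations are reproducible and
    jointly independent.
    """
    if realization_index < 0:
        raise ValueError("realization_index must be non-negative")
    if ts.n_timepoints < 4:
        raise ValueError("need at least 4 timepoints to randomize phases")
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed, realization_index])
    )
    x = ts.values
    n, T = x.shape
    f = np.fft.rfft(x, axis=1)
    n_freq = f.shape[1]
    even = T % 2 == 0
    # indices of freely randomizable positive-frequency bins
    stop = n_freq - 1 if even else n_freq
    n_free = stop - 1

    shape = (n, n_free) if spec.independent_phases_across_regions else (1, n_free)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=shape)
    out = f.copy()
    out[:, 1:stop] = np.abs(f[:, 1:stop]) * np.exp(1j * phases)
    if even:
        sshape = (n, 1) if spec.independent_phases_across_regions else (1, 1)
        signs = rng.choice([-1.0, 1.0], size=sshape)
        out[:, -1:] = np.abs(f[:, -1:]) * signs
    surrogate = np.fft.irfft(out, n=T, axis=1)
    return RegionalTimeSeries(
        values=surrogate,
        tr_seconds=ts.tr_seconds,
        region_labels=list(ts.region_labels),
    )


def surrogate_null_summary(
    ts: RegionalTimeSeries,
    params: WindowParams,
    spec: SurrogateSpec,
    include_censored: bool = True,
    on_degenerate: str = "error",
) -> SubjectSummary:
    """Null reference: the full windowed-triad pipeline on each surrogate.

    Per-state mean lifetime and mean absolute peak energy are averaged
    across realizations; a state absent from a realization is excluded
    from that realization's contribution (``realization_counts`` records
    how many realizations contained each state). Occurrence and transition
    counts are averaged the same way, so the occurrence total still sums
    to ``n_triangles * n_windows``.
    """
    per_real: list[SubjectSummary] = []
    for r in range(spec.n_realizations):
        try:
            sur = phase_randomize(ts, spec, r)
            dyn = sliding_window_connectivity(sur, params, on_degenerate=on_degenerate)
            per_real.append(subject_summary(dyn, include_censored=include_censored))
        except Exception as exc:
            raise RuntimeError(f"surrogate realization {r} failed: {exc}") from exc

    mean_life: dict[TriadState, float | None] = {}
    mean_peak: dict[TriadState, float | None] = {}
    counts: dict[TriadState, int] = {}
    for s in STATE_ORDER:
        lifes = [sm.mean_lifetime[s] for sm in per_real if sm.mean_lifetime[s] is not None]
        peaks = [
            sm.mean_abs_peak_energy[s]
            for sm in per_real
            if sm.mean_abs_peak_energy[s] is not None
        ]
        counts[s] = len(lifes)
        mean_life[s] = float(np.mean(lifes)) if lifes else None
        mean_peak[s] = float(np.mean(peaks)) if peaks else None

    occurrence = {
        s: float(np.mean([sm.occurrence[s] for sm in per_real])) for s in STATE_ORDER
    }
    episode_counts = {
        s: int(round(np.mean([sm.episode_counts[s] for sm in per_real])))
        for s in STATE_ORDER
    }
    transitions = np.mean([sm.transition_counts for sm in per_real], axis=0)

    return SubjectSummary(
        mean_lifetime=mean_life,
        mean_abs_peak_energy=mean_peak,
        episode_counts=episode_counts,
        occurrence=occurrence,
        transition_counts=transitions,
        n_triangles=per_real[0].n_triangles,
        n_windows=per_real[0].n_windows,
        realization_counts=counts,
    )
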