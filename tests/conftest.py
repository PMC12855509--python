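import numpy as np
import pytest
from hypothesis import settings

import triadyn as td
from triadyn.triads import STATE_ORDER

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def make_minimal_summary(lifetimes, peaks=None, occurrence=None, transitions=None,
                         n_triangles=1, n_windows=10, subject_id=None):
    """SubjectSummary factory for stats-level tests (maps keyed by symbol)."""
    def to_state_map(d, default=None):
        if d is None:
            return {s: default for s in STATE_ORDER}
        return {s: d.get(s.symbol, default) for s in STATE_ORDER}

    return td.SubjectSummary(
        mean_lifetime=to_state_map(lifetimes),
        mean_abs_peak_energy=to_state_map(peaks if peaks is not None else lifetimes),
        episode_counts=to_state_map({}, default=1),
        occurrence=to_state_map(occurrence, default=0),
        transition_counts=np.asarray(transitions) if transitions is not None
        else np.zeros((4, 4), dtype=np.int64),
        n_triangles=n_triangles,
        n_windows=n_windows,
        subject_id=subject_id,
    )


def make_study_subject(seed: int) -> td.RegionalTimeSeries:
    """One synthetic subject under the study conditions.

    Two 6-region blocks, within-block correlation 0.3, between-block
    correlation alternating -0.4 / +0.4 across six 150-timepoint regimes,
    AR(1) coefficient 0.3, TR 0.72 s. Regime flips plant triad-state
    transitions; the weak within-block correlation lets edges flicker
    negative so all four configurations occur, the imbalanced ones only
    transiently.
    """
    cov_anti = td.make_block_covariance(12, [6, 6], within_r=0.3, between_r=-0.4)
    cov_pos = td.make_block_covariance(12, [6, 6], within_r=0.3, between_r=0.4)
    regimes = [
        td.RegimeSpec(150, cov_anti if i % 2 == 0 else cov_pos,
                      label="anti" if i % 2 == 0 else "pos")
        for i in range(6)
    ]
    cfg = td.SyntheticConfig(
        n_regions=12, regimes=regimes, ar_coefficient=0.3, tr_seconds=0.72, seed=seed
    )
    return td.generate_series(cfg)


@pytest.fixture(scope="session")
def study_cohort():
    """10-subject cohort: (real summaries, surrogate null summaries)."""
    params = td.WindowParams(window_length=50, step=1)
    reals, nulls = [], []
    for s in range(10):
        ts = make_study_subject(1000 + s)
        dyn = td.sliding_window_connectivity(ts, params)
        reals.append(td.subject_summary(dyn, subject_id=f"sub{s:02d}"))
        spec = td.SurrogateSpec(n_realizations=10, seed=2000 + s)
        nulls.append(td.surrogate_null_summary(ts, params, spec))
    return reals, nulls
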