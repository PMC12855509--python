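"""Group-level nonparametric comparisons.

Subject-level summaries (one mean lifetime and one mean absolute peak
energy per triadic state per subject) are compared with paired Wilcoxon
signed-rank tests, Cliff's delta effect sizes, and Benjamini-Hochberg FDR
correction within each declared family of tests: the 6 state-pair
comparisons per metric, and the 4 real-versus-surrogate lifetime tests.
The balanced-minus-imbalanced lifetime gap (real vs surrogate) gets its
own single paired test, with an optional sign-flip permutation test as a
sensitivity check.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .triads import STATE_ORDER, SubjectSummary, TriadState

__all__ = [
    "Comparison",
    "GroupResult",
    "wilcoxon_signed_rank",
    "cliffs_delta",
    "bh_fdr",
    "compare_states",
    "compare_real_vs_surrogate",
    "permutation_gap_test",
]

logger = logging.getLogger(__name__)


@dataclass
class Comparison:
    """One paired comparison: test statistic, p, effect size, q."""

    name: str
    metric: str
    n_subjects: int
    wilcoxon_statistic: float
    p_value: float
    cliffs_delta: float
    q_value: float = np.nan


@dataclass
class GroupResult:
    """A family (or families) of comparisons with FDR-adjusted q-values."""

    comparisons: list[Comparison] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "comparison": c.name,
                    "metric": c.metric,
                    "n": c.n_subjects,
                    "statistic": c.wilcoxon_statistic,
                    "p": c.p_value,
                    "cliffs_delta": c.cliffs_delta,
                    "q": c.q_value,
                }
                for c in self.comparisons
            ]
        )

    def get(self, name: str, metric: str | None = None) -> Comparison:
        for c in self.comparisons:
            if c.name == name and (metric is None or c.metric == metric):
                return c
        raise KeyError(f"no comparison {name!r} (metric={metric!r})")


def wilcoxon_signed_rank(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped; at least 5 non-zero pairs are required.
    The exact null distribution is used for n <= 25 (ties included — the
    exact method permutes the midranks), the normal approximation with
    continuity correction otherwise. The statistic is the smaller of the
    two signed rank sums.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("degenerate pairing: all paired differences are zero")
    if d.size < 5:
        raise ValueError(
            f"only {d.size} non-zero paired differences; need at least 5"
        )
    if d.size <= 25:
        res = sps.wilcoxon(d, zero_method="wilcox", alternative="two-sided", method="exact")
    else:
        res = sps.wilcoxon(
            d,
            zero_method="wilcox",
            alternative="two-sided",
            method="approx",
            correction=True,
        )
    return float(res.statistic), float(res.pvalue)


def cliffs_delta(x: Sequence[float], y: Sequence[float]) -> float:
    """Cliff's delta: P(x > y) - P(x < y) over all cross pairs, in [-1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("cliffs_delta requires non-empty samples")
    diff = x[:, None] - y[None, :]
    return float((np.sum(diff > 0) - np.sum(diff < 0)) / (x.size * y.size))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError(f"p-values must lie in [0, 1], got {p}")
    return multipletests(p, method="fdr_bh")[1]


def _metric_values(
    summaries: Sequence[SubjectSummary], metric: str
) -> dict[TriadState, np.ndarray]:
    attr = {"lifetime": "mean_lifetime", "abs_peak_energy": "mean_abs_peak_energy"}[
        metric
    ]
    return {
        s: np.array([getattr(sm, attr)[s] for sm in summaries], dtype=float)
        for s in STATE_ORDER
    }


def compare_states(
    summaries: Sequence[SubjectSummary],
    metrics: Sequence[str] = ("lifetime", "abs_peak_energy"),
) -> GroupResult:
    """All 6 state-pair paired comparisons per metric, FDR within each metric.

    Subjects missing any of the four states are dropped up front (with a
    logged count); at least 5 complete subjects are required.
    """
    complete = [
        sm
        for sm in summaries
        if all(sm.mean_lifetime[s] is not None for s in STATE_ORDER)
    ]
    dropped = len(summaries) - len(complete)
    if dropped:
        logger.info("dropped %d subject(s) missing at least one state", dropped)
    if len(complete) < 5:
        raise ValueError(
            f"need >= 5 subjects with all four states present, have {len(complete)}"
        )

    result = GroupResult()
    for metric in metrics:
        values = _metric_values(complete, metric)
        family: list[Comparison] = []
        for a, b in itertools.combinations(STATE_ORDER, 2):
            xa, xb = values[a], values[b]
            stat, p = wilcoxon_signed_rank(xa, xb)
            family.append(
                Comparison(
                    name=f"{a.symbol} vs {b.symbol}",
                    metric=metric,
                    n_subjects=len(complete),
                    wilcoxon_statistic=stat,
                    p_value=p,
                    cliffs_delta=cliffs_delta(xa, xb),
                )
            )
        q = bh_fdr([c.p_value for c in family])
        for c, qv in zip(family, q):
            c.q_value = float(qv)
        result.comparisons.extend(family)
    return result


def compare_real_vs_surrogate(
    real: Sequence[SubjectSummary], null: Sequence[SubjectSummary]
) -> GroupResult:
    """Real-vs-surrogate lifetimes: 4 per-state paired tests plus the balance gap.

    The per-state tests form one BH family of 4. The gap test compares
    each subject's balanced-minus-imbalanced mean-lifetime difference in
    the real data against the same quantity in its surrogate null; a
    positive Cliff's delta means the gap is larger in the real data.
    Subjects missing a state are excluded pairwise per comparison, with
    counts logged.
    """
    if len(real) != len(null):
        raise ValueError(
            f"subject mismatch: {len(real)} real vs {len(null)} surrogate summaries"
        )
    result = GroupResult()
    family: list[Comparison] = []
    for s in STATE_ORDER:
        pairs = [
            (r.mean_lifetime[s], n.mean_lifetime[s])
            for r, n in zip(real, null)
            if r.mean_lifetime[s] is not None and n.mean_lifetime[s] is not None
        ]
        if len(pairs) < len(real):
            logger.info(
                "state %s: %d subject(s) excluded pairwise",
                s.symbol,
                len(real) - len(pairs),
            )
        xr = np.array([p[0] for p in pairs])
        xn = np.array([p[1] for p in pairs])
        stat, p = wilcoxon_signed_rank(xr, xn)
        family.append(
            Comparison(
                name=f"{s.symbol} real vs surrogate",
                metric="lifetime",
                n_subjects=len(pairs),
                wilcoxon_statistic=stat,
                p_value=p,
                cliffs_delta=cliffs_delta(xr, xn),
            )
        )
    q = bh_fdr([c.p_value for c in family])
    for c, qv in zip(family, q):
        c.q_value = float(qv)
    result.comparisons.extend(family)

    gap_pairs = []
    for r, n in zip(real, null):
        try:
            gap_pairs.append((r.balance_gap(), n.balance_gap()))
        except ValueError:
            continue
    if len(gap_pairs) < len(real):
        logger.info(
            "balance gap: %d subject(s) excluded pairwise", len(real) - len(gap_pairs)
        )
    gr = np.array([g[0] for g in gap_pairs])
    gn = np.array([g[1] for g in gap_pairs])
    stat, p = wilcoxon_signed_rank(gr, gn)
    result.comparisons.append(
        Comparison(
            name="balance gap real vs surrogate",
            metric="lifetime",
            n_subjects=len(gap_pairs),
            wilcoxon_statistic=stat,
            p_value=p,
            cliffs_delta=cliffs_delta(gr, gn),
            q_value=p,  # single-test family
        )
    )
    return result


def permutation_gap_test(
    real_gaps: Sequence[float],
    null_gaps: Sequence[float],
    n_permutations: int = 10_000,
    seed: int = 0,
) -> float:
    """Subject-level sign-flip permutation p-value for the paired gap test.

    Under the null, each subject's real/surrogate labels are exchangeable,
    so the paired differences are sign-symmetric; the two-sided p-value is
    the fraction of sign-flip resamples whose |mean difference| reaches the
    observed one (with the +1 small-sample correction).
    """
    d = np.asarray(real_gaps, dtype=float) - np.asarray(null_gaps, dtype=float)
    if d.size == 0:
        raise ValueError("no paired gaps")
    rng = np.random.default_rng(seed)
    observed = abs(d.mean())
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, d.size))
    perm = np.abs((signs * d).mean(axis=1))
    return float((1 + np.sum(perm >= observed - 1e-12)) / (1 + n_permutations))
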