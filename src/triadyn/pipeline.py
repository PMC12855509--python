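"""End-to-end orchestration: per-subject processing and group statistics.

``run_pipeline`` takes a manifest of subjects (id -> time-series path),
runs windowed connectivity, episode extraction, surrogate nulls and the
group-level comparisons, and writes a bundle of text outputs plus a
machine-readable run manifest (package/dependency versions, seed, config
hash). Per-subject failures are quarantined and reported rather than
aborting the run; the group stage requires at least 5 surviving subjects.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import statsmodels
import statsmodels.api as smf
import yaml

from . import __version__
from .dynamics import group_occurrence, group_transition_proportions, TransitionMatrix
from .io import (
    SCHEMA_VERSION,
    peek_n_timepoints,
    read_time_series,
    write_episode_table,
    write_state_matrix_tsv,
    write_summary_json,
)
from .stats import GroupResult, compare_real_vs_surrogate, compare_states
from .surrogate import SurrogateSpec, surrogate_null_summary
from .triads import STATE_ORDER, iter_triangle_episodes, subject_summary
from .windows import WindowParams, sliding_window_connectivity

__all__ = ["PipelineConfig", "run_pipeline", "fit_energy_lifetime"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one run needs; mirrors the YAML config file."""

    subjects: dict[str, str]
    out_dir: str
    tr_seconds: float = 0.72
    window_length: int = 50
    step: int = 1
    run_boundaries: tuple[int, ...] | None = None
    n_surrogates: int = 10
    independent_phases: bool = True
    include_censored: bool = True
    on_degenerate: str = "error"
    seed: int = 0
    log_level: str = "INFO"

    def window_params(self) -> WindowParams:
        return WindowParams(
            window_length=self.window_length,
            step=self.step,
            run_boundaries=self.run_boundaries,
        )

    def to_dict(self) -> dict:
        d = {
            "subjects": dict(self.subjects),
            "out_dir": self.out_dir,
            "tr_seconds": self.tr_seconds,
            "window_length": self.window_length,
            "step": self.step,
            "run_boundaries": list(self.run_boundaries) if self.run_boundaries else None,
            "n_surrogates": self.n_surrogates,
            "independent_phases": self.independent_phases,
            "include_censored": self.include_censored,
            "on_degenerate": self.on_degenerate,
            "seed": self.seed,
            "log_level": self.log_level,
        }
        return d

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if raw.get("run_boundaries"):
            raw["run_boundaries"] = tuple(raw["run_boundaries"])
        return cls(**raw)

    def validate(self) -> None:
        if not self.subjects:
            raise ValueError("no subjects in manifest")
        missing = [p for p in self.subjects.values() if not Path(p).is_file()]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")
        self.window_params()  # raises on bad window/step/boundaries
        if self.n_surrogates < 1:
            raise ValueError("n_surrogates must be >= 1")
        for sid, path in self.subjects.items():
            n_tp = peek_n_timepoints(path)
            if n_tp < self.window_length:
                raise ValueError(
                    f"subject {sid}: series of {n_tp} timepoints shorter than "
                    f"window ({self.window_length})"
                )


def _config_hash(config: PipelineConfig) -> str:
    h = hashlib.sha256(json.dumps(config.to_dict(), sort_keys=True).encode())
    for sid in sorted(config.subjects):
        h.update(sid.encode())
        h.update(Path(config.subjects[sid]).read_bytes())
    return h.hexdigest()


def fit_energy_lifetime(table: pd.DataFrame) -> dict:
    """OLS fits of peak energy on lifetime, per balance class.

    Imbalanced triads get a linear fit, balanced triads a quadratic one
    (the joint lifetime-energy distribution separates the two classes;
    the balanced branch saturates, hence the extra curvature term).
    Coefficients are data-dependent descriptive summaries, highest power
    first.
    """
    fits = {}
    for balanced, degree, name in ((False, 1, "imbalanced_linear"), (True, 2, "balanced_quadratic")):
        sub = table[table["is_balanced"] == balanced]
        x = sub["mean_lifetime"].to_numpy(dtype=float)
        y = sub["mean_abs_peak_energy"].to_numpy(dtype=float)
        if x.size < degree + 2:
            fits[name] = None
            continue
        design = np.column_stack([x**d for d in range(degree, -1, -1)])
        model = smf.OLS(y, design).fit()
        fits[name] = {
            "coefficients": [float(c) for c in model.params],
            "r_squared": float(model.rsquared),
            "n_points": int(x.size),
        }
    return fits


def _write_group_result(result: GroupResult, out: Path, stem: str) -> None:
    df = result.to_dataframe()
    df.to_csv(out / f"{stem}.tsv", sep="\t", index=False)
    (out / f"{stem}.json").write_text(
        json.dumps(
            {"schema_version": SCHEMA_VERSION, "comparisons": df.to_dict(orient="records")},
            indent=1,
        )
        + "\n"
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns a dict of in-memory results."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.window_params()
    timings: dict[str, float] = {}
    failures: dict[str, str] = {}
    real_summaries = {}
    null_summaries = {}

    t_start = time.perf_counter()
    for sid, path in config.subjects.items():
        t0 = time.perf_counter()
        try:
            ts = read_time_series(path, tr_seconds=config.tr_seconds)
            dyn = sliding_window_connectivity(ts, params, on_degenerate=config.on_degenerate)
            sdir = out / sid
            sdir.mkdir(exist_ok=True)
            write_episode_table(
                iter_triangle_episodes(dyn),
                sdir / "episodes.tsv",
                step=params.step,
                tr_seconds=ts.tr_seconds,
            )
            summ = subject_summary(
                dyn, include_censored=config.include_censored, subject_id=sid
            )
            write_summary_json(summ, sdir / "summary.json")
            spec = SurrogateSpec(
                n_realizations=config.n_surrogates,
                seed=config.seed,
                independent_phases_across_regions=config.independent_phases,
            )
            null = surrogate_null_summary(
                ts,
                params,
                spec,
                include_censored=config.include_censored,
                on_degenerate=config.on_degenerate,
            )
            null.subject_id = sid
            write_summary_json(null, sdir / "null_summary.json")
            real_summaries[sid] = summ
            null_summaries[sid] = null
        except Exception as exc:  # quarantine, keep going
            logger.error("subject %s failed: %s", sid, exc)
            failures[sid] = str(exc)
        timings[sid] = time.perf_counter() - t0

    if len(real_summaries) < 5:
        raise RuntimeError(
            f"group stage needs >= 5 surviving subjects, have {len(real_summaries)} "
            f"(failures: {failures})"
        )

    sids = sorted(real_summaries)
    reals = [real_summaries[s] for s in sids]
    nulls = [null_summaries[s] for s in sids]

    t0 = time.perf_counter()
    state_result = compare_states(reals)
    _write_group_result(state_result, out, "group_state_comparisons")
    null_result = compare_real_vs_surrogate(reals, nulls)
    _write_group_result(null_result, out, "group_real_vs_surrogate")

    occ = group_occurrence(reals)
    pd.DataFrame(
        {"state": [s.symbol for s in STATE_ORDER], "proportion": [occ[s] for s in STATE_ORDER]}
    ).to_csv(out / "group_occurrence.tsv", sep="\t", index=False)

    pooled = np.sum([np.asarray(sm_.transition_counts) for sm_ in reals], axis=0)
    write_state_matrix_tsv(pooled, out / "group_transition_counts.tsv")
    write_state_matrix_tsv(
        group_transition_proportions(reals), out / "group_transition_proportions.tsv"
    )
    write_state_matrix_tsv(
        group_transition_proportions(reals, row_normalized=True),
        out / "group_transition_row_proportions.tsv",
    )

    rows = []
    for sid, summ in zip(sids, reals):
        for s in STATE_ORDER:
            if summ.mean_lifetime[s] is None:
                continue
            rows.append(
                {
                    "subject": sid,
                    "state": s.symbol,
                    "is_balanced": s.is_balanced,
                    "mean_lifetime": summ.mean_lifetime[s],
                    "mean_abs_peak_energy": summ.mean_abs_peak_energy[s],
                }
            )
    joint = pd.DataFrame(rows)
    joint.to_csv(out / "group_lifetime_energy.tsv", sep="\t", index=False)
    fits = fit_energy_lifetime(joint)
    (out / "group_lifetime_energy_fits.json").write_text(json.dumps(fits, indent=1) + "\n")
    timings["group"] = time.perf_counter() - t0

    manifest = {
        "schema_version": SCHEMA_VERSION,
        "triadyn_version": __version__,
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
        },
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "n_subjects_completed": len(real_summaries),
        "failed_subjects": failures,
        "timings_seconds": {k: round(v, 3) for k, v in timings.items()},
        "total_seconds": round(time.perf_counter() - t_start, 3),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")

    return {
        "real_summaries": real_summaries,
        "null_summaries": null_summaries,
        "state_result": state_result,
        "null_result": null_result,
        "occurrence": occ,
        "fits": fits,
        "manifest": manifest,
        "failures": failures,
    }
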