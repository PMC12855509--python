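"""File formats: time-series matrices, network archives, tables, summaries.

The canonical interchange format for signals is a plain delimited text
matrix — one row per region, one column per timepoint, a header row of
timepoint indices, an optional leading column of region labels, and a
``#tr_seconds=`` comment line carrying the sampling interval. Dynamic
networks round-trip through NumPy ``.npz`` archives; episode tables and
group results are TSV; subject summaries are JSON keyed by the state
symbols "+++", "+-+", "-+-", "---".
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .timeseries import RegionalTimeSeries
from .triads import (
    STATE_ORDER,
    EpisodeRecord,
    SubjectSummary,
    TriadState,
)
from .windows import DynamicNetwork, WindowParams

__all__ = [
    "read_time_series",
    "write_time_series",
    "save_dynamic_network",
    "load_dynamic_network",
    "write_episode_table",
    "summary_to_dict",
    "summary_from_dict",
    "write_summary_json",
    "read_summary_json",
]

SCHEMA_VERSION = "1"


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def peek_n_timepoints(path: str | Path) -> int:
    """Cheap pre-flight: timepoint count from the first data row only."""
    path = Path(path)
    sep = _sep_for(path)
    rows = []
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            rows.append(s.split(sep))
            if len(rows) == 2:
                break
    if not rows:
        raise ValueError(f"{path}: no data rows")
    row = rows[-1]  # a data row (rows[0] may be the header)
    try:
        float(row[0])
        return len(row)
    except ValueError:
        return len(row) - 1  # leading label column


def read_time_series(path: str | Path, tr_seconds: float | None = None) -> RegionalTimeSeries:
    """Read a regions x timepoints matrix from TSV/CSV.

    The delimiter is chosen from the extension (``.csv`` -> comma,
    otherwise tab). A ``#tr_seconds=<float>`` comment line, if present,
    overrides the ``tr_seconds`` argument. A non-numeric first column is
    taken as region labels; a non-numeric first row as a header of
    timepoint indices. Decimal points only (no locale commas).
    """
    path = Path(path)
    sep = _sep_for(path)
    file_tr = None
    with open(path) as fh:
        lines = []
        for line in fh:
            stripped = line.strip()
            if stripped.startswith("#"):
                if stripped[1:].replace(" ", "").startswith("tr_seconds="):
                    file_tr = float(stripped.split("=", 1)[1])
                continue
            if stripped:
                lines.append(line.rstrip("\n"))
    if not lines:
        raise ValueError(f"{path}: no data rows")

    def _numeric(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    first = lines[0].split(sep)
    has_header = not all(_numeric(t) for t in first)
    rows = [ln.split(sep) for ln in (lines[1:] if has_header else lines)]
    widths = {len(r) for r in rows}
    if len(widths) > 1:
        expected = len(rows[0])
        for i, r in enumerate(rows):
            if len(r) != expected:
                raise ValueError(
                    f"{path}: ragged row {i + (2 if has_header else 1)} "
                    f"has {len(r)} fields, expected {expected}"
                )
    has_labels = rows and not _numeric(rows[0][0])
    labels = [r[0] for r in rows] if has_labels else None
    values = np.empty((len(rows), len(rows[0]) - (1 if has_labels else 0)))
    for i, r in enumerate(rows):
        for j, tok in enumerate(r[1:] if has_labels else r):
            try:
                values[i, j] = float(tok)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value {tok!r} at data row {i + 1}, "
                    f"column {j + 1}"
                ) from None

    if values.shape[0] < 3:
        raise ValueError(
            f"{path}: {values.shape[0]} regions found, need at least 3 for triads"
        )
    tr = file_tr if file_tr is not None else tr_seconds
    if tr is None:
        raise ValueError(
            f"{path}: no '#tr_seconds=' comment line and no tr_seconds argument"
        )
    return RegionalTimeSeries(values=values, tr_seconds=tr, region_labels=labels)


def write_time_series(ts: RegionalTimeSeries, path: str | Path) -> None:
    """Write the matrix with a ``#tr_seconds=`` line and timepoint header."""
    path = Path(path)
    sep = _sep_for(path)
    with open(path, "w") as fh:
        fh.write(f"#tr_seconds={ts.tr_seconds!r}\n")
        fh.write("region" + sep + sep.join(str(t) for t in range(ts.n_timepoints)) + "\n")
        for label, row in zip(ts.region_labels, ts.values):
            fh.write(label + sep + sep.join(repr(float(v)) for v in row) + "\n")


def save_dynamic_network(dyn: DynamicNetwork, path: str | Path) -> None:
    """Lossless ``.npz`` archive of a windowed network."""
    p = dyn.params
    np.savez_compressed(
        path,
        weights=dyn.weights,
        window_starts=dyn.window_starts,
        window_length=p.window_length,
        step=p.step,
        run_boundaries=np.asarray(p.run_boundaries if p.run_boundaries else [], dtype=np.int64),
        tr_seconds=dyn.tr_seconds,
        region_labels=np.asarray(dyn.region_labels or [], dtype=object),
        degenerate_entries=np.asarray(dyn.degenerate_entries, dtype=np.int64).reshape(-1, 2),
        schema_version=SCHEMA_VERSION,
    )


def load_dynamic_network(path: str | Path) -> DynamicNetwork:
    with np.load(path, allow_pickle=True) as z:
        boundaries = tuple(int(x) for x in z["run_boundaries"]) or None
        params = WindowParams(
            window_length=int(z["window_length"]),
            step=int(z["step"]),
            run_boundaries=boundaries,
        )
        labels = [str(x) for x in z["region_labels"]] or None
        return DynamicNetwork(
            weights=z["weights"],
            window_starts=z["window_starts"],
            params=params,
            tr_seconds=float(z["tr_seconds"]),
            region_labels=labels,
            degenerate_entries=[tuple(map(int, row)) for row in z["degenerate_entries"]],
        )


def write_episode_table(
    episodes_by_triangle,
    path: str | Path,
    step: int = 1,
    tr_seconds: float | None = None,
) -> None:
    """TSV episode table; adds a seconds conversion of lifetime when TR is known."""
    path = Path(path)
    with open(path, "w") as fh:
        cols = [
            "triangle_i",
            "triangle_j",
            "triangle_k",
            "state",
            "start_window",
            "lifetime_windows",
            "abs_peak_energy",
            "left_censored",
            "right_censored",
        ]
        if tr_seconds is not None:
            cols.append("lifetime_seconds")
        fh.write("\t".join(cols) + "\n")
        for tri, episodes in episodes_by_triangle:
            for e in episodes:
                row = [
                    str(tri[0]),
                    str(tri[1]),
                    str(tri[2]),
                    e.state.symbol,
                    str(e.start_window),
                    str(e.lifetime),
                    f"{e.abs_peak_energy:.10g}",
                    str(int(e.left_censored)),
                    str(int(e.right_censored)),
                ]
                if tr_seconds is not None:
                    row.append(f"{e.lifetime * step * tr_seconds:.10g}")
                fh.write("\t".join(row) + "\n")


def summary_to_dict(summary: SubjectSummary) -> dict:
    """JSON-ready dict of a :class:`SubjectSummary`, keyed by state symbols."""
    sym = [s.symbol for s in STATE_ORDER]
    tc = np.asarray(summary.transition_counts, dtype=float)
    return {
        "schema_version": SCHEMA_VERSION,
        "subject_id": summary.subject_id,
        "n_triangles": summary.n_triangles,
        "n_windows": summary.n_windows,
        "mean_lifetime": {s.symbol: summary.mean_lifetime[s] for s in STATE_ORDER},
        "mean_abs_peak_energy": {
            s.symbol: summary.mean_abs_peak_energy[s] for s in STATE_ORDER
        },
        "episode_counts": {s.symbol: summary.episode_counts[s] for s in STATE_ORDER},
        "occurrence": {s.symbol: summary.occurrence[s] for s in STATE_ORDER},
        "transition_counts": {
            a: {b: tc[i, j] for j, b in enumerate(sym)} for i, a in enumerate(sym)
        },
        "realization_counts": (
            {s.symbol: summary.realization_counts[s] for s in STATE_ORDER}
            if summary.realization_counts is not None
            else None
        ),
    }


def summary_from_dict(d: dict) -> SubjectSummary:
    sym = [s.symbol for s in STATE_ORDER]
    tc = np.array(
        [[d["transition_counts"][a][b] for b in sym] for a in sym], dtype=float
    )
    if np.allclose(tc, np.round(tc)):
        tc = tc.astype(np.int64)
    return SubjectSummary(
        mean_lifetime={s: d["mean_lifetime"][s.symbol] for s in STATE_ORDER},
        mean_abs_peak_energy={
            s: d["mean_abs_peak_energy"][s.symbol] for s in STATE_ORDER
        },
        episode_counts={s: d["episode_counts"][s.symbol] for s in STATE_ORDER},
        occurrence={s: d["occurrence"][s.symbol] for s in STATE_ORDER},
        transition_counts=tc,
        n_triangles=d["n_triangles"],
        n_windows=d["n_windows"],
        subject_id=d.get("subject_id"),
        realization_counts=(
            {s: d["realization_counts"][s.symbol] for s in STATE_ORDER}
            if d.get("realization_counts") is not None
            else None
        ),
    )


def write_summary_json(summary: SubjectSummary, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary_to_dict(summary), indent=1) + "\n")


def read_summary_json(path: str | Path) -> SubjectSummary:
    return summary_from_dict(json.loads(Path(path).read_text()))


def write_state_matrix_tsv(matrix: np.ndarray, path: str | Path) -> None:
    """4x4 matrix as TSV with state symbols as header and index."""
    sym = [s.symbol for s in STATE_ORDER]
    df = pd.DataFrame(np.asarray(matrix), index=sym, columns=sym)
    df.to_csv(path, sep="\t", index_label="from\\to")
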