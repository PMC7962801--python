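"""Readers and writers for the on-disk formats.

All tabular files are comma-delimited text with a header row. Trial logs
carry subject, block, target_style, distractor_style, target_location,
response_location, rt_s; fixation logs carry subject, motif, style, x_px,
y_px and an optional duration_ms. Matrices are written with style labels as
both header row and first column (row = target, column = distractor). Trees
travel as newick. Malformed rows are rejected with their line number.

Eye trackers export richer formats; converting such an export to the
fixation-log schema above is the intended extension point (only the
coordinates, subject, and stimulus identity are needed here).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .gaze import HeatmapGrid, StyleCorrelation
from .matrices import PairMatrix
from .records import FixationRecord, StyleSet, TrialRecord

TRIAL_COLUMNS = [
    "subject",
    "block",
    "target_style",
    "distractor_style",
    "target_location",
    "response_location",
    "rt_s",
]
FIXATION_COLUMNS = ["subject", "motif", "style", "x_px", "y_px"]


class FormatError(ValueError):
    """A file violated the expected schema; the message names the line."""


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")


def read_trials(path: str | Path) -> list[TrialRecord]:
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, TRIAL_COLUMNS, path)
    records: list[TrialRecord] = []
    for pos, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        try:
            rt = float(row.rt_s)
        except (TypeError, ValueError):
            raise FormatError(f"{path}: line {pos}: non-numeric rt_s {row.rt_s!r}") from None
        try:
            records.append(
                TrialRecord(
                    subject=str(row.subject),
                    block=int(row.block),
                    target_style=str(row.target_style),
                    distractor_style=str(row.distractor_style),
                    target_location=str(row.target_location),
                    response_location=str(row.response_location),
                    rt=rt,
                )
            )
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: line {pos}: {exc}") from None
    return records


def write_trials(trials: Sequence[TrialRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "subject": [t.subject for t in trials],
            "block": [t.block for t in trials],
            "target_style": [t.target_style for t in trials],
            "distractor_style": [t.distractor_style for t in trials],
            "target_location": [t.target_location for t in trials],
            "response_location": [t.response_location for t in trials],
            "rt_s": [repr(t.rt) for t in trials],  # repr round-trips floats exactly
        }
    )
    df.to_csv(path, index=False)


def read_fixations(path: str | Path) -> list[FixationRecord]:
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, FIXATION_COLUMNS, path)
    has_duration = "duration_ms" in df.columns
    records: list[FixationRecord] = []
    for pos, row in enumerate(df.itertuples(index=False), start=2):
        try:
            x, y = float(row.x_px), float(row.y_px)
        except (TypeError, ValueError):
            raise FormatError(
                f"{path}: line {pos}: non-numeric coordinates ({row.x_px!r}, {row.y_px!r})"
            ) from None
        duration = None
        if has_duration and isinstance(row.duration_ms, str) and row.duration_ms != "":
            try:
                duration = float(row.duration_ms)
            except ValueError:
                raise FormatError(
                    f"{path}: line {pos}: non-numeric duration_ms {row.duration_ms!r}"
                ) from None
        records.append(
            FixationRecord(
                subject=str(row.subject),
                motif=str(row.motif),
                style=str(row.style),
                x=x,
                y=y,
                duration_ms=duration,
            )
        )
    return records


def write_fixations(fixations: Sequence[FixationRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "subject": [f.subject for f in fixations],
            "motif": [f.motif for f in fixations],
            "style": [f.style for f in fixations],
            "x_px": [repr(f.x) for f in fixations],
            "y_px": [repr(f.y) for f in fixations],
            "duration_ms": ["" if f.duration_ms is None else repr(f.duration_ms) for f in fixations],
        }
    )
    df.to_csv(path, index=False)


def write_matrix(matrix: PairMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, index_label="target")


def read_matrix(path: str | Path, statistic: str) -> PairMatrix:
    df = pd.read_csv(path, index_col=0)
    return PairMatrix.from_frame(df, statistic)


def write_heatmap(h: HeatmapGrid, path: str | Path) -> None:
    """G×G grid as CSV preceded by '#'-prefixed metadata lines."""
    with open(path, "w") as fh:
        fh.write(f"# motif={h.motif} style={h.style} state={h.state} "
                 f"n_fixations={h.n_fixations} n_discarded={h.n_discarded}\n")
        np.savetxt(fh, h.mass, delimiter=",")


def read_heatmap(path: str | Path) -> HeatmapGrid:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise FormatError(f"{path}: expected a '#' metadata header line")
        meta = dict(kv.split("=", 1) for kv in header[1:].split())
        mass = np.loadtxt(fh, delimiter=",")
    return HeatmapGrid(
        motif=meta["motif"],
        style=meta["style"],
        mass=mass,
        n_fixations=int(meta["n_fixations"]),
        state=meta["state"],
        n_discarded=int(meta.get("n_discarded", 0)),
    )


def write_correlation(corr: StyleCorrelation, path_prefix: str | Path) -> None:
    """Write r / p / n-images matrices as three CSVs sharing a prefix."""
    prefix = Path(path_prefix)
    labels = corr.styles.labels
    for name, arr in (("r", corr.r), ("p", corr.p), ("n", corr.n_images)):
        pd.DataFrame(arr, index=labels, columns=labels).to_csv(
            prefix.with_name(prefix.name + f"_{name}.csv"), index_label="style"
        )


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
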