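"""Delimited-text readers and writers for traces, manifests and tables.

Trace files are one row per sample with columns ``time_s, grip_N, load_N,
platform_N, photogate`` (0/1); the sampling rate is inferred from the time
column and checked for uniformity.  A session manifest lists one trial per
row with the trace filename, so a full recorded session round-trips through
plain text.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .design import label_transitions
from .exceptions import SchemaError
from .measures import MEASURE_NAMES
from .simulate import ForceTrace, StimulusSpec, TrialRecord

TRACE_COLUMNS = ("time_s", "grip_N", "load_N", "platform_N", "photogate")
MANIFEST_COLUMNS = (
    "participant_id",
    "trial_index",
    "label",
    "mass_g",
    "side_length_cm",
    "magnitude_estimate",
    "trace_filename",
)

#: Relative tolerance for sampling-period uniformity (1 part in 10^4).
_DT_RTOL = 1e-4
_FLOAT_FORMAT = "%.12g"


def write_trace(path: str | Path, trace: ForceTrace) -> None:
    """Write one trial's trace as delimited text."""
    frame = pd.DataFrame(
        {
            "time_s": trace.times,
            "grip_N": np.asarray(trace.grip, dtype=float),
            "load_N": np.asarray(trace.load, dtype=float),
            "platform_N": np.asarray(trace.platform, dtype=float),
            "photogate": np.asarray(trace.photogate, dtype=bool).astype(int),
        }
    )
    frame.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def read_trace(path: str | Path) -> ForceTrace:
    """Read and validate a trace file written by :func:`write_trace`.

    The time column must be strictly increasing and uniformly sampled to
    within 1 part in 10^4; violations raise :class:`SchemaError` naming the
    offending row (1-based data rows).
    """
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise SchemaError(f"{path}: could not parse as delimited text: {exc}") from exc
    missing = set(TRACE_COLUMNS) - set(frame.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    if len(frame) < 2:
        raise SchemaError(f"{path}: need at least 2 samples, got {len(frame)}")
    t = frame["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    non_mono = np.nonzero(dt <= 0)[0]
    if non_mono.size:
        raise SchemaError(
            f"{path}: time column is not strictly increasing at row "
            f"{int(non_mono[0]) + 2}"
        )
    dt0 = (t[-1] - t[0]) / (len(t) - 1)
    bad = np.nonzero(np.abs(dt - dt0) > _DT_RTOL * dt0)[0]
    if bad.size:
        raise SchemaError(
            f"{path}: non-uniform sampling at row {int(bad[0]) + 2} "
            f"(dt = {dt[bad[0]]:.6g} s vs nominal {dt0:.6g} s)"
        )
    gate = frame["photogate"].to_numpy()
    return ForceTrace(
        sampling_rate=1.0 / dt0,
        grip=frame["grip_N"].to_numpy(dtype=float),
        load=frame["load_N"].to_numpy(dtype=float),
        platform=frame["platform_N"].to_numpy(dtype=float),
        photogate=gate.astype(bool),
    )


def write_session(
    directory: str | Path, records: list[TrialRecord], manifest_name: str = "manifest.csv"
) -> Path:
    """Write a cohort as one trace file per trial plus a session manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        fname = f"{rec.participant_id}_trial{rec.trial_index:03d}.csv"
        write_trace(directory / fname, rec.trace)
        rows.append(
            {
                "participant_id": rec.participant_id,
                "trial_index": rec.trial_index,
                "label": rec.condition.cube,
                "mass_g": rec.stimulus.mass,
                "side_length_cm": rec.stimulus.side_length,
                "magnitude_estimate": rec.magnitude_estimate,
                "trace_filename": fname,
            }
        )
    manifest_path = directory / manifest_name
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(
        manifest_path, index=False, float_format=_FLOAT_FORMAT
    )
    return manifest_path


def read_session(manifest_path: str | Path) -> list[TrialRecord]:
    """Rebuild TrialRecords from a manifest and its trace files.

    Transition conditions are recomputed from each participant's label
    order (sorted by trial index), with the first trial marked discard.
    """
    manifest_path = Path(manifest_path)
    frame = pd.read_csv(manifest_path)
    missing = set(MANIFEST_COLUMNS) - set(frame.columns)
    if missing:
        raise SchemaError(f"{manifest_path}: missing columns {sorted(missing)}")
    records: list[TrialRecord] = []
    for participant, group in frame.groupby("participant_id", sort=True):
        group = group.sort_values("trial_index")
        conditions = label_transitions(list(group["label"]))
        for (_, row), condition in zip(group.iterrows(), conditions):
            trace = read_trace(manifest_path.parent / row["trace_filename"])
            records.append(
                TrialRecord(
                    trace=trace,
                    stimulus=StimulusSpec(
                        float(row["mass_g"]), float(row["side_length_cm"])
                    ),
                    condition=condition,
                    magnitude_estimate=float(row["magnitude_estimate"]),
                    participant_id=str(participant),
                    trial_index=int(row["trial_index"]),
                )
            )
    return records


def write_measures(path: str | Path, measures: pd.DataFrame) -> None:
    """Write the per-trial measures table; absent values become empty fields."""
    measures.to_csv(path, index=False, float_format=_FLOAT_FORMAT, na_rep="")


def read_measures(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    required = {"participant_id", "trial_index", "cube", "switch", *MEASURE_NAMES}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    return frame
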