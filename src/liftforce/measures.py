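"""Trial-level dependent measures and data-preparation rules.

Each trial reduces to nine scalars:

========  =============================================================
PLF       peak load force (N), from the doubled handle channel
PLFR      peak load force rate (N/s)
PGF       peak grip force (N)
PGFR      peak grip force rate (N/s)
LF1st     load force at the first peak in load force rate (N)
LPD1      load phase duration from the handle's 0.2 N onset (s)
PPFR      peak platform force rate (N/s), searchable only up to lift-off
PF1st     platform force at the first peak in platform force rate (N)
LPD2      load phase duration from the platform's 0.4 N onset (s)
========  =============================================================

plus the participant-normalized perceptual %-score.  Handle-derived
measures are searched from force onset to the end of the trace (the handle
records through the hold phase); platform-derived measures stop at lift-off
because the platform physically cannot record later — the truncation that
makes light-object platform data unreliable.  Any measure may be absent;
absences carry a reason string rather than being silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError, MissingCellError
from .signal import (
    FilterSpec,
    detect_liftoff,
    detect_onset,
    differentiate,
    find_first_rate_peak,
    find_global_peak,
    lowpass_zero_phase,
)
from .simulate import ForceTrace, TrialRecord

#: Measure names in reporting order.
MEASURE_NAMES = (
    "PLF",
    "PLFR",
    "PGF",
    "PGFR",
    "LF1st",
    "LPD1",
    "PPFR",
    "PF1st",
    "LPD2",
)

#: (handle measure, platform measure) pairs compared in the agreement analysis.
HANDLE_PLATFORM_PAIRS = (("PLFR", "PPFR"), ("LF1st", "PF1st"), ("LPD1", "LPD2"))


@dataclass
class ExtractionConfig:
    """Parameters of the trace-to-measures pipeline.

    ``handle_force_scale`` converts the single-digit handle reading to total
    load force (2.0: the thumb's share is not measured); the 0.2 N handle
    onset threshold applies to this doubled signal, while the platform's
    0.4 N threshold applies to the full-force platform reduction.
    ``baseline_window`` is the initial quiet span used to estimate the
    platform's resting reading.
    """

    handle_onset_threshold: float = 0.2  # N, on the doubled load force
    platform_onset_threshold: float = 0.4  # N, on the platform reduction
    handle_force_scale: float = 2.0
    filter: FilterSpec = field(default_factory=FilterSpec)
    min_prominence: float = 0.05
    baseline_window: float = 0.2  # s
    literal_percent_sign: bool = False
    #: Span (s) before a recording boundary within which a rate peak cannot
    #: be told apart from the zero-phase filter's edge transient; None means
    #: one filter time constant, 1 / cutoff.
    edge_guard: float | None = None

    def __post_init__(self) -> None:
        if self.handle_onset_threshold <= 0 or self.platform_onset_threshold <= 0:
            raise InvalidArgumentError("onset thresholds must be > 0 N")
        if self.handle_force_scale <= 0:
            raise InvalidArgumentError("handle_force_scale must be > 0")
        if not 0 < self.min_prominence < 1:
            raise InvalidArgumentError("min_prominence must lie in (0, 1)")
        if self.baseline_window <= 0:
            raise InvalidArgumentError("baseline_window must be > 0 s")


@dataclass
class TrialMeasures:
    """The nine derived scalars of one trial; any may be None (undetectable).

    ``absent`` maps each missing measure to the reason it could not be
    computed, so missingness is never silent.
    """

    PLF: float | None = None
    PLFR: float | None = None
    PGF: float | None = None
    PGFR: float | None = None
    LF1st: float | None = None
    LPD1: float | None = None
    PPFR: float | None = None
    PF1st: float | None = None
    LPD2: float | None = None
    pct_score: float | None = None
    absent: dict[str, str] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in MEASURE_NAMES}


def _reduction_series(
    platform: np.ndarray, fs: float, config: ExtractionConfig
) -> np.ndarray:
    """Baseline-minus-reading on an already-bounded platform segment."""
    n_base = int(round(config.baseline_window * fs))
    if n_base < 1 or n_base > len(platform):
        raise InvalidArgumentError(
            f"baseline window of {config.baseline_window} s needs {n_base} "
            f"samples but the platform segment has {len(platform)}"
        )
    filtered = lowpass_zero_phase(platform, fs, config.filter)
    baseline = float(np.median(filtered[:n_base]))
    return baseline - filtered


def platform_reduction(
    trace: ForceTrace, config: ExtractionConfig = ExtractionConfig(), clip: bool = False
) -> np.ndarray:
    """Force removed from the platform: resting baseline minus the reading.

    The baseline is the median of the filtered platform channel over the
    initial ``baseline_window`` seconds, which must precede force onset.
    Until lift-off the reduction mirrors the total applied load force; after
    lift-off it plateaus at the object's weight-force.
    """
    reduction = _reduction_series(
        np.asarray(trace.platform, dtype=float), trace.sampling_rate, config
    )
    if clip:
        reduction = np.maximum(reduction, 0.0)
    return reduction


def extract_measures(
    trial: TrialRecord | ForceTrace, config: ExtractionConfig = ExtractionConfig()
) -> TrialMeasures:
    """Reduce one trial's trace to the nine dependent measures.

    Pipeline: filter all force channels; double the handle load; compute
    rates by central difference; detect the handle (0.2 N) and platform
    (0.4 N) onsets and the photogate lift-off; then take peaks, first-rate
    peaks and load-phase durations over the appropriate windows.  A missing
    lift-off leaves durations and platform measures absent but handle peaks
    still computed, mirroring what each instrument can actually record.
    """
    trace = trial.trace if isinstance(trial, TrialRecord) else trial
    fs = trace.sampling_rate
    out = TrialMeasures()

    grip = lowpass_zero_phase(trace.grip, fs, config.filter)
    handle = lowpass_zero_phase(trace.load, fs, config.filter)
    total_load = handle * config.handle_force_scale
    load_rate = differentiate(total_load, fs)
    grip_rate = differentiate(grip, fs)

    t_end = (trace.n_samples - 1) / fs
    guard = (
        config.edge_guard
        if config.edge_guard is not None
        else 1.0 / config.filter.cutoff
    )
    onset = detect_onset(total_load, fs, config.handle_onset_threshold)
    liftoff = detect_liftoff(trace.photogate, fs)

    # The platform records only up to lift-off, so its channel is bounded
    # there *before* filtering; otherwise the zero-phase filter would smear
    # the post-lift-off plateau backwards and fabricate a pre-lift-off rate
    # peak that the instrument never saw.
    reduction: np.ndarray | None
    platform_short_reason: str | None = None
    platform_samples = np.asarray(trace.platform, dtype=float)
    if liftoff is not None:
        platform_samples = platform_samples[: int(round(liftoff * fs)) + 1]
    min_filter_len = 3 * config.filter.order + 1
    n_base = int(round(config.baseline_window * fs))
    if len(platform_samples) < max(min_filter_len, n_base):
        reduction = None
        reduction_rate = None
        p_onset = None
        platform_short_reason = (
            f"platform recording window of {len(platform_samples)} samples is "
            "too short to filter and baseline"
        )
    else:
        reduction = _reduction_series(platform_samples, fs, config)
        reduction_rate = differentiate(reduction, fs)
        p_onset = detect_onset(reduction, fs, config.platform_onset_threshold)

    if onset is None:
        reason = (
            f"total load force never exceeded {config.handle_onset_threshold} N"
        )
        for name in ("PLF", "PLFR", "PGF", "PGFR", "LF1st", "LPD1"):
            out.absent[name] = reason
    else:
        out.PLF, _ = find_global_peak(total_load, (onset, t_end), fs)
        out.PLFR, _ = find_global_peak(load_rate, (onset, t_end), fs)
        out.PGF, _ = find_global_peak(grip, (onset, t_end), fs)
        out.PGFR, _ = find_global_peak(grip_rate, (onset, t_end), fs)
        first = find_first_rate_peak(
            load_rate, onset, t_end - guard, fs, config.min_prominence
        )
        if first is None:
            out.absent["LF1st"] = "no prominent first peak in load force rate"
        else:
            _, t_first = first
            out.LF1st = float(total_load[int(round(t_first * fs))])
        if liftoff is None:
            out.absent["LPD1"] = "no lift-off recorded"
        elif liftoff < onset:
            out.absent["LPD1"] = "lift-off preceded the handle force onset"
        else:
            out.LPD1 = liftoff - onset

    platform_reasons: dict[str, str] = {}
    if platform_short_reason is not None:
        platform_reasons = dict.fromkeys(
            ("PPFR", "PF1st", "LPD2"), platform_short_reason
        )
    elif p_onset is None:
        platform_reasons = dict.fromkeys(
            ("PPFR", "PF1st", "LPD2"),
            f"platform force reduction never exceeded "
            f"{config.platform_onset_threshold} N",
        )
    elif liftoff is None:
        platform_reasons = dict.fromkeys(
            ("PPFR", "PF1st", "LPD2"),
            "no lift-off recorded (platform cannot bound its window)",
        )
    elif liftoff < p_onset:
        platform_reasons = dict.fromkeys(
            ("PPFR", "PF1st", "LPD2"), "lift-off preceded the platform onset"
        )
    if platform_reasons:
        out.absent.update(platform_reasons)
    else:
        # The platform records only until lift-off: all windows end there.
        out.PPFR, _ = find_global_peak(reduction_rate, (p_onset, liftoff), fs)
        first = find_first_rate_peak(
            reduction_rate, p_onset, liftoff - guard, fs, config.min_prominence
        )
        if first is None:
            out.absent["PF1st"] = (
                "platform force rate still rising at lift-off (peak truncated)"
            )
        else:
            _, t_first = first
            out.PF1st = float(reduction[int(round(t_first * fs))])
        out.LPD2 = liftoff - p_onset
    return out


def percent_scores(estimates, literal_sign: bool = False) -> np.ndarray:
    """Normalize one participant's magnitude estimates to %-scores.

    The default sign convention is ``(estimate - mean) / mean * 100`` so
    heavier-felt objects score positive; ``literal_sign=True`` flips to
    ``(mean - estimate) / mean * 100``.  Scores always average to zero.
    """
    x = np.asarray(estimates, dtype=float)
    if x.size == 0:
        raise InvalidArgumentError("need at least one magnitude estimate")
    if not np.all(x > 0):
        raise InvalidArgumentError("magnitude estimates must all be positive")
    mean = x.mean()
    scores = (x - mean) / mean * 100.0
    return -scores if literal_sign else scores


def trim_outliers(values, k: float = 3.0) -> np.ndarray:
    """Inclusion mask excluding values more than ``k`` SDs from the mean.

    Mean and SD (n - 1 denominator) are computed once on the full input;
    the rule is not re-iterated.  A degenerate spread (SD = 0) retains
    everything.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InvalidArgumentError(f"need at least 2 values to trim, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise InvalidArgumentError("trim_outliers requires finite values")
    sd = x.std(ddof=1)
    if sd == 0:
        return np.ones(x.size, dtype=bool)
    return np.abs(x - x.mean()) <= k * sd


def condition_means(
    measures: pd.DataFrame,
    measure_columns: tuple[str, ...] | list[str] | None = None,
    strict: bool = True,
) -> pd.DataFrame:
    """Per-participant means in each (cube, switch) cell, per measure.

    ``measures`` is a long table with ``participant_id``, ``cube``,
    ``switch`` columns plus one column per measure; ``discard``-labelled
    trials are removed and NaN (absent or trimmed) values drop out of the
    means.  Returns a tidy frame with columns ``participant_id``, ``cube``,
    ``switch``, ``measure``, ``value``.

    With ``strict=True`` an empty cell raises :class:`MissingCellError`
    naming the participant, cell and measure; with ``strict=False`` the cell
    mean is NaN and it is the caller's job to handle it.
    """
    required = {"participant_id", "cube", "switch"}
    missing = required - set(measures.columns)
    if missing:
        raise InvalidArgumentError(f"measures table lacks columns: {sorted(missing)}")
    if measure_columns is None:
        measure_columns = [
            c for c in measures.columns if c not in required and c != "trial_index"
        ]
    data = measures[measures["switch"] != "discard"]
    long = data.melt(
        id_vars=["participant_id", "cube", "switch"],
        value_vars=list(measure_columns),
        var_name="measure",
        value_name="value",
    )
    cells = (
        long.groupby(["participant_id", "cube", "switch", "measure"], sort=True)[
            "value"
        ]
        .mean()
        .reset_index()
    )
    # Reinstate cells with zero rows (a participant may lack a cube/switch
    # combination entirely) so missingness is explicit.
    participants = sorted(data["participant_id"].unique())
    cubes = sorted(data["cube"].unique())
    switches = sorted(data["switch"].unique())
    full_index = pd.MultiIndex.from_product(
        [participants, cubes, switches, list(measure_columns)],
        names=["participant_id", "cube", "switch", "measure"],
    )
    cells = (
        cells.set_index(["participant_id", "cube", "switch", "measure"])
        .reindex(full_index)
        .reset_index()
    )
    if strict:
        empty = cells[cells["value"].isna()]
        if not empty.empty:
            row = empty.iloc[0]
            raise MissingCellError(
                f"participant {row['participant_id']}: no retained values for "
                f"{row['measure']} in cell ({row['cube']}, {row['switch']}) "
                f"({len(empty)} empty cells in total)"
            )
    return cells


def records_to_condition_frame(records) -> pd.DataFrame:
    """Adapter: (participant, ConditionLabel, TrialMeasures) triples to a table."""
    rows = []
    for participant, condition, tm in records:
        row = {
            "participant_id": participant,
            "cube": condition.cube,
            "switch": condition.switch,
        }
        row.update({k: (np.nan if v is None else v) for k, v in tm.as_dict().items()})
        if tm.pct_score is not None:
            row["pct_score"] = tm.pct_score
        rows.append(row)
    return pd.DataFrame(rows)
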