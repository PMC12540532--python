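"""Trace-level signal-processing primitives.

Force channels are smoothed with a fourth-order zero-phase (forward-backward)
low-pass Butterworth filter at 14 Hz before differentiation and event
detection, matching standard practice in grip/load-force studies.  Rates of
force change use a three-point central difference; onsets are strict
threshold crossings; lift-off comes from the photogate channel; peaks are
first-occurrence maxima, with a prominence-based detector standing in for
the human rater who traditionally marks the *first* peak of a force-rate
profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .exceptions import InvalidArgumentError


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase low-pass Butterworth filter parameters.

    ``order`` is the order of the underlying Butterworth design; the
    forward-backward application squares its magnitude response, so the
    attenuation of a tone at frequency f is ``1 / (1 + (f / cutoff)**(2 * order))``.
    """

    order: int = 4
    cutoff: float = 14.0  # Hz

    def __post_init__(self) -> None:
        if self.order < 1:
            raise InvalidArgumentError(f"filter order must be >= 1, got {self.order}")
        if self.cutoff <= 0:
            raise InvalidArgumentError(f"cutoff must be > 0 Hz, got {self.cutoff}")


@dataclass(frozen=True)
class EventTimes:
    """Load-phase landmarks of one trial: force onset and lift-off (seconds)."""

    onset_time: float | None = None
    liftoff_time: float | None = None

    def __post_init__(self) -> None:
        if (
            self.onset_time is not None
            and self.liftoff_time is not None
            and self.onset_time > self.liftoff_time
        ):
            raise InvalidArgumentError(
                f"onset_time ({self.onset_time}) must not exceed "
                f"liftoff_time ({self.liftoff_time})"
            )


def lowpass_zero_phase(
    signal: np.ndarray, sampling_rate: float, spec: FilterSpec = FilterSpec()
) -> np.ndarray:
    """Apply the zero-phase low-pass Butterworth filter to one channel.

    Output length equals input length; DC gain is 1; phase lag is zero by
    forward-backward application.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise InvalidArgumentError("signal must be one-dimensional")
    min_len = 3 * spec.order + 1
    if x.size < min_len:
        raise InvalidArgumentError(
            f"signal too short to filter: need at least {min_len} samples "
            f"(3 x order + 1), got {x.size}"
        )
    if spec.cutoff >= sampling_rate / 2:
        raise InvalidArgumentError(
            f"cutoff {spec.cutoff} Hz must be below the Nyquist frequency "
            f"{sampling_rate / 2} Hz"
        )
    b, a = scipy.signal.butter(spec.order, spec.cutoff, btype="low", fs=sampling_rate)
    return scipy.signal.filtfilt(b, a, x, padlen=3 * spec.order)


def differentiate(signal: np.ndarray, sampling_rate: float) -> np.ndarray:
    """Three-point central-difference derivative, in signal units per second.

    Interior samples use ``(x[i+1] - x[i-1]) * fs / 2``; the two boundary
    samples use one-sided first differences so the output keeps the input's
    length.  Exact for polynomials of degree <= 2 on the interior.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 3:
        raise InvalidArgumentError(f"need at least 3 samples to differentiate, got {x.size}")
    return np.gradient(x, 1.0 / sampling_rate)


def detect_onset(
    signal: np.ndarray, sampling_rate: float, threshold: float
) -> float | None:
    """Time of the first sample strictly exceeding ``threshold``, or None."""
    if threshold <= 0:
        raise InvalidArgumentError(f"threshold must be > 0, got {threshold}")
    x = np.asarray(signal, dtype=float)
    above = x > threshold
    if not above.any():
        return None
    return int(np.argmax(above)) / sampling_rate


def detect_liftoff(photogate: np.ndarray, sampling_rate: float) -> float | None:
    """Time of the first True photogate sample (object off the surface)."""
    gate = np.asarray(photogate, dtype=bool)
    if not gate.any():
        return None
    return int(np.argmax(gate)) / sampling_rate


def _window_indices(
    n: int, start_time: float, end_time: float, sampling_rate: float
) -> tuple[int, int]:
    """Inclusive sample-index bounds of a [start, end] time window."""
    i0 = int(np.ceil(start_time * sampling_rate - 1e-9))
    i1 = int(np.floor(end_time * sampling_rate + 1e-9))
    i0 = max(i0, 0)
    i1 = min(i1, n - 1)
    return i0, i1


def find_global_peak(
    signal: np.ndarray,
    window: tuple[float, float],
    sampling_rate: float,
) -> tuple[float, float]:
    """Maximum value over a time window and the time of its first occurrence.

    Plateaus are resolved to their first sample.
    """
    x = np.asarray(signal, dtype=float)
    start_time, end_time = window
    i0, i1 = _window_indices(x.size, start_time, end_time, sampling_rate)
    if i1 < i0:
        raise InvalidArgumentError(
            f"empty peak-search window [{start_time}, {end_time}] s"
        )
    seg = x[i0 : i1 + 1]
    j = int(np.argmax(seg))
    return float(seg[j]), (i0 + j) / sampling_rate


def find_first_rate_peak(
    rate: np.ndarray,
    onset_time: float,
    end_time: float,
    sampling_rate: float,
    min_prominence: float = 0.05,
) -> tuple[float, float] | None:
    """First sufficiently prominent local maximum of a force-rate series.

    Scans ``[onset_time, end_time]`` for the earliest local maximum whose
    prominence is at least ``min_prominence`` times the window maximum.
    Returns ``(value, time)``; plateaus resolve to their first sample.
    Returns None when no interior local maximum qualifies — notably when the
    rate is still rising at the end of the window, the signature of a peak
    truncated at lift-off.
    """
    x = np.asarray(rate, dtype=float)
    if onset_time >= end_time:
        return None
    i0, i1 = _window_indices(x.size, onset_time, end_time, sampling_rate)
    seg = x[i0 : i1 + 1]
    if seg.size < 3:
        return None
    peaks, props = scipy.signal.find_peaks(seg, prominence=0, plateau_size=(1, None))
    if peaks.size == 0:
        return None
    threshold = min_prominence * abs(seg.max())
    for prominence, left_edge in zip(props["prominences"], props["left_edges"]):
        if prominence >= threshold:
            j = int(left_edge)
            return float(seg[j]), (i0 + j) / sampling_rate
    return None
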