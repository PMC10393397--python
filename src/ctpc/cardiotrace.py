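"""Raw cardiac traces: smoothing, beat detection, rate windows, flatline (ULT).

A trace is the synchronized record of an optical heartbeat sensor (mV) and
body temperature (deg C) while the animal is heated on a slow ramp. The chain
implemented here is: optional triangular (Bartlett) smoothing -> peak-based
beat detection -> windowed heart-rate-vs-temperature series -> detection of
the terminal flatline, whose temperature is the upper lethal temperature
(ULT).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks
from scipy.signal.windows import triang

TRACE_COLUMNS = ["time_s", "signal_mV", "temp_C"]


class TraceError(ValueError):
    """Invalid cardiac trace or processing parameters."""


@dataclass
class CardiacTrace:
    """One individual's sensor signal and body temperature versus time."""

    time: np.ndarray  # s, strictly increasing
    signal: np.ndarray  # mV
    temp: np.ndarray  # deg C
    sample_hz: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        self.temp = np.asarray(self.temp, dtype=float)
        if not (len(self.time) == len(self.signal) == len(self.temp)):
            raise TraceError("time, signal and temp must have equal length")
        if self.time.size >= 2 and not np.all(np.diff(self.time) > 0):
            raise TraceError("time must be strictly increasing")
        if not self.sample_hz > 0:
            raise TraceError("sample_hz must be positive")

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0]) if self.time.size else 0.0

    def to_csv(self, path, header_lines: Sequence[str] = ()) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            pd.DataFrame(
                {"time_s": self.time, "signal_mV": self.signal, "temp_C": self.temp}
            ).to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path, sample_hz: Optional[float] = None,
                 meta: Optional[dict] = None) -> "CardiacTrace":
        df = pd.read_csv(path, comment="#")
        missing = [c for c in TRACE_COLUMNS if c not in df.columns]
        if missing:
            raise TraceError(f"trace file {path} lacks columns {missing}")
        t = df["time_s"].to_numpy(float)
        if sample_hz is None:
            if t.size < 2:
                raise TraceError("cannot infer sample rate from <2 samples")
            sample_hz = 1.0 / float(np.median(np.diff(t)))
        return cls(t, df["signal_mV"].to_numpy(float), df["temp_C"].to_numpy(float),
                   sample_hz, meta or {})


@dataclass
class HeartRateSeries:
    """Windowed heart rate (bpm) versus window-mean temperature."""

    temp_mid: np.ndarray  # deg C
    hr_bpm: np.ndarray
    n_beats: np.ndarray
    t_start: np.ndarray  # s, window start times
    window_s: float
    step_s: float

    def __len__(self) -> int:
        return len(self.temp_mid)

    def to_tsv(self, path, header_lines: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            pd.DataFrame(
                {"temp_mid_C": self.temp_mid, "hr_bpm": self.hr_bpm,
                 "n_beats": self.n_beats}
            ).to_csv(fh, sep="\t", index=False)


@dataclass(frozen=True)
class FlatlineCall:
    """The first window of a terminal sub-threshold run: the ULT call."""

    ULT: float  # deg C
    onset_time: float  # s, start of the flatlined run
    criterion: str


def bartlett_smooth(trace: CardiacTrace, window_s: float) -> CardiacTrace:
    """Convolve the signal with a unit-sum triangular (Bartlett) kernel.

    Length is preserved; edge windows are renormalized by the local kernel
    mass so a constant signal passes through unchanged. Time and temperature
    channels are untouched.
    """
    if not 0 < window_s < trace.duration:
        raise TraceError("window_s must be positive and shorter than the trace")
    m = int(round(window_s * trace.sample_hz))
    if m < 3:
        raise TraceError(f"smoothing window of {m} samples is below the 3-sample minimum")
    if m % 2 == 0:
        m += 1
    kernel = triang(m)
    kernel = kernel / kernel.sum()
    smoothed = np.convolve(trace.signal, kernel, mode="same")
    norm = np.convolve(np.ones_like(trace.signal), kernel, mode="same")
    return CardiacTrace(trace.time, smoothed / norm, trace.temp,
                        trace.sample_hz, dict(trace.meta))


def auto_prominence(trace: CardiacTrace, factor: float = 5.0) -> float:
    """Default peak prominence: ``factor`` x MAD of the median-centred signal.

    The MAD is robust to the beat pulses themselves (they occupy a minority
    of samples), so this tracks the sensor noise floor.
    """
    resid = trace.signal - np.median(trace.signal)
    mad = float(np.median(np.abs(resid - np.median(resid))))
    return max(factor * mad, 1e-9)


def detect_beats(
    trace: CardiacTrace,
    min_prominence: Optional[float] = None,
    refractory_s: float = 0.25,
    prominence_window_s: float = 1.0,
) -> np.ndarray:
    """Beat times: signal maxima with the stated prominence, spaced by a refractory gap.

    Prominence is evaluated within a ``prominence_window_s`` neighbourhood:
    over long quiescent stretches (a flatlined heart) an unbounded prominence
    would be measured against the deepest noise valleys and pass isolated
    noise maxima as beats. A flat or empty trace yields an empty array, not
    an error. When ``min_prominence`` is None it is set per-trace by
    :func:`auto_prominence`.
    """
    if not refractory_s > 0:
        raise TraceError("refractory_s must be positive")
    if trace.signal.size == 0 or np.ptp(trace.signal) == 0:
        return np.empty(0)
    if min_prominence is None:
        min_prominence = auto_prominence(trace)
    distance = max(int(round(refractory_s * trace.sample_hz)), 1)
    wlen = max(int(prominence_window_s * trace.sample_hz), 2 * distance + 1)
    idx, _ = find_peaks(trace.signal, prominence=min_prominence,
                        distance=distance, wlen=wlen)
    return trace.time[idx]


def hr_series(
    beats: np.ndarray,
    trace: CardiacTrace,
    window_s: float = 60.0,
    step_s: float = 30.0,
) -> HeartRateSeries:
    """Windowed rate: hr_bpm = 60 * n_beats / window_s, temp_mid = window-mean temp.

    Windows are indexed by start time and advance by ``step_s``; only full
    windows are emitted. Empty windows give 0 bpm.
    """
    if not (window_s >= step_s > 0):
        raise TraceError("require window_s >= step_s > 0")
    beats = np.asarray(beats, dtype=float)
    t0, t_end = trace.time[0], trace.time[-1]
    starts = []
    s = t0
    while s + window_s <= t_end + 1e-9:
        starts.append(s)
        s += step_s
    starts = np.asarray(starts)
    if starts.size == 0:
        raise TraceError("trace shorter than one window")
    n = np.searchsorted(beats, starts + window_s) - np.searchsorted(beats, starts)
    temp_mid = np.empty(starts.size)
    for i, st in enumerate(starts):
        sel = (trace.time >= st) & (trace.time < st + window_s)
        temp_mid[i] = trace.temp[sel].mean()
    return HeartRateSeries(temp_mid, 60.0 * n / window_s, n.astype(int),
                           starts, window_s, step_s)


def detect_flatline(
    series: HeartRateSeries,
    hr_floor: float = 5.0,
    sustain_s: float = 120.0,
) -> Optional[FlatlineCall]:
    """Call the ULT: first window starting a terminal sub-floor run of >= sustain_s.

    The run must persist to the end of the series — a transient flatline that
    recovers is not lethal and is not called. Returns None when no qualifying
    run exists. Requires a heating ramp (non-decreasing window temperatures).
    """
    if not hr_floor > 0:
        raise TraceError("hr_floor must be positive")
    if np.any(np.diff(series.temp_mid) < -1e-6):
        raise TraceError("flatline detection is defined on heating ramps only "
                         "(temp_mid must be non-decreasing)")
    below = series.hr_bpm < hr_floor
    if not below[-1]:
        return None
    # first index from which every window is below the floor
    i = len(below)
    while i > 0 and below[i - 1]:
        i -= 1
    run_duration = (series.t_start[-1] + series.window_s) - series.t_start[i]
    if run_duration < sustain_s:
        return None
    return FlatlineCall(
        ULT=float(series.temp_mid[i]),
        onset_time=float(series.t_start[i]),
        criterion=f"hr<{hr_floor}bpm sustained >= {sustain_s}s to trace end",
    )
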