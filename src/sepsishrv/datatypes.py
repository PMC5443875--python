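"""Shared signal containers for the ECG → RR → tachogram pipeline.

Units follow field convention: beat times in seconds, RR intervals in
milliseconds, ECG amplitude in millivolts, sampling rates in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: per-beat quality flags
FLAG_NORMAL = "normal"
FLAG_INTERPOLATED = "interpolated"
FLAG_REJECTED = "rejected"

#: physiological RR screen for rat, in ms (HR 120–1200 bpm)
RAT_RR_MIN_MS = 50.0
RAT_RR_MAX_MS = 500.0


@dataclass
class ECGRecord:
    """Single-lead ECG voltage trace.

    Parameters
    ----------
    samples : array of mV values
    sampling_rate : Hz
    start_time : time of the first sample, s
    ground_truth_beats : optional true beat times (s) carried by the
        simulator so detector output can be scored against them.
    """

    samples: np.ndarray
    sampling_rate: float
    start_time: float = 0.0
    ground_truth_beats: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("ECG samples must be finite")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.sampling_rate


@dataclass
class BeatSeries:
    """Detected R-peak times (s, strictly ascending) and RR intervals (ms).

    ``rr[i]`` is the interval ending at ``r_times[i+1]``; ``quality_flags``
    has one entry per beat.
    """

    r_times: np.ndarray
    quality_flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.r_times = np.asarray(self.r_times, dtype=float)
        if self.r_times.ndim != 1:
            raise ValueError("r_times must be 1-D")
        if self.r_times.size >= 2 and not np.all(np.diff(self.r_times) > 0):
            raise ValueError("r_times must be strictly ascending")
        if not self.quality_flags:
            self.quality_flags = [FLAG_NORMAL] * self.r_times.size
        if len(self.quality_flags) != self.r_times.size:
            raise ValueError("one quality flag per beat required")

    @property
    def n_beats(self) -> int:
        return int(self.r_times.size)

    @property
    def rr(self) -> np.ndarray:
        """RR intervals in milliseconds."""
        return np.diff(self.r_times) * 1000.0

    @property
    def rr_times(self) -> np.ndarray:
        """Time stamp (s) of each RR interval: the terminating beat."""
        return self.r_times[1:]

    def physiological_screen(
        self, rr_min: float = RAT_RR_MIN_MS, rr_max: float = RAT_RR_MAX_MS
    ) -> np.ndarray:
        """Boolean mask of RR intervals inside the rodent screen (ms)."""
        rr = self.rr
        return (rr >= rr_min) & (rr <= rr_max)


@dataclass
class Tachogram:
    """Evenly resampled RR signal, ready for spectral analysis.

    values are RR in ms on a uniform grid at ``sampling_rate`` Hz starting
    at ``origin_time`` seconds.
    """

    values: np.ndarray
    sampling_rate: float = 10.0
    detrended: bool = False
    origin_time: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("tachogram values must be finite")

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def duration(self) -> float:
        return self.values.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.origin_time + np.arange(self.values.size) / self.sampling_rate
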