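"""Synthetic cardiac-autonomic data generators.

This module produces every input the analysis pipeline consumes:

* RR-interval sequences from an integral pulse frequency modulation (IPFM)
  model, the standard physiological model linking autonomic modulation of
  the sinus node to beat timing.  A beat is emitted each time the integral
  of the modulated rate ``(1 + m(t)) / T`` crosses a successive integer,
  where ``T`` is the mean RR interval and ``m`` a zero-mean modulation made
  of sinusoids (prescribed VLF/LF/HF content) plus band-limited broadband
  noise.
* Template ECG waveforms at 1 kHz with a QRS complex at each simulated beat
  time; the true beat times travel with the record so detectors can be
  scored against ground truth.
* Cohort tables that emulate the published group structure (sham, sepsis
  good prognosis, sepsis bad prognosis) by independent normal draws from
  per-variable mean ± SEM profiles, with SD = SEM * sqrt(n).
* Survival tables with all sham animals censored at the horizon and a
  configurable septic mortality fraction.

All generators are fully seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq

from .datatypes import BeatSeries, ECGRecord

__all__ = [
    "ModulationSpec",
    "ECGTemplate",
    "GroupProfile",
    "simulate_rr_ipfm",
    "simulate_stationary_tachogram",
    "simulate_ecg",
    "simulate_cohort",
    "simulate_survival",
    "TABLE1_PROFILES",
    "TABLE2_PROFILES",
]

#: broadband modulation is represented on this grid (Hz) and spline-interpolated,
#: which band-limits it to below the 5 Hz Nyquist of the 10 Hz tachogram
_BROADBAND_GRID_HZ = 10.0


@dataclass
class ModulationSpec:
    """Prescription for the IPFM modulation signal.

    Parameters
    ----------
    mean_rr : mean RR interval, ms.
    components : list of ``(frequency_hz, amplitude, phase_rad)`` sinusoids;
        a 2-tuple ``(frequency, amplitude)`` is accepted and gets phase 0.
        Amplitudes are dimensionless fractions of the mean rate.
    broadband_sd : SD of the band-limited broadband modulation (dimensionless).
    duration : length of RR sequence to produce, s.
    """

    mean_rr: float
    components: list[tuple] = field(default_factory=list)
    broadband_sd: float = 0.0
    duration: float = 360.0

    def __post_init__(self) -> None:
        self.components = [
            (float(c[0]), float(c[1]), float(c[2]) if len(c) > 2 else 0.0)
            for c in self.components
        ]
        if self.mean_rr <= 0:
            raise ValueError("mean_rr must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.broadband_sd < 0:
            raise ValueError("broadband_sd must be non-negative")
        for f, a, _ in self.components:
            if f <= 0 or f > 5.0:
                raise ValueError(
                    "component frequencies must lie in (0, 5] Hz "
                    "(Nyquist of the 10 Hz tachogram)"
                )
            if a < 0:
                raise ValueError("component amplitudes must be non-negative")
        if self.amplitude_sum >= 1.0:
            raise ValueError(
                "sum of modulation amplitudes must be < 1 so the "
                "instantaneous rate stays positive"
            )

    @property
    def amplitude_sum(self) -> float:
        return float(sum(a for _, a, _ in self.components))


def simulate_rr_ipfm(spec: ModulationSpec, seed: int) -> BeatSeries:
    """Generate a beat sequence from the IPFM model.

    Beat times are the crossings of successive integers by
    ``I(t) = (1/T) ∫ (1 + m(τ)) dτ``; each crossing is located by bracketed
    bisection (Brent) to 1e-6 s, well below one ECG sample at 1 kHz.

    Returns a :class:`BeatSeries` whose RR sequence spans at least
    ``spec.duration`` seconds.  Same spec and seed give bitwise-identical
    beat times.
    """
    rng = np.random.default_rng(seed)
    T = spec.mean_rr / 1000.0  # s
    amp = spec.amplitude_sum
    # clip broadband tails so 1 + m(t) stays strictly positive
    b_clip = min(4.0 * spec.broadband_sd, 0.99 - amp)
    # worst-case slowest instantaneous rate -> longest possible interval
    m_floor = -(amp + b_clip)
    max_interval = T / (1.0 + m_floor)

    horizon = spec.duration + 3.0 * max_interval
    if spec.broadband_sd > 0:
        dt = 1.0 / _BROADBAND_GRID_HZ
        grid = np.arange(0.0, horizon + 2 * dt, dt)
        b = rng.normal(0.0, spec.broadband_sd, size=grid.size)
        b = np.clip(b, -b_clip, b_clip)
        B = CubicSpline(grid, b).antiderivative()
    else:
        B = None

    freqs = np.array([f for f, _, _ in spec.components])
    amps = np.array([a for _, a, _ in spec.components])
    phases = np.array([p for _, _, p in spec.components])

    def integral(t: float) -> float:
        """I(t): integrated rate in beats, I(0) = 0."""
        val = t
        if freqs.size:
            w = 2.0 * np.pi * freqs
            val += float(
                np.sum(amps / w * (np.cos(phases) - np.cos(w * t + phases)))
            )
        if B is not None:
            val += float(B(t))
        return val / T

    beats = [0.0]
    k = 1
    t_prev = 0.0
    while t_prev < spec.duration:
        lo = t_prev
        hi = t_prev + max_interval
        # expand bracket defensively (clipping keeps rate positive, so finite)
        while integral(hi) < k:
            hi += max_interval
        t_k = brentq(lambda t: integral(t) - k, lo, hi, xtol=1e-6)
        beats.append(t_k)
        t_prev = t_k
        k += 1

    if len(beats) < 2:
        raise ValueError("duration too short to produce at least 2 beats")
    return BeatSeries(r_times=np.asarray(beats))


def _gaussian_bump(
    t: np.ndarray, center: float, width_s: float, amplitude: float
) -> np.ndarray:
    # width is the full wave width; treat as 6 sigma so the bump is contained
    sigma = width_s / 6.0
    return amplitude * np.exp(-0.5 * ((t - center) / sigma) ** 2)


@dataclass
class ECGTemplate:
    """Morphology template for synthetic single-lead ECG.

    ``p_wave`` / ``t_wave`` are optional ``(width_ms, amplitude_mv,
    offset_ms)`` tuples giving each wave's width, peak amplitude and center
    offset relative to the R peak (negative offset = before the R peak).
    """

    qrs_width: float = 12.0  # ms; rodent QRS is narrow
    qrs_amplitude: float = 1.0  # mV
    p_wave: tuple[float, float, float] | None = (20.0, 0.1, -40.0)
    t_wave: tuple[float, float, float] | None = (30.0, 0.2, 40.0)
    noise_sd: float = 0.0  # mV
    sampling_rate: float = 1000.0  # Hz

    def __post_init__(self) -> None:
        if self.qrs_width <= 0:
            raise ValueError("qrs_width must be positive")
        if self.qrs_amplitude == 0:
            raise ValueError("qrs_amplitude must be nonzero")
        if self.sampling_rate < 250:
            raise ValueError("sampling_rate must be at least 250 Hz")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def simulate_ecg(beats: BeatSeries, template: ECGTemplate, seed: int) -> ECGRecord:
    """Render an ECG voltage trace with one QRS complex per beat.

    Gaussian bumps (QRS, optional P and T waves) are centered at each beat
    time; additive white Gaussian noise of ``template.noise_sd`` mV is
    applied.  The record carries the beat times as ground-truth metadata.
    """
    if beats.n_beats < 2:
        raise ValueError("at least 2 beats required")
    rr_s = np.diff(beats.r_times)
    if np.any(rr_s * 1000.0 < template.qrs_width):
        raise ValueError("beat spacing shorter than QRS width: complexes overlap")

    fs = template.sampling_rate
    t_end = beats.r_times[-1] + 0.1
    n = int(np.ceil(t_end * fs)) + 1
    t = np.arange(n) / fs
    signal = np.zeros(n)

    waves = [(template.qrs_width, template.qrs_amplitude, 0.0)]
    if template.p_wave is not None:
        waves.append(template.p_wave)
    if template.t_wave is not None:
        waves.append(template.t_wave)

    for center in beats.r_times:
        for width_ms, amp_mv, offset_ms in waves:
            c = center + offset_ms / 1000.0
            w = width_ms / 1000.0
            lo = max(0, int((c - w) * fs))
            hi = min(n, int((c + w) * fs) + 1)
            if hi > lo:
                signal[lo:hi] += _gaussian_bump(t[lo:hi], c, w, amp_mv)

    if template.noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, template.noise_sd, size=n)

    return ECGRecord(
        samples=signal,
        sampling_rate=fs,
        start_time=0.0,
        ground_truth_beats=beats.r_times.copy(),
    )


def simulate_stationary_tachogram(
    seed: int,
    duration: float = 1800.0,
    fs: float = 10.0,
    vlf: tuple[float, float, float] = (0.05, 0.15, 2.0),
    lf: tuple[float, float, float] = (0.3, 0.5, 9.0),
    hf: tuple[float, float, float] = (1.2, 1.8, 8.0),
    floor_power: float = 0.5,
    mean_rr: float = 0.0,
):
    """Stationary Gaussian tachogram with smooth band-shaped spectrum.

    Each ``(low_hz, high_hz, power_ms2)`` component is order-2
    Butterworth band-pass filtered white noise scaled to the requested
    power, plus a white floor — broad spectral peaks like real HRV rather
    than pure lines.  Returned detrended (zero-mean) unless ``mean_rr`` is
    nonzero.  Default band powers give the LF-dominant, HF-strong pattern
    typical of anesthetized rat recordings.
    """
    from scipy.signal import butter, filtfilt

    from .datatypes import Tachogram

    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))

    def band_noise(lo: float, hi: float, power: float) -> np.ndarray:
        w = rng.standard_normal(n)
        b, a = butter(2, [lo / (fs / 2), hi / (fs / 2)], "bandpass")
        x = filtfilt(b, a, w)
        return x * np.sqrt(power / x.var())

    x = sum(band_noise(lo, hi, p) for lo, hi, p in (vlf, lf, hf))
    if floor_power > 0:
        x = x + rng.standard_normal(n) * np.sqrt(floor_power)
    return Tachogram(
        values=x + mean_rr,
        sampling_rate=fs,
        detrended=(mean_rr == 0.0),
    )


@dataclass
class GroupProfile:
    """Per-group mean ± SEM profile for cohort simulation.

    ``variables`` maps variable name to ``(mean, sem)``.  Draws are
    independent normals with SD = SEM * sqrt(n), the inversion of how the
    source tables report dispersion.
    """

    name: str
    n: int
    variables: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size n must be >= 1")
        for var, (mean, sem) in self.variables.items():
            if sem < 0:
                raise ValueError(f"SEM for {var!r} must be non-negative")


# Published 24-h group profiles (mean, SEM): clinical severity and
# hemodynamics for sham (n=8), sepsis good prognosis (n=6), sepsis bad
# prognosis (n=5).
TABLE1_PROFILES: list[GroupProfile] = [
    GroupProfile(
        "sham",
        8,
        {
            "severity": (2, 1),
            "map_mmhg": (121, 6),
            "peak_velocity": (0.97, 0.03),
            "heart_rate": (426, 13),
            "stroke_volume": (0.24, 0.01),
            "cardiac_output": (103, 2),
        },
    ),
    GroupProfile(
        "sepsis_good",
        6,
        {
            "severity": (3, 2),
            "map_mmhg": (109, 5),
            "peak_velocity": (1.18, 0.06),
            "heart_rate": (451, 18),
            "stroke_volume": (0.26, 0.02),
            "cardiac_output": (115, 5),
        },
    ),
    GroupProfile(
        "sepsis_bad",
        5,
        {
            "severity": (4, 1),
            "map_mmhg": (106, 8),
            "peak_velocity": (0.85, 0.04),
            "heart_rate": (474, 14),
            "stroke_volume": (0.18, 0.01),
            "cardiac_output": (85, 5),
        },
    ),
]

# Circulating hormones, cytokines and oxidative/nitrosative markers at 24 h
# (subset of animals assayed: n = 6 / 5 / 4).
TABLE2_PROFILES: list[GroupProfile] = [
    GroupProfile(
        "sham",
        6,
        {
            "adrenaline": (3.6, 0.6),
            "vasopressin": (73, 11),
            "cortisol": (4.5, 0.4),
            "tnf": (355, 48),
            "il1": (17, 4),
            "il6": (70, 28),
            "il10": (49, 6),
            "nox": (37, 7),
            "carbonyl": (1.2, 0.1),
        },
    ),
    GroupProfile(
        "sepsis_good",
        5,
        {
            "adrenaline": (3.9, 0.5),
            "vasopressin": (64, 13),
            "cortisol": (3.4, 0.5),
            "tnf": (265, 60),
            "il1": (47, 11),
            "il6": (83, 22),
            "il10": (105, 37),
            "nox": (98, 23),
            "carbonyl": (2.2, 0.5),
        },
    ),
    GroupProfile(
        "sepsis_bad",
        4,
        {
            "adrenaline": (3.3, 0.4),
            "vasopressin": (22, 8),
            "cortisol": (3.4, 0.5),
            "tnf": (350, 55),
            "il1": (13, 3),
            "il6": (56, 9),
            "il10": (78, 27),
            "nox": (25, 6),
            "carbonyl": (2.6, 0.7),
        },
    ),
]


def simulate_cohort(profiles: list[GroupProfile], seed: int) -> pd.DataFrame:
    """Draw one row per animal from group mean ± SEM profiles.

    Values drawn below zero are truncated at 0 and recorded in the
    ``truncated_fields`` column (physiologic floor; truncation rather than
    redraw keeps draws independent and auditable).  The integer-valued
    clinical severity score, if present, is rounded and clipped to 0–12.
    """
    if not profiles:
        raise ValueError("at least one group profile required")
    rng = np.random.default_rng(seed)
    rows = []
    animal = 0
    for prof in profiles:
        sds = {v: sem * np.sqrt(prof.n) for v, (_, sem) in prof.variables.items()}
        for _ in range(prof.n):
            animal += 1
            row: dict = {"animal_id": f"A{animal:03d}", "group": prof.name}
            truncated = []
            for var, (mean, _) in prof.variables.items():
                val = rng.normal(mean, sds[var]) if sds[var] > 0 else float(mean)
                if val < 0:
                    val = 0.0
                    truncated.append(var)
                if var == "severity":
                    val = float(np.clip(np.round(val), 0, 12))
                row[var] = val
            row["truncated_fields"] = ";".join(truncated)
            rows.append(row)
    return pd.DataFrame(rows)


def simulate_survival(
    n_sham: int,
    n_sepsis: int,
    sepsis_mortality: float,
    horizon: float = 24.0,
    seed: int = 0,
    deterministic_count: bool = True,
) -> pd.DataFrame:
    """Simulate a two-arm survival table over ``horizon`` hours.

    Sham animals are all censored at the horizon.  With
    ``deterministic_count`` the number of septic deaths is exactly
    ``round(n_sepsis * sepsis_mortality)``; otherwise each septic animal
    dies with probability ``sepsis_mortality`` (Bernoulli mode).  Death
    times are uniform on (0, horizon).
    """
    if not 0.0 <= sepsis_mortality <= 1.0:
        raise ValueError("sepsis_mortality must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_sham):
        rows.append(
            {"animal_id": f"S{i + 1:03d}", "group": "sham",
             "time_h": horizon, "event": 0}
        )
    if deterministic_count:
        n_deaths = int(round(n_sepsis * sepsis_mortality))
        dying = rng.choice(n_sepsis, size=n_deaths, replace=False)
        died = np.zeros(n_sepsis, dtype=bool)
        died[dying] = True
    else:
        died = rng.random(n_sepsis) < sepsis_mortality
    for i in range(n_sepsis):
        if died[i]:
            t = float(rng.uniform(0.0, horizon))
            while t == 0.0:  # open interval
                t = float(rng.uniform(0.0, horizon))
            rows.append(
                {"animal_id": f"P{i + 1:03d}", "group": "sepsis",
                 "time_h": t, "event": 1}
            )
        else:
            rows.append(
                {"animal_id": f"P{i + 1:03d}", "group": "sepsis",
                 "time_h": horizon, "event": 0}
            )
    return pd.DataFrame(rows)
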