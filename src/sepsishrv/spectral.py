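"""Autoregressive spectral analysis of the RR tachogram.

The HRV indices follow the rat-specific band scheme: VLF (0, 0.2] Hz,
LF (0.2, 0.75] Hz, HF (0.75, 3] Hz on a 10 Hz tachogram.  Each recording
is split into 3-min segments with 50 % overlap; per segment an AR model
(Burg, default order 16) is fitted to the detrended tachogram, the
parametric PSD is integrated over the bands, and the per-segment indices
are arithmetically averaged.

Normalized units are LF% = LF / (LF + HF) * 100 and HF% analogously, i.e.
the denominator is the in-band total power above the VLF edge, so the two
always sum to 100.  The reported total power is the full-spectrum integral
over (0, Nyquist], which therefore exceeds VLF + LF + HF slightly.

The PSD is one-sided (density 2 * sigma^2 / (fs * |A|^2)), so band
integrals are in ms^2 and the full-spectrum integral equals the process
variance (Parseval).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.regression.linear_model import burg as _burg
from statsmodels.regression.linear_model import yule_walker as _yule_walker

from .datatypes import Tachogram
from .ecg import detrend_tachogram

__all__ = [
    "SpectralBands",
    "ARSpectrum",
    "HRVIndices",
    "segment_tachogram",
    "fit_ar",
    "select_ar_order_aic",
    "ar_psd",
    "band_powers",
    "hrv_indices",
]

DEFAULT_AR_ORDER = 16
DEFAULT_N_FREQ = 2048


@dataclass(frozen=True)
class SpectralBands:
    """Half-open (low, high] frequency bands, Hz."""

    vlf: tuple[float, float] = (0.0, 0.2)
    lf: tuple[float, float] = (0.2, 0.75)
    hf: tuple[float, float] = (0.75, 3.0)

    def __post_init__(self) -> None:
        lo = [self.vlf[0], self.lf[0], self.hf[0]]
        hi = [self.vlf[1], self.lf[1], self.hf[1]]
        if not all(h > l for l, h in zip(lo, hi)):
            raise ValueError("each band must have high > low")
        if not (self.vlf[1] == self.lf[0] and self.lf[1] == self.hf[0]):
            raise ValueError("bands must be contiguous and ascending")
        if self.hf[1] > 5.0:
            raise ValueError("HF upper edge must not exceed the 5 Hz Nyquist")


@dataclass
class ARSpectrum:
    """Fitted all-pole model: x_t = sum_k a_k x_{t-k} + e_t, var(e) = sigma2."""

    coefficients: np.ndarray
    innovation_variance: float
    sampling_rate: float

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.innovation_variance <= 0:
            raise ValueError("innovation variance must be positive")

    @property
    def order(self) -> int:
        return int(self.coefficients.size)

    def is_stable(self) -> bool:
        """All characteristic roots strictly inside the unit circle."""
        if self.order == 0:
            return True
        poly = np.concatenate([[1.0], -self.coefficients])
        roots = np.roots(poly)  # roots of z^p - a1 z^{p-1} - ... - ap
        return bool(np.all(np.abs(roots) < 1.0))


@dataclass
class HRVIndices:
    """Band powers (ms^2), sympathovagal ratio and normalized units (%).

    Undefined ratios (HF power 0, or no power above the VLF edge) are NaN,
    never infinity, so downstream statistics stay well-defined.
    """

    vlf_power: float
    lf_power: float
    hf_power: float
    total_power: float
    lf_hf: float
    lf_norm: float
    hf_norm: float
    n_segments: int = 1

    def to_dict(self) -> dict[str, float]:
        return {
            "vlf_power": self.vlf_power,
            "lf_power": self.lf_power,
            "hf_power": self.hf_power,
            "total_power": self.total_power,
            "lf_hf": self.lf_hf,
            "lf_norm": self.lf_norm,
            "hf_norm": self.hf_norm,
            "n_segments": self.n_segments,
        }


def segment_tachogram(
    t: Tachogram, length: float = 180.0, overlap: float = 0.5
) -> list[Tachogram]:
    """Split a tachogram into full-length overlapping windows.

    Windows start every ``length * (1 - overlap)`` seconds; only windows
    that fit entirely are returned and the trailing remainder is dropped.
    """
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must be in [0, 1)")
    if t.duration < length:
        raise ValueError(
            f"recording too short: {t.duration:.1f} s < segment length {length} s"
        )
    n_win = int(round(length * t.sampling_rate))
    step = int(round(length * (1.0 - overlap) * t.sampling_rate))
    out = []
    start = 0
    while start + n_win <= t.n:
        out.append(
            Tachogram(
                values=t.values[start : start + n_win],
                sampling_rate=t.sampling_rate,
                detrended=t.detrended,
                origin_time=t.origin_time + start / t.sampling_rate,
            )
        )
        start += step
    return out


def fit_ar(
    segment: Tachogram, order: int = DEFAULT_AR_ORDER, method: str = "burg"
) -> ARSpectrum:
    """Fit a stable AR model to a detrended tachogram segment.

    Burg (default) maximizes forward/backward prediction accuracy and is
    numerically stable on short segments; the innovation variance is the
    final prediction error of the recursion.  Yule–Walker is retained as an
    independent cross-check route.
    """
    if not segment.detrended:
        raise ValueError("segment must be detrended before AR fitting")
    x = np.asarray(segment.values, dtype=float)
    if order < 1:
        raise ValueError("order must be >= 1")
    if order >= x.size / 2:
        raise ValueError("order must be < half the segment length")
    if method == "burg":
        coefs, sigma2 = _burg(x, order=order, demean=True)
    elif method == "yule_walker":
        coefs, sigma = _yule_walker(x, order=order, method="mle")
        sigma2 = float(sigma) ** 2
    else:
        raise ValueError(f"unknown AR method {method!r}")
    model = ARSpectrum(
        coefficients=np.asarray(coefs),
        innovation_variance=float(sigma2),
        sampling_rate=segment.sampling_rate,
    )
    if not model.is_stable():
        raise ValueError("unstable AR fit rejected")
    return model


def select_ar_order_aic(
    segment: Tachogram, orders: range = range(8, 25), method: str = "burg"
) -> int:
    """Pick the AR order minimizing AIC = n log(sigma2) + 2 order."""
    n = segment.n
    best_order, best_aic = None, np.inf
    for p in orders:
        try:
            model = fit_ar(segment, order=p, method=method)
        except ValueError:
            continue
        aic = n * np.log(model.innovation_variance) + 2 * p
        if aic < best_aic:
            best_order, best_aic = p, aic
    if best_order is None:
        raise ValueError("no admissible AR order in the candidate range")
    return best_order


def ar_psd(
    model: ARSpectrum, n_freq: int = DEFAULT_N_FREQ
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided parametric PSD of an AR model.

    Returns ``(freqs, density)``; density is
    ``2 sigma^2 / (fs |A(e^{-i 2 pi f / fs})|^2)`` in ms^2/Hz, so the
    integral over (0, fs/2] recovers the process variance.

    The grid is uniform over [0, fs/2] plus local refinement around each
    resonant pole: near-unit-circle poles produce spectral lines far
    narrower than any practical uniform spacing, and without refinement
    their (often dominant) mass is lost to the trapezoidal band integrals.
    Refinement points are sinh-spaced over +/- 30 half-widths of each line.
    """
    if not model.is_stable():
        raise ValueError("PSD undefined for unstable model")
    fs = model.sampling_rate
    freqs = np.linspace(0.0, fs / 2.0, n_freq)
    if model.order > 0:
        poly = np.concatenate([[1.0], -model.coefficients])
        roots = np.roots(poly)
        extra = []
        u = np.sinh(np.linspace(-np.arcsinh(30.0), np.arcsinh(30.0), 301))
        for root in roots:
            if root.imag <= 0:
                continue  # conjugate pairs: keep upper half-plane only
            f0 = np.angle(root) * fs / (2.0 * np.pi)
            half_width = max((1.0 - np.abs(root)) * fs / (2.0 * np.pi), 1e-9)
            pts = f0 + half_width * u
            extra.append(pts[(pts > 0.0) & (pts < fs / 2.0)])
        if extra:
            freqs = np.unique(np.concatenate([freqs] + extra))
    k = np.arange(1, model.order + 1)
    # A(f) = 1 - sum_k a_k exp(-i 2 pi f k / fs)
    phase = np.exp(-2j * np.pi * np.outer(freqs, k) / fs)
    a_f = 1.0 - phase @ model.coefficients
    density = 2.0 * model.innovation_variance / (fs * np.abs(a_f) ** 2)
    return freqs, density


def _band_integral(
    freqs: np.ndarray, density: np.ndarray, lo: float, hi: float
) -> float:
    """Trapezoidal integral of the density over [lo, hi], with the band
    edges inserted by linear interpolation so bands partition the total."""
    if hi <= freqs[0] or lo >= freqs[-1]:
        return 0.0
    lo = max(lo, freqs[0])
    hi = min(hi, freqs[-1])
    inner = (freqs > lo) & (freqs < hi)
    f = np.concatenate([[lo], freqs[inner], [hi]])
    d = np.concatenate(
        [[np.interp(lo, freqs, density)], density[inner], [np.interp(hi, freqs, density)]]
    )
    return float(np.trapezoid(d, f))


def band_powers(
    freqs: np.ndarray,
    density: np.ndarray,
    bands: SpectralBands | None = None,
) -> HRVIndices:
    """Integrate a PSD over the VLF/LF/HF bands for one segment.

    Total power is the full-spectrum integral over (0, fs/2].  The LF/HF
    ratio and the normalized units are NaN when their denominators vanish.
    """
    if bands is None:
        bands = SpectralBands()
    freqs = np.asarray(freqs, float)
    density = np.asarray(density, float)
    if np.any(density < 0):
        raise ValueError("PSD density must be non-negative")
    if freqs[-1] < bands.hf[1]:
        raise ValueError("PSD grid must cover the HF band")
    vlf = _band_integral(freqs, density, *bands.vlf)
    lf = _band_integral(freqs, density, *bands.lf)
    hf = _band_integral(freqs, density, *bands.hf)
    total = _band_integral(freqs, density, 0.0, freqs[-1])
    lf_hf = lf / hf if hf > 0 else np.nan
    above_vlf = lf + hf  # in-band total minus VLF
    if above_vlf > 0:
        lf_norm = lf / above_vlf * 100.0
        hf_norm = hf / above_vlf * 100.0
    else:
        lf_norm = hf_norm = np.nan
    return HRVIndices(
        vlf_power=vlf,
        lf_power=lf,
        hf_power=hf,
        total_power=total,
        lf_hf=lf_hf,
        lf_norm=lf_norm,
        hf_norm=hf_norm,
        n_segments=1,
    )


def hrv_indices(
    t: Tachogram,
    ar_order: int = DEFAULT_AR_ORDER,
    method: str = "burg",
    segment_length: float = 180.0,
    overlap: float = 0.5,
    bands: SpectralBands | None = None,
    n_freq: int = DEFAULT_N_FREQ,
    detrend_strength: float = 500.0,
) -> HRVIndices:
    """Full spectral chain for one recording.

    segment -> detrend (if not already) -> AR fit -> PSD -> band powers;
    per-segment indices are arithmetically averaged (NaN segments excluded
    per index) and the segment count recorded.
    """
    segments = segment_tachogram(t, length=segment_length, overlap=overlap)
    per_segment = []
    for i, seg in enumerate(segments):
        try:
            if not seg.detrended:
                seg = detrend_tachogram(seg, strength=detrend_strength)
            if np.var(seg.values) < 1e-10:
                # zero-variance limit (e.g. metronomic RR): no spectral power
                per_segment.append(
                    HRVIndices(0.0, 0.0, 0.0, 0.0, np.nan, np.nan, np.nan)
                )
                continue
            model = fit_ar(seg, order=ar_order, method=method)
            freqs, density = ar_psd(model, n_freq=n_freq)
            per_segment.append(band_powers(freqs, density, bands))
        except ValueError as exc:
            raise ValueError(f"segment {i}: {exc}") from exc
    keys = ["vlf_power", "lf_power", "hf_power", "total_power",
            "lf_hf", "lf_norm", "hf_norm"]
    stacked = {k: np.array([getattr(s, k) for s in per_segment]) for k in keys}
    with np.errstate(invalid="ignore"):
        averaged = {
            k: (float(np.nanmean(v)) if not np.all(np.isnan(v)) else np.nan)
            for k, v in stacked.items()
        }
    return HRVIndices(n_segments=len(per_segment), **averaged)
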