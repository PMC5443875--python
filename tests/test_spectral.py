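"""AR spectral estimation and HRV index tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import lfilter

from sepsishrv.datatypes import Tachogram
from sepsishrv.ecg import build_tachogram, detrend_tachogram
from sepsishrv.simulate import (
    ModulationSpec,
    simulate_rr_ipfm,
    simulate_stationary_tachogram,
)
from sepsishrv.spectral import (
    ARSpectrum,
    SpectralBands,
    ar_psd,
    band_powers,
    fit_ar,
    hrv_indices,
    segment_tachogram,
    select_ar_order_aic,
)


def _white_segment(seed, n=1800, fs=10.0):
    rng = np.random.default_rng(seed)
    return Tachogram(values=rng.standard_normal(n), sampling_rate=fs,
                     detrended=True)


class TestSegmentation:
    @pytest.mark.parametrize("minutes,expected", [(6, 3), (8, 4), (9, 5)])
    def test_segment_counts(self, minutes, expected):
        """3-min windows stepping 1.5 min; trailing remainder dropped."""
        t = Tachogram(values=np.zeros(minutes * 60 * 10), sampling_rate=10.0)
        segs = segment_tachogram(t)
        assert len(segs) == expected
        assert all(s.n == 1800 for s in segs)

    def test_segment_start_times(self):
        t = Tachogram(values=np.zeros(3600), sampling_rate=10.0)
        segs = segment_tachogram(t)
        assert [s.origin_time for s in segs] == [0.0, 90.0, 180.0]

    def test_too_short_rejected(self):
        t = Tachogram(values=np.zeros(1200), sampling_rate=10.0)
        with pytest.raises(ValueError, match="too short"):
            segment_tachogram(t)


class TestARFit:
    def test_white_noise_small_coefficients(self):
        """Burg on white noise: every coefficient magnitude < 0.1 at
        n = 1800 (50 replicates)."""
        max_coef = max(
            np.max(np.abs(fit_ar(_white_segment(s), order=16).coefficients))
            for s in range(50)
        )
        assert max_coef < 0.1

    def test_known_ar4_recovery(self):
        """Parameter recovery: an AR(4) with two resonances is recovered
        within 5 % per coefficient at n = 10^4."""
        # poles at 1 Hz (r=0.8) and 3 Hz (r=0.7), fs = 10 Hz
        p1 = 0.8 * np.exp(2j * np.pi * 1.0 / 10.0)
        p2 = 0.7 * np.exp(2j * np.pi * 3.0 / 10.0)
        a_poly = np.real(np.poly([p1, np.conj(p1), p2, np.conj(p2)]))
        true_coefs = -a_poly[1:]  # x_t = sum a_k x_{t-k} + e_t
        rng = np.random.default_rng(0)
        x = lfilter([1.0], a_poly, rng.standard_normal(10_000))
        seg = Tachogram(values=x, sampling_rate=10.0, detrended=True)
        model = fit_ar(seg, order=4)
        np.testing.assert_allclose(model.coefficients, true_coefs, rtol=0.05)

    def test_yule_walker_close_to_burg(self):
        seg = simulate_stationary_tachogram(seed=0, duration=600.0)
        b = fit_ar(seg, order=16, method="burg")
        y = fit_ar(seg, order=16, method="yule_walker")
        f, db = ar_psd(b)
        _, dy = ar_psd(y)
        bp_b = band_powers(f, db)
        bp_y = band_powers(f, dy)
        assert abs(bp_b.lf_power - bp_y.lf_power) / bp_b.lf_power < 0.2
        assert abs(bp_b.hf_power - bp_y.hf_power) / bp_b.hf_power < 0.2

    def test_excessive_order_rejected(self):
        with pytest.raises(ValueError, match="order"):
            fit_ar(_white_segment(0, n=20), order=20)

    def test_not_detrended_rejected(self):
        t = Tachogram(values=np.random.default_rng(0).standard_normal(1800),
                      sampling_rate=10.0, detrended=False)
        with pytest.raises(ValueError, match="detrended"):
            fit_ar(t, order=16)

    def test_aic_order_selection_in_range(self):
        seg = simulate_stationary_tachogram(seed=3, duration=600.0)
        order = select_ar_order_aic(seg)
        assert 8 <= order <= 24


class TestARPSD:
    def test_white_model_flat_density(self):
        """Order-0 model: one-sided density 2 sigma^2 / fs everywhere."""
        model = ARSpectrum(coefficients=np.array([]), innovation_variance=4.0,
                           sampling_rate=10.0)
        f, d = ar_psd(model)
        np.testing.assert_allclose(d, 2.0 * 4.0 / 10.0)

    def test_resonant_pole_peak_location(self):
        """AR(2) with a pole at 1 Hz peaks within 0.02 Hz of 1 Hz."""
        r, f0, fs = 0.95, 1.0, 10.0
        theta = 2 * np.pi * f0 / fs
        coefs = np.array([2 * r * np.cos(theta), -(r**2)])
        model = ARSpectrum(coefficients=coefs, innovation_variance=1.0,
                           sampling_rate=fs)
        f, d = ar_psd(model)
        assert abs(f[np.argmax(d)] - f0) < 0.02

    def test_parseval(self):
        """PSD integral over (0, fs/2] matches the sample variance of a
        long realization within 1 %."""
        seg = _white_segment(1, n=100_000)
        model = fit_ar(seg, order=16)
        f, d = ar_psd(model)
        total = np.trapezoid(d, f)
        assert abs(total - seg.values.var()) / seg.values.var() < 0.01

    def test_unstable_model_rejected(self):
        model = ARSpectrum(coefficients=np.array([1.5]),
                           innovation_variance=1.0, sampling_rate=10.0)
        with pytest.raises(ValueError, match="unstable|undefined"):
            ar_psd(model)


class TestBandPowers:
    def test_concentrated_density_in_lf(self):
        """All power near 0.5 Hz lands in LF; HF is 0, LF norm is 100 and
        LF/HF is undefined (NaN, not inf)."""
        f = np.linspace(0, 5, 2048)
        d = np.zeros_like(f)
        center = np.argmin(np.abs(f - 0.5))
        d[center - 2 : center + 3] = 100.0
        bp = band_powers(f, d)
        assert bp.hf_power == 0.0
        assert bp.vlf_power == 0.0
        assert np.isclose(bp.lf_power, bp.total_power)
        assert np.isclose(bp.lf_norm, 100.0)
        assert np.isnan(bp.lf_hf)

    def test_flat_density_closed_form(self):
        """Flat density c over (0, 3]: band powers are width * c."""
        f = np.linspace(0, 5, 20001)
        c = 2.0
        d = np.where(f <= 3.0, c, 0.0)
        bp = band_powers(f, d)
        assert np.isclose(bp.vlf_power, 0.2 * c, rtol=1e-3)
        assert np.isclose(bp.lf_power, 0.55 * c, rtol=1e-3)
        assert np.isclose(bp.hf_power, 2.25 * c, rtol=1e-3)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_normalization_identity_property(self, seed):
        """lf_norm + hf_norm = 100 within 1e-6 for any non-degenerate PSD."""
        rng = np.random.default_rng(seed)
        f = np.linspace(0, 5, 512)
        d = rng.exponential(1.0, size=f.size)
        bp = band_powers(f, d)
        assert abs(bp.lf_norm + bp.hf_norm - 100.0) < 1e-6

    def test_grid_not_covering_hf_rejected(self):
        f = np.linspace(0, 2, 100)
        with pytest.raises(ValueError, match="HF"):
            band_powers(f, np.ones_like(f))

    def test_band_validation(self):
        with pytest.raises(ValueError, match="contiguous"):
            SpectralBands(vlf=(0.0, 0.2), lf=(0.3, 0.75), hf=(0.75, 3.0))
        with pytest.raises(ValueError, match="Nyquist"):
            SpectralBands(hf=(0.75, 6.0))


class TestHRVIndices:
    def test_single_lf_component_dominates(self):
        """IPFM with one 0.4 Hz component: averaged LF norm > 95."""
        spec = ModulationSpec(mean_rr=140.0, components=[(0.4, 0.05)],
                              duration=400.0)
        beats = simulate_rr_ipfm(spec, seed=0)
        tach = detrend_tachogram(build_tachogram(beats))
        idx = hrv_indices(tach)
        assert idx.lf_norm > 95.0
        assert idx.n_segments == 3

    def test_constant_rr_zero_power(self):
        """Metronomic RR: total power < 1 ms^2 (zero-variance limit)."""
        spec = ModulationSpec(mean_rr=140.0, components=[], duration=400.0)
        beats = simulate_rr_ipfm(spec, seed=0)
        idx = hrv_indices(detrend_tachogram(build_tachogram(beats)))
        assert idx.total_power < 1.0

    def test_hf_monotone_in_hf_amplitude(self):
        """Estimated HF power never decreases along an HF-amplitude ladder
        (median over seeds)."""
        ladder = [0.01, 0.02, 0.03, 0.04, 0.05]
        medians = []
        for a in ladder:
            vals = []
            for seed in range(5):
                spec = ModulationSpec(
                    mean_rr=140.0,
                    components=[(0.4, 0.03), (1.5, a)],
                    broadband_sd=0.01,
                    duration=200.0,
                )
                beats = simulate_rr_ipfm(spec, seed)
                t = detrend_tachogram(build_tachogram(beats))
                vals.append(hrv_indices(t, segment_length=180.0).hf_power)
            medians.append(np.median(vals))
        assert all(b >= a for a, b in zip(medians, medians[1:]))

    def test_averaging_invariance(self):
        """One 6-min segment vs averaged 3-min overlapping segments gives
        total power within 15 % on a stationary signal."""
        t = simulate_stationary_tachogram(seed=2, duration=360.0)
        one = hrv_indices(t, segment_length=360.0)
        many = hrv_indices(t, segment_length=180.0, overlap=0.5)
        assert one.n_segments == 1 and many.n_segments == 3
        assert abs(one.total_power - many.total_power) / one.total_power < 0.15
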