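# Methods

## Beat-sequence model (IPFM)

The generator uses integral pulse frequency modulation, the standard
physiological model linking autonomic modulation of the sinus node to
beat timing: beat k occurs at the time t_k where

    (1/T) ∫₀^{t_k} (1 + m(τ)) dτ = k,

with T the mean RR interval and m a zero-mean modulation. m is a sum of
sinusoids (each `(frequency, amplitude, phase)`) plus broadband noise
sampled on a 10 Hz grid and cubic-spline interpolated, which band-limits
it below the 5 Hz Nyquist of the downstream tachogram. Validity requires
Σ amplitudes < 1; broadband tails are clipped at ±4 SD (and never beyond
0.99 − Σa) so the instantaneous rate stays positive and the integral
strictly increasing. Each integer crossing is located by bracketed
root-finding (Brent) to 1e-6 s — three orders of magnitude below one ECG
sample — so simulated beat times are effectively exact for detector
scoring.

For small modulation the RR series approximates T·(1 − m(t)); a sinusoid
of amplitude a contributes RR power ≈ (aT)²/2, attenuated by the
interval-averaging factor sinc²(πfT). This linearization underlies the
spectral-peak and ratio-recovery checks: an amplitude ratio a_LF/a_HF =
√2 at similar sinc factors yields an LF:HF power ratio near 2.

## ECG synthesis and R-peak detection

ECG is rendered at 1 kHz (configurable ≥ 250 Hz) as Gaussian bumps: a
narrow QRS (default 12 ms wide, 1 mV) at each beat time plus optional P
and T waves and additive white Gaussian noise. Beat spacings shorter
than the QRS width are rejected as physically overlapping complexes.

Detection is a Pan–Tompkins-style chain with rodent settings: zero-phase
Butterworth band-pass 10–50 Hz (rat QRS is narrower and faster than
human), derivative, squaring, 30 ms moving-window integration, then an
adaptive threshold that tracks running signal and noise peak levels
(threshold = noise + 0.25·(signal − noise)) with a 60 ms refractory
period (supports heart rates up to 1000 bpm). Accepted detections are
refined to the raw-signal local maximum within ± half the integration
window; because every statistic in the chain scales linearly with the
input, detection is invariant to positive amplitude scaling. A flat or
sub-threshold record raises an explicit no-beats error rather than
returning an empty series.

## RR editing, tachogram, detrending

RR intervals deviating more than 30 % (configurable) from an 11-interval
running median are flagged and replaced by cubic interpolation through
the clean intervals; beat times are rebuilt from the corrected cumulative
sum, and recordings with more than 20 % flagged intervals are rejected as
unanalyzable. The replacement count is returned with the series. A physiological screen of 50–500 ms (rat) is available on the
interval series.

The tachogram attributes each RR interval to its terminating beat and
cubic-spline resamples onto a uniform 10 Hz grid spanning first to last
beat (no extrapolation). Detrending defaults to the smoothness-priors
regularized least squares (trend = (I + λ²D₂ᵀD₂)⁻¹ z, second-difference
D₂); λ = 500 at 10 Hz puts the effective high-pass cutoff near 0.09 Hz,
below the 0.2 Hz VLF upper edge, so LF and HF content passes essentially
unchanged (verified < 2 % HF-power change on ramp+sinusoid inputs). An
order-1 polynomial detrend is offered as a fallback. Output is exactly
zero-mean.

## AR spectral indices

Segments of 180 s with 50 % overlap (windows start every 90 s; trailing
remainder dropped). Per segment an AR model is fitted by Burg's method
(default order 16, conventional for short RR series; optional AIC
selection over 8–24; Yule–Walker retained as a cross-check route);
unstable fits are rejected. The one-sided PSD is

    S(f) = 2σ² / (fs·|A(e^{−i2πf/fs})|²),

so the integral over (0, fs/2] equals the process variance (Parseval,
verified to 1 %). The evaluation grid is 2048 uniform points over
[0, 5] Hz plus sinh-spaced refinement (±30 half-widths, 301 points)
around each resonant pole: near-unit-circle poles — which arise whenever
the modulation is tonal and broadband power is low — produce spectral
lines far narrower than any uniform spacing, and without refinement most
of their mass is lost to the trapezoidal band integrals.

Band powers integrate the PSD over VLF (0, 0.2], LF (0.2, 0.75] and
HF (0.75, 3] Hz (band edges inserted into the grid by interpolation so
the bands partition the spectrum exactly). Reported total power is the
full-spectrum integral over (0, Nyquist], and therefore slightly exceeds
VLF+LF+HF. Normalized units use the in-band total above the VLF edge:
LF% = LF/(LF+HF)×100 and HF% analogously — the conventional definition,
and the only one under which the two printed formulas sum to exactly
100; this identity is enforced to 1e-6. Undefined ratios (zero HF power,
no power above VLF) are reported as missing values, never infinities, so
downstream statistics stay well-defined. Per-segment indices (including
ratios and normalized units) are arithmetically averaged, skipping
undefined segments per index; segments with variance below 1e-10 ms²
(metronomic RR) short-circuit to zero power. Segment count is recorded.

## Hemodynamics and prognosis

Aortic cross-section is circular with a literature diameter of 2.6 mm
for rats of this age (per-animal overrides accepted): area = π(d/2)² in
cm². SV (ml) = VTI (cm) × area (cm²); CO (ml/min) = SV × HR (bpm). The
prognosis rule is strict: peak velocity must exceed 0.93 m/s for "good";
equality classifies as "bad" (the cutoff is configurable). A 0.2–2.5 m/s
physiologic screen on peak velocity warns without rejecting.

## Cohort, survival and statistics

Cohort tables are drawn per group from (mean, SEM) profiles with
SD = SEM·√n (the tables the profiles emulate report mean ± SEM);
variables are independent normals, negative draws are truncated at zero
and flagged (truncation rather than redraw keeps draws independent and
auditable), and the integer clinical severity score (sum of six 0/1/2
items, range 0–12) is rounded and clipped. The default profiles encode
the published group structure: hemodynamics/severity for 8 sham, 6
good-prognosis and 5 bad-prognosis animals, and hormones/cytokines for
the assayed subset (6/5/4). Because per-animal HRV values were never
published numerically, the group HRV contrast in the simulator is
qualitative by design — elevated LF and LF/HF in good-prognosis sepsis,
relatively higher vagal weight in bad prognosis — and tests assert
ordering, not absolute levels.

Survival: sham animals are censored at the horizon (24 h); septic deaths
are uniform on (0, horizon), with either an exact death count
(round(n × mortality), default, reproducing the published 8/19) or
per-animal Bernoulli draws.

Statistics follow the small-animal-cohort convention: a
Lilliefors-corrected KS normality gate at α = 0.05 (plain KS with
estimated parameters is anticonservative); Student's t or one-way ANOVA
with all-pairs Bonferroni (×3) post hocs when every group passes,
Mann–Whitney or Kruskal–Wallis with Bonferroni-adjusted pairwise rank
tests otherwise. Pairwise markers follow the source-table convention
(a: vs sham, b: vs good prognosis) on adjusted p-values. Spearman
correlations use pairwise-complete observations (minimum 5); group
comparisons use listwise deletion within each variable. Kaplan–Meier and
log-rank come from lifelines; with zero events the log-rank p is
reported missing.

## Synthetic-data scope

The generators emulate: beat-to-beat autonomic modulation with
prescribed band content (IPFM), stationary tachograms with smooth
band-shaped spectra (Butterworth-filtered noise; default VLF 2 / LF 9 /
HF 8 ms² + 0.5 ms² floor, the broad-peak shape of real HRV spectra),
clean-morphology ECG with additive white noise, independent-normal
cohort draws, and uniform death times. They do not emulate:
non-stationarity within recordings, ectopy and arrhythmia, respiratory
modulation coupling, baseline wander and electrode artifacts, inter-variable
correlations within animals (unless a correlation structure is supplied),
or any pathophysiological mechanism of sepsis — group differences are
purely distributional. Passing tests therefore demonstrate correctness
of the computational chain under controlled conditions, not robustness
to every artifact of real recordings.

## Validation conditions and problem sizes

The self-validation experiments (`sepsishrv.benchmarks`) use: 30-min
stationary tachograms, 25 seeds, for the AR-vs-Welch oracle comparison
(Welch with 4096-sample segments as the non-parametric reference);
400-s recordings at 20 dB SNR (QRS 1 mV, noise 0.1 mV), 25 seeds, for
LF:HF = 2.0 recovery through the full ECG chain; a 6-min recording at
450 bpm and 20 dB SNR with 10 ms matching tolerance for the detector
operating point; and 5000 replicates at n = 8 per group for the type-I
error of the gated two-group test. These sizes keep the full validation
suite to a few minutes on one CPU while leaving Monte-Carlo noise well
below the margins being tested.

## Known limitations

- The AR-vs-periodogram agreement degrades for purely tonal modulation
  with no broadband power (spectral lines): pole-grid refinement
  recovers the line mass, but relative band errors at hard band edges
  become sensitive to pole-frequency estimation error. Real HRV is not
  line-like; the stationary generator reflects that.
- SEM→SD inversion plus small group sizes means some published pairwise
  contrasts (e.g. the vasopressin bad-vs-good difference) have limited
  re-detection power on any single simulated draw; the statistics tests
  assert detection rates consistent with the actual power, not certainty.
- The detector is tuned for clean rodent morphology; it is not validated
  on human ECG, multi-lead records, or pathological waveforms.
- Hormone/cytokine draws are attached to the first animals of each group
  when merging the assay subset into the cohort (animal identity across
  the two source tables is not published).
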