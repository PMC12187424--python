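# Methods

Signal model, parameter defaults, generator scope and numerical design
choices for the `jvpradar` pipeline. Everything here describes what the
code computes; no claim is made that has not been measured by the test
suite or the acceptance script.

## 1. Signal model

### 1.1 FMCW beat signal

A linear chirp of bandwidth `B` over duration `Tc` reflected by a target
at range `R` produces, after mixing, a beat tone

```
f_b = 2 R B / (c Tc),
```

sampled at the ADC rate. The receiver is I-only: each chirp yields a
*real* cosine

```
s_a[n] = A cos(2π f_b n / f_adc + 4π R / λ + φ_a),    φ_a = −2π Δ a sin(α),
```

for antenna index `a`, element spacing `Δ` (in wavelengths) and direction
of arrival `α`. The sign of `φ_a` follows the delay convention, so the
steering vector `A(α) = [1, exp(−iπ sin α)]` (half-wavelength pair) peaks
at the true angle. Complex data exists only after the fast-time FFT —
mirroring hardware without a quadrature mixer.

The phase of the selected range bin is `4πR/λ + φ_a`, so a skin
displacement `d(t)` superimposed on the base range appears as a phase
modulation `θ(t) = 4π d(t) / λ`.

### 1.2 Radar defaults (`RadarConfig`)

| Parameter | Default | Note |
|---|---|---|
| `n_rx` | 3 | one adjacent half-wavelength pair + third channel |
| `n_chirps_per_frame` | 8 | |
| `n_samples_per_chirp` | 128 | |
| `adc_rate` | 1 MHz | |
| `chirp_duration` | 132.987 µs | |
| `frame_rate` | 250 Hz | slow-time sampling rate |
| `start_frequency` | 58 GHz | |
| `bandwidth` | 5.5 GHz | |
| `rx_spacing_wavelengths` | 0.5 | at the 60.75 GHz band centre |

Wavelength is taken at the band centre: λ = c / 60.75 GHz = 4.935 mm.
Range-bin spacing follows from the *sampled* portion of the sweep
(128 samples at 1 MHz out of 132.987 µs): 28.3 mm per bin. The default
base range of 0.05 m places the skin echo in bin 2.

### 1.3 Synthetic waveforms (`synth`)

**Venous (JVP) cycle** — signed Gaussian bumps on the unit cycle:
a/c/v waves at phases 0.10/0.25/0.60 with amplitudes 150/60/120 µm and
widths 0.05/0.04/0.07; x/y descents at 0.18/0.75 with depths 100/130 µm
and widths 0.05/0.08. The cycle is Fourier-truncated to harmonics below
4 Hz, so the band-containment property holds *by construction*, not
asymptotically. A `posture_factor` scales only the venous component.

**Full trajectory** = venous + arterial sinusoid (80 µm at the cardiac
rate, default 1.13 Hz) + respiration (200 µm at 0.25 Hz) + white noise
(5 µm SD).

**Speaker plate** — the two-tone calibration trajectory
`d(t) = a₁ sin 2π f₁ t + a₂ sin 2π f₂ t` with defaults
a₁ = a₂ = 50 µm, f₁ = 50 Hz, f₂ = 54 Hz; the 4 Hz difference produces a
0.25 s beat envelope, verified analytically in the tests.

**PPG** — sampled at 273.1 Hz; one systolic bump (centre 0.18, width 0.09
of the cycle, amplitude 1) plus a dicrotic bump (0.55, 0.11, 0.30). The
widths were chosen so the *fundamental* is the dominant spectral line —
a requirement of the synchronization method, checked for rates 1.13, 1.2
and 1.5 Hz.

**Scene** (`SceneSpec`): base range 0.05 m, DoA 0°, reflection amplitude
1, additive-noise SNR 30 dB (`None` = noise-free), and a
`weak_channel_gain` (default 0.25) applied to antennas beyond the primary
pair. The composite is normalized to peak |amplitude| 1 to emulate ADC
full scale.

## 2. Pipeline stages and numerical choices

### 2.1 Range FFT and bin selection

Per-chirp mean removal suppresses the DC spike, then a real-input FFT
gives 65 bins. By default the first chirp of each frame is kept rather
than averaging chirps: averaging reduces white-noise variance by the
chirp count (verified: ×8) but low-pass-filters fine slow-time detail of
the pulse waveform, so it is off by default and available as an option.

The skin bin is the *first* local maximum above 3× the median magnitude
(DC excluded): the closest reflector is the skin; stronger later echoes
are other obstacles.

### 2.2 I/Q extraction and antenna selection

The slow-time I/Q stream is the selected bin's complex value per frame —
equivalent to inverse-transforming a one-bin-masked spectrum, without the
detour.

Per-antenna SNR is the ratio of 0.75–4 Hz to out-of-band power in the
periodogram of the channel's phase-difference signal. Channels within
6 dB of the best are treated as interchangeable, because the estimate
shows up to ~3.5 dB of spread even between noise-free channels; among
interchangeable channels the lowest-index *adjacent* pair is selected,
because the steering model is only valid for half-wavelength spacing — a
pair spaced one wavelength aliases the angle (asin(2 sin α)). If no
adjacent pair qualifies (e.g. a dead middle channel), the two
highest-SNR channels are returned.

### 2.3 Eigen-beamforming

The spatial covariance `R = X Xᴴ / N` of a single coherent source is
rank-one (measured eigenvalue ratios > 10⁵ on noise-free sources), so no
matrix inverse is ever formed. The dominant eigenvector `e₁` (phase-fixed
so its first component is real-positive) both combines the pair
(`y = e₁ᴴ x`, verified √2 amplitude gain on identical channels) and
localizes the source through
`P(α) = A_p(α)ᴴ R A_p(α)`, `A_p(α) = e₁ (e₁ᴴ A(α))`, scanned over
−90°…90° at 1° steps. Long records use a sliding covariance (window 256
frames, hop 128, averaged).

### 2.4 Circle correction and phase demodulation

The I/Q trajectory of a vibrating target is an arc whose centre is offset
by the receiver's DC leakage. The centre is estimated by Taubin's
algebraic circle fit in its SVD form (centred data augmented with the
normalized squared radius; the fit is the smallest right singular
vector), which is numerically stable on small arcs and, on noisy data,
at least as accurate as the Kåsa least-squares fit (property-tested
against an in-test Kåsa oracle). Fits are performed per block of 256
samples (trailing partial blocks merged) so slow drift of the offset is
tracked. Phase is then the four-quadrant angle of the recentered stream,
unwrapped; displacement is the cumulative sum of phase increments scaled
by λ/4π, mean-removed. Round-trip accuracy on known trajectories:
correlation > 0.95, amplitude error < 10%.

### 2.5 Band filtering

Bandpass: 1021-tap linear-phase FIR (Hamming window), passband
0.75–4 Hz. Bandstop: 511-tap linear-phase FIR at 0.9–1.1 Hz designed by
weighted least squares (`firls`, stopband weight 10³), reaching −34.7 dB
at 1.0 Hz; a window-design notch of this length is infeasible (−2 dB).
The cascade's group delay is (1021−1)/2 + (511−1)/2 = **765 samples**,
and exactly that many samples are trimmed from each record end. Note that
*complete* FIR settling takes 1021 + 511 − 2 = 1530 samples; the
765-sample trim removes the group-delay transient, and steady-state gain
tests measure beyond sample 1530.

The bandstop removes the arterial fundamental when the heart rate falls
inside 0.9–1.1 Hz, which also notches the venous fundamental; harmonic
content in 1.8–4 Hz survives (> 50% of power, measured), which is why
downstream period estimation must not rely on the fundamental.

### 2.6 Pulse detection

The cardiac period is estimated from the *autocorrelation* over lags
corresponding to 0.75–4 Hz — robust to the notched fundamental, where a
spectral argmax locks onto the second harmonic. The reference pulse is
the cycle (among all complete interior cycles, at least five required)
with the highest mean normalized cross-correlation against the others.
Detection slides a Pearson correlation of the template over the record,
takes local maxima above the threshold, and accepts them greedily in
descending correlation; accepted pulses may overlap by at most 5% of the
template length, absorbing ±1–2 samples of peak jitter without admitting
duplicates. On synthetic records at 10 dB SNR the recall is ≥ 90%.

### 2.7 Radar–PPG common frequency

The PPG (273.1 Hz) is resampled to 250 Hz by a polyphase filter with the
exact ratio 2500/2731. Both signals are Hann-windowed and transformed
with `nfft = ⌈fs/0.02⌉ = 12500` (0.02 Hz resolution); the common
frequency is the argmax of the product of the two magnitude spectra over
0.8–2 Hz. The estimate is flagged `low_confidence` when the product peak
is below 20× the in-band median: measured null peak/median ratios on
white noise are 3–7, versus ~4×10⁴ with genuine cardiac content.

## 3. Generator scope and limitations

- Single skin echo plus optional static reflector; no multipath, tissue
  penetration or electromagnetic propagation modelling.
- The array is one linear half-wavelength pair plus an attenuated third
  channel; DoA is meaningful in one plane, within ±90°, and the
  acceptance check spans ±20°.
- The I-only receiver model means image-frequency leakage exists at
  non-bin-centred ranges; tests that need exact phase relations use
  bin-centred ranges where the image term is orthogonal.
- The venous waveform is a stylized periodic template; beat-to-beat
  variability is limited to additive noise. Recall/accuracy figures on
  this generator bound the method's behaviour on the model, not on
  humans.
- `low_confidence` thresholds and the 6 dB antenna tolerance were
  calibrated on this generator's null/artifact distributions; real
  hardware may need recalibration.

## 4. Problem sizes

Default runs: 30 s × 250 frames/s × 3 antennas × 8 chirps × 128 samples
(≈ 2.3·10⁷ samples, ~180 MB as float64). The full pipeline on such a
record takes ~2 s; the test suite ~11 s; the acceptance script ~7 s.
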