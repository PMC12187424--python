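# jvpradar

Contact-free extraction of the jugular venous pulse (JVP) from 60 GHz
frequency-modulated continuous-wave (FMCW) radar, end to end: a physical
echo simulator, range processing, eigen-beamforming, circle-fit I/Q
correction, phase-derived displacement, physiological band filtering, and
template-correlation pulse detection with PPG-based frequency
cross-validation.

## The problem

The JVP — the pressure waveform of the jugular vein, with its a/c/v waves
and x/y descents — is a window on right-heart function, but is normally
assessed by eye or by invasive catheterization. A millimetre-wave radar
pointed at the neck sees skin displacements of tens to hundreds of
micrometres; at λ ≈ 4.93 mm a displacement `d` produces a round-trip
phase change

```
Δθ = 4π d / λ,
```

so micrometre motion maps to milliradian phase, well within reach of
coherent processing. The challenge is everything around that equation:
isolating the skin echo in range, combining antennas so a weak venous
signal survives, removing the receiver's I/Q offset, separating the
venous waveform from the much stronger carotid (arterial) pulse, and
deciding which of the detected oscillations are actually pulses.

## The method

1. **Simulation / acquisition** (`synth`): real-valued (I-only) beat
   signals for each chirp, antenna and frame; a scene is a base range, a
   direction of arrival, and a skin trajectory (synthetic JVP, two-tone
   speaker plate, or arbitrary).
2. **Range processing** (`rangeproc`): per-chirp mean removal and fast-time
   FFT; the first spectral spike above the noise floor is the skin bin;
   that bin's complex value per frame is the slow-time I/Q stream. Antenna
   pairs are chosen by displacement-band SNR, preferring an adjacent
   half-wavelength pair.
3. **Eigen-beamforming** (`beamform`): the spatial covariance
   `R = X Xᴴ / N` of a coherent source is rank-one, so inverse-based
   beamformers fail; instead signals are combined along the dominant
   eigenvector `e₁`, and the angular pseudo-spectrum
   `P(α) = A_p(α)ᴴ R A_p(α)` with `A_p = e₁ (e₁ᴴ A(α))` localizes the
   source on a 1° grid.
4. **Displacement** (`displacement`): per-block Taubin (SVD) circle fits
   remove the I/Q offset; the recentered phase is unwrapped and converted
   by `d = θ λ / 4π`.
5. **Detection** (`jvpdetect`): a 0.75–4 Hz linear-phase bandpass (1021
   taps) cascaded with a 0.9–1.1 Hz bandstop (511 taps) suppresses
   respiration and the arterial fundamental; the combined group delay of
   765 samples is trimmed from each end. A reference cycle is chosen by
   mean cross-correlation against all cycles, and pulses are accepted
   where the sliding Pearson correlation with that template peaks above
   threshold. Radar and PPG recordings are cross-validated by the argmax
   of their spectral-magnitude product over 0.8–2 Hz.

## Worked example

Thirty seconds of synthetic neck echo at the default scene (range 5 cm,
broadside, 30 dB SNR, cardiac fundamental 1.13 Hz), processed end to end:

```python
import numpy as np
from jvpradar import PipelineConfig, run_pipeline, synth_ppg, common_frequency

cfg = PipelineConfig(seed=42, duration_s=30.0)
res = run_pipeline(cfg, "simulate")

print(res.selected_bin)        # 2        (range bin of the skin echo)
print(res.antenna_pair)        # (0, 1)   (adjacent half-wavelength pair)
print(res.doa.peak_angle_deg)  # 0.0      (broadside source localized)
print(res.trim_bounds)         # (765, 6735)
print(res.template.cycle_length)  # 221   (≈ 250 Hz / 1.13 Hz)
print(res.pulses.n_pulses)     # 27 pulses, mean correlation 0.99
print(np.std(res.displacement.values) * 1e6)  # ≈ 181 µm RMS displacement

ppg = synth_ppg(cfg.jvp.cardiac_rate, 30.0, seed=43)
out = common_frequency(res.displacement, ppg)
print(out.frequency_hz)        # 1.14 Hz (resolution 0.02 Hz), confident
```

The same pipeline is available from the command line:

```bash
jvpradar simulate --seed 42 --out scene.h5
jvpradar process scene.h5 --out results/
jvpradar doa scene.h5
```

## Reproduction

All headline numbers are recomputed from fresh simulations by

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

which writes, per target, the computed value and the number of
measurements it summarizes: the symmetric direction-of-arrival half-width
over which a noise-free source is localized to within 2°, the common
radar/PPG cardiac frequency on 30-s synthetic recordings, and the higher
of the two tones recovered from the synthetic speaker-plate trajectory.
The script takes well under a minute; the full test suite
(`python -m pytest -q tests/`) runs in under a minute on one CPU.

See `docs/methods.md` for the signal model, parameter defaults and
numerical design choices.
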