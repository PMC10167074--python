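# lfpac

Stimulus-locked and cross-frequency analysis of local field potential
(LFP) recordings: trial segmentation and event-related averaging,
rectified-RMS z-score maps, EPSP slope measurement, Butterworth band
filtering with Hilbert envelope/phase, FFT and Welch spectra,
Morlet-wavelet scalograms, three phase–amplitude coupling (PAC)
estimators, and two-channel phase coherence.

It is written for electrophysiologists analyzing intracranial or
extracellular recordings (ABF or EDF files) from stimulation or
free-running protocols, as a scriptable library with a thin command-line
interface — every analysis is also callable on in-memory arrays.

## The estimators

**Phase–amplitude coupling.** The raw signal x(t) is band-filtered in a
narrow modulating band f_p and a broad modulated band f_A; the Hilbert
transform yields the instantaneous phase φ(t) of the slow band and
envelope A(t) of the fast band. Binning A by φ (18 bins of 20°) gives
the amplitude distribution over phase, quantified three ways:

- **KL modulation index** — MI = (log N − H(P)) / log N, where P is the
  normalized phase-binned amplitude distribution and H its Shannon
  entropy. MI = 0 for a flat profile, 1 when all mass sits in one bin.
- **Mean vector length** — |⟨A e^{iφ}⟩| / ⟨A⟩ (normalized to be
  dimensionless).
- **Phase-locking value** — |⟨e^{i(φ − φ_A)}⟩|, where φ_A is the phase
  of the envelope's fluctuation in the modulating band.

Scanning (f_p, f_A) over a grid gives the **comodulogram**. A
wavelet-power variant bins Morlet power of the modulated band instead of
the Hilbert envelope, and a **cycle-detection** variant restricts the
estimate to trough-to-trough cycles of the slow rhythm, which keeps the
estimate sensitive when the modulating oscillation is intermittent.

**Phase coherence.** For two channels, PC(j, k) = |⟨e^{i(P₁ − P₂)}⟩|
over all Morlet time–frequency samples in time window j and frequency
window k — 1 for a fixed phase relation, near 0 for independent phases.

## Worked example

```python
from lfpac.synth import PacSpec, make_pac_signal
from lfpac.coupling import comodulogram, pac_wavelet_phase_power

sig = make_pac_signal(PacSpec(duration=60.0, f_p=8.0, f_a=80.0,
                              depth=0.7, snr=3.0, seed=1))
com = comodulogram(sig)  # phase 2-14 Hz x amplitude 30-120 Hz
fp, fa = com.argmax_freqs()
print(f"strongest coupling: {fp:.0f} Hz phase -> {fa:.0f} Hz amplitude "
      f"(KL-MI = {com.mi.max():.4f})")

prof = pac_wavelet_phase_power(sig, phase_band=(6, 10), amp_range=(60, 100))
print(f"band-pair MI = {prof.mi:.4f}, preferred phase = "
      f"{prof.peak_phase:.2f} rad")
```

prints

```
strongest coupling: 8 Hz phase -> 80 Hz amplitude (KL-MI = 0.0106)
band-pair MI = 0.0903, preferred phase = 0.17 rad
```

The generator couples an 8 Hz rhythm's phase to an 80 Hz oscillation's
amplitude at depth 0.7 under 3:1 SNR; the comodulogram recovers the pair
exactly, and the profile peak sits within one 20° bin of the generator's
coupling phase (0 rad).

The same pipeline runs from the shell on ABF/EDF files:

```bash
lfpac synth pac --out demo.edf --duration 60
lfpac comodulogram --file demo.edf --channel 1 --no-stim --out demo_com
lfpac pac --file demo.edf --channel 1 --no-stim --method cycle --out demo_pac
```

For stimulation protocols, `--stim-channel/--threshold/--inter-stim-time`
detect pulses and `--t-initial/--t-final` cut peristimulus windows
(t = 0 at the stimulus); see `lfpac --help`.

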