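# Methods

This note documents the models, parameter defaults and numerical choices
in lfpac, and what the synthetic tests do and do not establish about
real recordings.

## Signal model and I/O

A `Recording` is a channels × samples array at one sampling rate, in the
file's physical units (typically mV). EDF/EDF+ is parsed with MNE; its
SI rescaling is undone from the per-channel unit field so values match
the recording system. ABF version 1 is parsed by a reader written
against the documented ABF-1 header layout (both int16 gain/offset-scaled
and float32 data sections); ABF-2 is rejected with an explicit error.
Format resolution is by file content, never extension. Episodic ABF
sweeps are concatenated into one continuous trace in acquisition order —
sweep boundaries are kept as metadata, but trial structure is always
derived from the stimulus channel, since stimulation, not acquisition
paging, defines the experiment's trials.

Resampling (downsampling only) applies a zero-phase order-8 Butterworth
low-pass at 0.4 × target rate before polyphase rate conversion, so
content above the new Nyquist cannot alias into the analysis bands.
Non-integer ratios are handled by the rational approximation of the rate
quotient.

## Segmentation

Stimulus onsets are rising threshold crossings (first sample at or above
threshold after one below). A refractory period of half the declared
interstimulus interval suppresses re-triggering on artifact ringing; for
paired-pulse protocols the refractory period is half the declared
within-pair interval instead, so both pulses are kept. Trials are cut as
[t_initial, t_final] windows with t = 0 at the stimulus; windows that
would overrun the recording are dropped (not zero-padded — padding would
bias every spectral estimate downstream). With no stimulation the whole
trace is one trial.

## Time domain

The RMS z-score map rectifies each trial, computes RMS in sliding
windows (default 50 ms window, 10 ms hop — not prescribed by any
convention; chosen to resolve ~100 ms power transients at 1 kHz and
exposed as parameters), and z-scores each trial's RMS series against its
own mean and SD. The z-score is signed; an absolute-value option exists
for display as strictly positive magnitudes. A constant trial (zero SD)
returns zeros with a warning rather than dividing by zero.

Slope measurement differentiates by first difference × fs after an
optional moving-average smoothing (default 1 ms; raw differentiation of
noisy traces is slope-unstable). The maximum-magnitude derivative in the
user's window is reported with its time (ties break to the earliest
sample; derivative values are assigned to inter-sample midpoints). For
an alpha-function EPSP a·(t/τ)·e^{1−t/τ} the analytic maximum slope is
a·e/τ at onset, which the discrete estimate matches within 1% at 10 kHz.

## Filtering and spectra

Band filters are Butterworth designs realized as second-order sections
(stable for narrow bands) and applied forward–backward. Zero-phase
filtering is essential here because the filtered phase feeds the
coupling estimators: any group delay would masquerade as a preferred
coupling phase. The two-pass application squares the magnitude response,
so the response table reported for verification is the *effective*
response — band edges read −6.02 dB there, i.e. the classical −3.01 dB
per pass. Signals are reflect-padded by three low-frequency periods
before filtering and the Hilbert transform, and trimmed after, keeping
edge transients out of the returned arrays.

FFT spectra are one-sided magnitudes scaled 2|X|/N (a unit sine reads 1
at its bin). Welch PSDs use a Hann window and 50% overlap by default and
integrate to the signal variance (Parseval check in the tests). Band
power is a trapezoidal integral with exact band-edge interpolation;
relative band power divides by the full-range integral.

## Time–frequency

The Morlet wavelet at frequency f is a complex exponential under a
Gaussian of SD n_cycles/(2πf) — the standard cycles parameterization.
Default n_cycles = 7 balances frequency and time resolution for LFP
bands; the tests verify the expected trade-off (more cycles: narrower
frequency marginal, wider click response). Wavelets are
amplitude-normalized so a unit sine yields power ≈ 1 in its row, making
rows comparable before display transforms. Convolution is by FFT with
reflective padding; samples within one wavelet half-length of the edges
are flagged (cone of influence) but not blanked. The frequency grid is
linear at ~1 Hz steps by default, geometric on request.

Trial averaging averages *power*, not complex coefficients, so induced
(non-phase-locked) activity survives. "Norm" z-scores each frequency row
across time (flattening the 1/f gradient); "Log" is dB relative to the
maximum cell; when both are requested log precedes normalization, since
z-scoring after the log operates on a scale where multiplicative power
changes are additive.

## Phase–amplitude coupling

Profiles use 18 phase bins (20°), the convention of the KL-MI
literature. KL-MI = (log N − H)/log N; mean vector length is normalized
by mean amplitude to be scale-free; PLV phases the envelope by filtering
it in the modulating band and taking its Hilbert phase.

Comodulogram bandwidths: the phase band is narrow (width = p_step); the
amplitude band must be wide enough to carry the modulation sidebands at
f_A ± f_p, so its width is max(a_step, 2 × f_p). The amplitude filter
uses order 5 against order 3 for the phase band: with a gentler rolloff
the grid cell one step below the carrier passes the lower sideband plus
the carrier's skirt, and their beat envelope can out-modulate the true
cell, displacing the argmax. The steeper filter restores recovery within
one grid step at depth ≥ 0.5 and SNR ≥ 3 (the conditions of the
parameter-recovery tests).

Cycle detection finds local minima of the filtered modulating band with
prominence ≥ 0.25 × the 95th-percentile envelope and minimum spacing of
half the band's shortest period; consecutive troughs bound a cycle, and
cycles with durations outside the band's period range (±25%) are
rejected. The upper-percentile prominence reference tracks the
oscillation's amplitude rather than the silence between bursts, so a
rhythm present 10–100% of the time is segmented correctly; rhythms
present < ~5% of the time may need an explicit prominence. The
cycle-based estimator then bins phase and band-mean Morlet power using
only samples inside accepted cycles (cycles weighted by duration, which
for near-periodic rhythms equals per-cycle averaging), which is why it
stays sensitive when the slow rhythm is intermittent while the
whole-signal estimate dilutes toward uniform.

Phase coherence splits the recording into consecutive wd_time windows
and [f_low, f_high] into contiguous frequency windows; within each epoch
the phase difference of the two channels' Morlet coefficients is pooled
over time samples and wavelet frequencies and the resultant length
|⟨e^{id}⟩| reported. The modulus makes the value real in [0, 1] and
invariant to any constant lag. Wavelet smoothing correlates neighboring
samples, so the null floor at 1 s windows is ~0.24, not 1/√n — the null
tests assert the floor empirically and its decrease with window length.

Surrogates circularly rotate the modulated signal by random lags ≥ 1 s,
destroying phase–amplitude alignment while preserving both spectra.
Significance thresholds are left to the user; no correction is
auto-applied.

## Synthetic generator

`make_pac_signal` produces
g(t)·cos(φ(t)) + [1 + depth·g(t)·cos(φ(t) − ψ)]·sin(2πf_A t) + noise,
with φ(t) = 2πf_p t by default. Using cosine for the slow component
makes its Hilbert phase equal φ(t), so the profile peak sits at ψ by
construction. The burst gate g(t) silences the slow rhythm and the
modulation while the fast carrier persists unmodulated — the regime
where the modulating band is "not continuously present" but fast
activity is. Defaults (60 s, 1 kHz, 8→80 Hz, depth 0.7, SNR 3 with
Gaussian white noise, SNR as RMS ratio) are the study conditions for all
recovery tests.

The `stochastic` modulator mode draws φ(t) from narrowband Gaussian
noise (2 Hz bandwidth around f_p, ~0.5 s coherence time). This exists
because a strictly periodic modulator is invariant under circular
time shifts — the phase-binned profile merely rotates, and every index
here is rotation-invariant — so surrogate destruction is only a
meaningful property for a modulator with phase diffusion, which is also
the realistic regime for biological rhythms.

What the generator does *not* emulate: 1/f background (available as an
option, off by default so analytic expectations stay closed-form),
nonsinusoidal slow rhythms (whose harmonics can produce spurious PAC),
movement/stimulation artifacts, and nonstationary coupling strength.
Passing tests therefore establish correctness of the estimators under
their own model assumptions, not robustness to those confounds —
surrogate testing remains necessary on real data.

`make_stim_recording` emulates a 3 s-ISI stimulation protocol (with an
optional 0.1 s paired-pulse mode) as rectangular pulses plus an
alpha-function evoked response at fixed latency; `make_coherent_pair`
mixes a shared band-limited source into two channels with the coupling
parameter as the shared-variance fraction.

## Problem sizes and determinism

All tests and the acceptance script run on generated data: 20–60 s at
1 kHz, grids of 13 phase × 19 amplitude frequencies — sizes at which
every property they assert is stable across seeds while the whole suite
completes in well under a minute apart from the 60 s comodulogram scans.
Every stochastic fixture is seeded; the acceptance script derives all of
its seeds from the `--seed` argument, and identical invocations produce
byte-identical outputs.
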