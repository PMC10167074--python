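"""PAC estimators, cycle detection, phase coherence and surrogates."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lfpac.io import ChannelSignal
from lfpac.segmentation import TrialSet
from lfpac.spectral import BandFilterSpec, filter_and_decompose
from lfpac.coupling import (
    PhaseAmplitudeProfile,
    circular_shift,
    comodulogram,
    detect_cycles,
    modulation_index,
    pac_cycle_based,
    pac_surrogates,
    pac_wavelet_phase_power,
    phase_amplitude_profile,
    phase_coherence,
)
from lfpac.synth import PacSpec, make_coherent_pair, make_pac_signal

FS = 1000.0
BIN_WIDTH = 2 * np.pi / 18


def _one_hot_profile(n_bins=18, k=0):
    normalized = np.zeros(n_bins)
    normalized[k] = 1.0
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    return PhaseAmplitudeProfile(edges, normalized.copy(), normalized,
                                 mi=None, method="kl_mi")


class TestProfile:
    def test_uniform_phases_constant_amplitude(self):
        phases = np.linspace(-np.pi + 1e-6, np.pi, 18_000)
        prof = phase_amplitude_profile(phases, np.full(18_000, 3.3))
        np.testing.assert_allclose(prof.normalized, 1 / 18, atol=1e-12)

    def test_cosine_modulation_recovered(self):
        """amplitude = 1 + cos(phase) binned densely reproduces the cosine.

        The exact expectation per bin is the integral mean of 1 + cos over
        the bin: 1 + (sin(hi) - sin(lo)) / (hi - lo).
        """
        phases = np.linspace(-np.pi + 1e-9, np.pi, 360_000)
        amp = 1 + np.cos(phases)
        prof = phase_amplitude_profile(phases, amp, n_bins=18)
        lo, hi = prof.bin_edges[:-1], prof.bin_edges[1:]
        expected = 1 + (np.sin(hi) - np.sin(lo)) / (hi - lo)
        expected /= expected.sum()
        np.testing.assert_allclose(prof.normalized, expected, atol=2e-4)

    def test_empty_bin_rejected(self):
        phases = np.full(100, 0.1)  # all mass in one bin
        with pytest.raises(ValueError, match="no samples"):
            phase_amplitude_profile(phases, np.ones(100))

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_joint_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        phases = rng.uniform(-np.pi, np.pi, 2000)
        amp = rng.exponential(1.0, 2000)
        perm = rng.permutation(2000)
        p1 = phase_amplitude_profile(phases, amp, n_bins=6)
        p2 = phase_amplitude_profile(phases[perm], amp[perm], n_bins=6)
        np.testing.assert_allclose(p1.normalized, p2.normalized, atol=1e-12)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_normalized_sums_to_one(self, seed):
        rng = np.random.default_rng(seed)
        prof = phase_amplitude_profile(
            rng.uniform(-np.pi, np.pi, 5000), rng.gamma(2.0, 1.0, 5000), n_bins=8
        )
        assert prof.normalized.sum() == pytest.approx(1.0, abs=1e-9)


class TestModulationIndex:
    def test_uniform_profile_zero(self):
        phases = np.linspace(-np.pi + 1e-6, np.pi, 18_000)
        prof = phase_amplitude_profile(phases, np.ones(18_000))
        assert modulation_index(prof) == 0.0

    def test_single_bin_profile_one(self):
        assert modulation_index(_one_hot_profile()) == pytest.approx(1.0)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_kl_mi_bounded(self, seed):
        """kl_mi stays in [0, 1] for arbitrary random profiles."""
        rng = np.random.default_rng(seed)
        prof = phase_amplitude_profile(
            rng.uniform(-np.pi, np.pi, 4000), rng.gamma(1.5, 2.0, 4000), n_bins=12
        )
        mi = modulation_index(prof)
        assert 0.0 <= mi <= 1.0

    def test_amplitude_scale_invariance(self, rng):
        phases = rng.uniform(-np.pi, np.pi, 5000)
        amp = rng.gamma(2.0, 1.0, 5000)
        for method in ("kl_mi", "mvl"):
            a = modulation_index(phase=phases, amplitude=amp, method=method)
            b = modulation_index(phase=phases, amplitude=100.0 * amp, method=method)
            assert a == pytest.approx(b, rel=1e-9)

    def test_zero_amplitude_rejected(self, rng):
        phases = rng.uniform(-np.pi, np.pi, 100)
        with pytest.raises(ValueError, match="zero total amplitude"):
            modulation_index(phase=phases, amplitude=np.zeros(100), method="mvl")

    def test_depth_monotonicity_all_methods(self):
        """Each index strictly increases with coupling depth at fixed seed."""
        series = {}
        for depth in (0.2, 0.5, 0.8):
            sig = make_pac_signal(PacSpec(duration=20.0, depth=depth, seed=11))
            ph = filter_and_decompose(sig, BandFilterSpec(6, 10, 3, FS)).phase
            env = filter_and_decompose(sig, BandFilterSpec(60, 100, 5, FS)).envelope
            series[depth] = (ph, env)
        for method in ("kl_mi", "mvl", "plv"):
            vals = [
                modulation_index(phase=ph, amplitude=env, method=method,
                                 fs=FS, phase_band=(6, 10))
                for ph, env in series.values()
            ]
            assert vals[0] < vals[1] < vals[2], method


class TestComodulogram:
    def test_recovers_generator_frequencies(self, coupled_sig, coupled_spec):
        com = comodulogram(coupled_sig, phase_range=(4, 12), amp_range=(40, 120),
                           p_step=2.0, a_step=10.0)
        fp, fa = com.argmax_freqs()
        assert abs(fp - coupled_spec.f_p) <= 2.0
        assert abs(fa - coupled_spec.f_a) <= 10.0
        assert np.all(com.mi >= 0)

    def test_single_channel_argument_symmetry(self, coupled_sig):
        a = comodulogram(coupled_sig, None, (6, 10), (60, 100), 2.0, 20.0)
        b = comodulogram(coupled_sig, coupled_sig, (6, 10), (60, 100), 2.0, 20.0)
        np.testing.assert_allclose(a.mi, b.mi)

    def test_inverted_bands_warn(self, coupled_sig):
        with pytest.warns(UserWarning, match="inverted"):
            comodulogram(coupled_sig, phase_range=(30, 40), amp_range=(10, 20),
                         p_step=5.0, a_step=5.0)


class TestWaveletPhasePower:
    def test_peak_at_coupling_phase(self):
        spec = PacSpec(duration=30.0, coupling_phase=np.pi / 2, seed=8)
        prof = pac_wavelet_phase_power(make_pac_signal(spec),
                                       phase_band=(6, 10), amp_range=(60, 100))
        assert abs(prof.peak_phase - spec.coupling_phase) <= BIN_WIDTH

    def test_unmodulated_carrier_flat(self):
        sig = make_pac_signal(PacSpec(duration=30.0, depth=0.0, seed=9))
        prof = pac_wavelet_phase_power(sig, phase_band=(6, 10), amp_range=(60, 100))
        assert prof.mean_amplitude.max() / prof.mean_amplitude.min() < 1.1

    def test_per_trial_average_of_identical_trials(self, coupled_sig):
        row = coupled_sig.samples[:10_000]
        ts = TrialSet(np.tile(row, (3, 1)), FS, np.arange(10_000) / FS)
        single = pac_wavelet_phase_power(
            ChannelSignal(row, FS), phase_band=(6, 10), amp_range=(60, 100))
        averaged = pac_wavelet_phase_power(ts, phase_band=(6, 10),
                                           amp_range=(60, 100))
        np.testing.assert_allclose(averaged.normalized, single.normalized, atol=1e-12)
        assert averaged.mi == pytest.approx(single.mi)

    def test_amplitude_rescaling_invariance(self, coupled_sig):
        scaled = ChannelSignal(5.0 * coupled_sig.samples, FS)
        p1 = pac_wavelet_phase_power(coupled_sig, phase_band=(6, 10),
                                     amp_range=(60, 100))
        p2 = pac_wavelet_phase_power(scaled, phase_band=(6, 10),
                                     amp_range=(60, 100))
        assert p1.mi == pytest.approx(p2.mi, rel=1e-6)


class TestDetectCycles:
    def test_sine_cycle_count_and_duration(self):
        t = np.arange(10_000) / FS
        sig = ChannelSignal(np.sin(2 * np.pi * 8 * t), FS)
        dec = filter_and_decompose(sig, BandFilterSpec(6, 10, 3, FS))
        cycles = detect_cycles(dec)
        assert abs(cycles.n_cycles - 79) <= 1
        durations = [(b - a) / FS for a, b in cycles.windows]
        assert np.mean(durations) == pytest.approx(0.125, abs=0.002)

    def test_silent_middle_third_has_no_cycles(self):
        t = np.arange(30_000) / FS
        x = np.sin(2 * np.pi * 8 * t)
        x[10_000:20_000] = 0.0
        dec = filter_and_decompose(ChannelSignal(x, FS), BandFilterSpec(6, 10, 3, FS))
        cycles = detect_cycles(dec)
        mids = [(a + b) / 2 / FS for a, b in cycles.windows]
        # allow filter ring-down at the silence edges
        assert not any(10.5 < m < 19.5 for m in mids)

    def test_windows_ordered_and_disjoint(self, coupled_sig):
        dec = filter_and_decompose(coupled_sig, BandFilterSpec(6, 10, 3, FS))
        cycles = detect_cycles(dec)
        flat = [i for w in cycles.windows for i in w]
        assert flat == sorted(flat)

    def test_too_few_troughs_rejected(self):
        t = np.arange(3000) / FS
        sig = ChannelSignal(np.zeros_like(t), FS)
        dec = filter_and_decompose(sig, BandFilterSpec(6, 10, 3, FS))
        with pytest.raises(ValueError, match="trough"):
            detect_cycles(dec)


class TestCycleBasedPac:
    def test_agrees_with_wavelet_method_when_stationary(self, coupled_sig):
        prof_w = pac_wavelet_phase_power(coupled_sig, phase_band=(6, 10),
                                         amp_range=(60, 100))
        prof_c, cycles = pac_cycle_based(coupled_sig, phase_band=(6, 10),
                                         amp_range=(60, 100))
        cos = np.dot(prof_w.normalized, prof_c.normalized) / (
            np.linalg.norm(prof_w.normalized) * np.linalg.norm(prof_c.normalized))
        assert cos > 0.95
        assert cycles.n_cycles > 100

    def test_intermittent_rhythm_advantage(self):
        """With the slow rhythm present 30% of the time, restricting the
        estimate to detected cycles preserves the coupling the whole-signal
        method dilutes."""
        bursts = tuple((10.0 * k, 10.0 * k + 3.0) for k in range(6))
        sig = make_pac_signal(PacSpec(duration=60.0, seed=3, bursts=bursts))
        prof_w = pac_wavelet_phase_power(sig, phase_band=(6, 10),
                                         amp_range=(60, 100))
        prof_c, _ = pac_cycle_based(sig, phase_band=(6, 10), amp_range=(60, 100))
        assert prof_c.mi > 2.0 * prof_w.mi

    def test_two_channel_degenerate_equals_single(self, coupled_sig):
        p1, _ = pac_cycle_based(coupled_sig, None, (6, 10), (60, 100))
        p2, _ = pac_cycle_based(coupled_sig, coupled_sig, (6, 10), (60, 100))
        np.testing.assert_allclose(p1.normalized, p2.normalized)

    def test_too_few_cycles_reports_count(self):
        """A 0.4 s burst holds ~3 cycles of 8 Hz, under the minimum of 5."""
        sig = make_pac_signal(PacSpec(duration=2.0, seed=3, snr=None,
                                      bursts=((0.0, 0.4),)))
        with pytest.raises(ValueError, match="cycle"):
            pac_cycle_based(sig, phase_band=(6, 10), amp_range=(60, 100))


class TestPhaseCoherence:
    def test_self_coherence_is_one(self, coupled_sig):
        short = ChannelSignal(coupled_sig.samples[:10_000], FS)
        cm = phase_coherence(short, short, wd_time=1.0)
        np.testing.assert_allclose(cm.pc, 1.0, atol=1e-9)

    def test_constant_lag_keeps_coherence(self):
        t = np.arange(20_000) / FS
        x = np.sin(2 * np.pi * 10 * t)
        s1 = ChannelSignal(x, FS)
        s2 = ChannelSignal(np.roll(x, 25), FS)  # quarter-period lag
        cm = phase_coherence(s1, s2, wd_time=1.0, f_low=4, f_high=16,
                             n_freq_windows=3)
        band_row = cm.pc[1]  # window containing 10 Hz
        assert band_row.min() > 0.95

    def test_independent_noise_low_coherence(self, rng):
        n1 = ChannelSignal(rng.standard_normal(20_000), FS)
        n2 = ChannelSignal(rng.standard_normal(20_000), FS)
        cm = phase_coherence(n1, n2, wd_time=1.0)
        assert cm.pc.mean() < 0.3
        cm4 = phase_coherence(n1, n2, wd_time=4.0)
        assert cm4.pc.mean() < cm.pc.mean()  # longer windows average down

    def test_values_in_unit_interval(self, rng):
        s1, s2 = make_coherent_pair(duration=10.0, coupling=0.5, seed=6)
        cm = phase_coherence(s1, s2, wd_time=1.0)
        assert np.all((cm.pc >= 0) & (cm.pc <= 1))

    def test_length_mismatch_rejected(self, rng):
        s1 = ChannelSignal(rng.standard_normal(5000), FS)
        s2 = ChannelSignal(rng.standard_normal(4000), FS)
        with pytest.raises(ValueError, match="length"):
            phase_coherence(s1, s2, wd_time=1.0)


class TestSurrogates:
    def test_shift_destroys_stochastic_coupling(self):
        sig = make_pac_signal(PacSpec(duration=60.0, seed=1, modulator="stochastic"))
        mi0 = pac_wavelet_phase_power(sig, phase_band=(6, 10),
                                      amp_range=(60, 100)).mi
        shifted = circular_shift(sig, 1.0)
        mi1 = pac_wavelet_phase_power(sig, shifted, phase_band=(6, 10),
                                      amp_range=(60, 100)).mi
        assert mi1 < 0.1 * mi0

    def test_surrogate_distribution_below_true_mi(self):
        sig = make_pac_signal(PacSpec(duration=30.0, seed=1, modulator="stochastic"))
        true_mi = pac_wavelet_phase_power(sig, phase_band=(6, 10),
                                          amp_range=(60, 100)).mi
        null = pac_surrogates(sig, phase_band=(6, 10), amp_band=(60, 100),
                              n_surrogates=20, seed=0)
        assert null.max() < true_mi
        assert null.shape == (20,)
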