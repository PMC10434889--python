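import numpy as np
import pytest

import sleepdyn as sd
from sleepdyn.fields import FieldSignal, exponential_kernel


def _one_spike_session():
    return sd.SpikeTrainSet(
        neuron_ids=["a"],
        spike_times={"a": np.array([0.001])},
        t_start=0.0,
        t_end=1.0,
    )


class TestBuildSlfp:
    def test_silent_input_gives_zero_signal(self):
        spikes = sd.SpikeTrainSet(
            neuron_ids=["a"], spike_times={"a": np.empty(0)}, t_start=0, t_end=1
        )
        sig = sd.build_slfp(spikes)
        assert not sig.samples.any()
        assert sig.fs == pytest.approx(125.0)

    def test_closed_form_kernel_response(self):
        sig = sd.build_slfp(_one_spike_session(), bin_width=0.008, tau=0.024)
        expected = np.exp(-0.008 * np.arange(4) / 0.024)
        np.testing.assert_allclose(sig.samples[:4], expected, rtol=1e-12)

    def test_population_average_linearity(self, rng):
        times_a = np.sort(rng.uniform(0, 10, 200))
        times_b = np.sort(rng.uniform(0, 10, 300))
        sa = sd.SpikeTrainSet(["a"], {"a": times_a}, t_start=0, t_end=10)
        sb = sd.SpikeTrainSet(["b"], {"b": times_b}, t_start=0, t_end=10)
        sab = sd.SpikeTrainSet(
            ["a", "b"], {"a": times_a, "b": times_b}, t_start=0, t_end=10
        )
        fa = sd.build_slfp(sa).samples
        fb = sd.build_slfp(sb).samples
        fab = sd.build_slfp(sab).samples
        np.testing.assert_allclose(fab, (fa + fb) / 2, rtol=1e-9)

    def test_no_excitatory_errors(self):
        spikes = sd.SpikeTrainSet(
            ["a"], {"a": np.array([0.5])},
            excitatory={"a": False}, t_start=0, t_end=1,
        )
        with pytest.raises(ValueError):
            sd.build_slfp(spikes)

    def test_kernel_truncated_at_ten_tau(self):
        k = exponential_kernel(0.008, 0.024)
        assert k[0] == 1.0
        assert len(k) == int(np.ceil(10 * 0.024 / 0.008))


class TestWelch:
    def test_sinusoid_peaks_at_its_frequency(self):
        fs = 125.0
        t = np.arange(0, 20, 1 / fs)
        sig = FieldSignal(np.sin(2 * np.pi * 4 * t), fs=fs)
        spec = sd.welch_psd(sig)
        assert spec.freqs[np.argmax(spec.psd)] == pytest.approx(4.0)

    def test_parseval_on_white_noise(self, rng):
        fs = 125.0
        x = rng.normal(size=int(fs * 200))
        spec = sd.welch_psd(FieldSignal(x, fs=fs))
        df = spec.freqs[1] - spec.freqs[0]
        assert spec.psd.sum() * df == pytest.approx(x.var(), rel=0.05)

    def test_too_short_signal_errors(self):
        with pytest.raises(ValueError):
            sd.welch_psd(FieldSignal(np.zeros(100), fs=125.0))

    def test_sws_slfp_has_delta_peak(self, standard_session):
        """UP/DOWN alternation concentrates sLFP power below 4 Hz."""
        spikes, hyp, _ = standard_session
        from sleepdyn.pipeline import session_field_complexity

        sws = session_field_complexity(spikes, hyp, "SWS", max_duration=120)
        wake = session_field_complexity(spikes, hyp, "Wake", max_duration=120)
        assert sws["delta_fraction"] > wake["delta_fraction"]


class TestCoherence:
    def test_identical_signals_fully_coherent(self, rng):
        x = rng.normal(size=125 * 30)
        sig = FieldSignal(x, fs=125.0)
        spec = sd.msc_coherence(sig, sig)
        assert np.all(spec.coherence > 0.999)

    def test_independent_noise_near_zero(self, rng):
        a = FieldSignal(rng.normal(size=125 * 120), fs=125.0)
        b = FieldSignal(rng.normal(size=125 * 120), fs=125.0)
        spec = sd.msc_coherence(a, b)
        assert spec.coherence.mean() <= 0.2

    def test_coherence_decreases_with_noise_power(self, rng):
        x = rng.normal(size=125 * 60)
        means = []
        for noise_sd in (0.5, 2.0):
            y = x + noise_sd * rng.normal(size=x.size)
            spec = sd.msc_coherence(
                FieldSignal(x, fs=125.0), FieldSignal(y, fs=125.0)
            )
            means.append(spec.coherence.mean())
        assert means[0] > means[1]

    def test_fs_mismatch_errors(self, rng):
        a = FieldSignal(rng.normal(size=1000), fs=125.0)
        b = FieldSignal(rng.normal(size=1000), fs=100.0)
        with pytest.raises(ValueError):
            sd.msc_coherence(a, b)


class TestSpectralSlope:
    def test_exact_power_law(self):
        f = np.arange(1.0, 41.0)
        spec = sd.SpectralResult(freqs=f, psd=f ** -2.0)
        assert sd.spectral_slope(spec, (1, 40)) == pytest.approx(2.0)

    def test_white_noise_is_flat(self, rng):
        x = rng.normal(size=125 * 400)
        spec = sd.welch_psd(FieldSignal(x, fs=125.0))
        assert abs(sd.spectral_slope(spec, (1, 40))) < 0.1

    def test_brownian_signal_slope_near_two(self, rng):
        x = np.cumsum(rng.normal(size=125 * 400))
        spec = sd.welch_psd(FieldSignal(x, fs=125.0))
        assert sd.spectral_slope(spec, (1, 40)) == pytest.approx(2.0, abs=0.3)

    def test_nonpositive_psd_errors(self):
        f = np.arange(1.0, 11.0)
        spec = sd.SpectralResult(freqs=f, psd=np.zeros(10))
        with pytest.raises(ValueError):
            sd.spectral_slope(spec, (1, 10))
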