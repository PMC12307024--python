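import dataclasses

import numpy as np
import pytest
from scipy import stats

from rifteeg import (SimConfig, TagConfig, frame_schedule_rate,
                     make_amplitude_tag, make_luminance_tag, simulate_dataset,
                     simulate_epoch, windowed_power)


def _spectrum_bins(x, fs=1000.0):
    """Amplitude spectrum of a 1-D waveform, indexed by Hz."""
    return np.abs(np.fft.rfft(x) / x.size)


class TestTagWaveforms:
    def test_luminance_tag_is_single_tone_at_visual_frequency(self):
        tag = TagConfig()
        w = make_luminance_tag(1.0, tag)
        assert w.min() >= 0 and w.max() <= 1
        amp = _spectrum_bins(w)
        amp[0] = 0.0  # remove the 0.5 mean
        assert np.argmax(amp) == 68
        off = np.delete(amp, 68)
        assert np.all(off < 1e-12)

    def test_zero_depth_means_constant_half(self):
        tag = TagConfig(modulation_depth=0.0)
        assert np.allclose(make_luminance_tag(1.0, tag), 0.5)
        assert np.allclose(make_amplitude_tag(np.ones(100), tag), 0.5)
        # value at tagging onset is 0.5 regardless of depth (sin(0) = 0)
        assert make_luminance_tag(1.0, TagConfig())[0] == pytest.approx(0.5)

    def test_amplitude_tag_constant_envelope_has_dc_and_54hz_only(self):
        tag = TagConfig()
        y = make_amplitude_tag(np.ones(1000), tag)
        amp = _spectrum_bins(y)
        assert amp[0] == pytest.approx(0.5)
        assert amp[54] == pytest.approx(0.25)
        others = np.delete(amp, [0, 54])
        assert np.all(others < 1e-12)

    def test_amplitude_tag_zero_envelope_and_length(self):
        tag = TagConfig()
        assert np.all(make_amplitude_tag(np.zeros(500), tag) == 0)
        assert make_amplitude_tag(np.ones(777), tag).shape == (777,)
        with pytest.raises(ValueError):
            make_amplitude_tag(np.array([]), tag)

    def test_aliasing_tag_frequency_rejected(self):
        with pytest.raises(ValueError, match="[Nn]yquist|alias"):
            TagConfig(f_visual=600.0, sample_rate=1000.0)

    def test_tag_frequencies_must_differ_by_at_least_1hz(self):
        with pytest.raises(ValueError):
            TagConfig(f_audio=54.0, f_visual=54.5)


@pytest.mark.parametrize("args,expected", [
    ((120, 4, 3), 1440),
    ((120, 1, 1), 120),
    ((60, 4, 3), 720),
])
def test_frame_schedule_rate(args, expected):
    assert frame_schedule_rate(*args) == expected


def test_frame_schedule_rate_rejects_non_positive():
    with pytest.raises(ValueError):
        frame_schedule_rate(120, 0, 3)


class TestEpochs:
    def test_epoch_time_axis_and_shapes(self, noiseless_cfg):
        ds = simulate_dataset(noiseless_cfg)
        assert len(ds) == 1
        e = ds[0]
        assert e.data.shape == (2, 31, 2000)
        assert e.times[0] == pytest.approx(-1.0)
        assert e.times[-1] == pytest.approx(0.999)
        assert set(e.condition) == {"related", "unrelated"}

    def test_baseline_of_noiseless_epoch_is_silent(self, noiseless_cfg):
        trial = simulate_epoch(noiseless_cfg, "related", rng=0)
        assert np.all(trial[:, :1000] == 0)
        assert np.any(trial[:, 1000:] != 0)

    def test_seed_determinism(self, small_cfg):
        a = simulate_dataset(small_cfg)
        b = simulate_dataset(small_cfg)
        for ea, eb in zip(a, b):
            np.testing.assert_array_equal(ea.data, eb.data)
            assert list(ea.condition) == list(eb.condition)

    def test_unknown_condition_rejected(self, noiseless_cfg):
        with pytest.raises(ValueError):
            simulate_epoch(noiseless_cfg, "neutral", rng=0)


class TestIntermodulation:
    """The multiplicative interaction is the only source of f2±f1 power."""

    def _im_power(self, g, seed=1):
        cfg = SimConfig(n_participants=1, n_trials_per_condition=1,
                        noise_sd=0.0, alpha_amp=0.0, participant_sigma=0.0,
                        g_related=g, g_unrelated=g, seed=seed)
        spec = windowed_power(simulate_dataset(cfg), "tagging", 1, 150)
        return spec.power[0, 0, :, spec.freq_index(14.0)], \
            spec.power[0, 0, :, spec.freq_index(122.0)], \
            spec.power[0, 0, :, spec.freq_index(54.0)], cfg

    def test_nullity_without_interaction(self):
        p14, p122, p54, _ = self._im_power(0.0)
        assert np.all(p14 <= 1e-12 * p54.max())
        assert np.all(p122 <= 1e-12 * p54.max())

    def test_closed_form_power_at_difference_and_sum(self):
        # product-to-sum: g*a_sin*v_sin = (g*amp_a*amp_v/2)*(cos(2pi*14t)-cos(2pi*122t))
        g = 0.5
        p14, p122, _, cfg = self._im_power(g)
        expected = (g * cfg.amp_audio * cfg.amp_visual / 2.0 / 2.0) ** 2
        ch = int(np.argmax(cfg.topo_im))
        assert p14[ch] == pytest.approx(expected, rel=1e-9)
        assert p122[ch] == pytest.approx(expected, rel=1e-9)

    def test_monotonic_in_gain(self):
        powers = [self._im_power(g)[0].max() for g in (0.25, 0.5, 1.0, 2.0)]
        assert np.all(np.diff(powers) > 0)

    def test_topography_ranking_matches_weights(self):
        # noiseless 14 Hz bin power is exactly proportional to topo_im**2,
        # so the channel ranking follows the interaction weights
        p14, _, _, cfg = self._im_power(1.0)
        const = (cfg.amp_audio * cfg.amp_visual / 4.0) ** 2
        np.testing.assert_allclose(p14, const * cfg.topo_im ** 2,
                                   rtol=1e-9, atol=1e-30)
        # rounding restores the exact ties of symmetric channel pairs
        ranks = stats.rankdata(np.round(p14 / const, 9))
        np.testing.assert_allclose(ranks,
                                   stats.rankdata(np.round(cfg.topo_im ** 2, 9)))


class TestSimConfigValidation:
    def test_gain_ordering_enforced(self):
        with pytest.raises(ValueError):
            SimConfig(g_related=0.6, g_unrelated=0.3)

    def test_non_positive_amplitudes_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(amp_audio=0.0)

    def test_topography_shape_and_scale_checked(self, montage):
        with pytest.raises(ValueError):
            SimConfig(topo_im=np.ones(5))
        with pytest.raises(ValueError):
            SimConfig(topo_im=np.full(montage.n_channels, 0.5))

    def test_non_integer_sample_count_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(baseline_duration=0.0005)
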