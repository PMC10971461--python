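"""Stimulus synthesis: block structure, spectral shaping, dichoptic pairing,
and drift rendering."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ofrlab import stimulus
from ofrlab.stimulus import (
    DichopticPair,
    StimulusSpec,
    generate_line_profile,
    lowpass_raised_cosine,
    make_dichoptic_pair,
    measure_drift_speed,
    normalize_rms_contrast,
    render_frame_sequence,
    raised_cosine_gain,
)


def _small_spec(**kw):
    defaults = dict(aperture_deg=2.4, pixel_pitch_deg=0.03, seed=0)
    defaults.update(kw)
    return StimulusSpec(**defaults)


class TestLineProfile:
    def test_binary_block_structure(self):
        spec = _small_spec(seed=11)  # 80 samples, 40 blocks
        pat = generate_line_profile(spec)
        assert pat.values.size == spec.n_samples == 80
        c = spec.rms_contrast
        assert set(np.unique(pat.values)) <= {-c, c}
        blocks = pat.values.reshape(-1, spec.block_rows_px)
        assert (blocks == blocks[:, [0]]).all(), "values must be constant within a block"

    def test_mean_zero_in_expectation(self):
        # a single draw need not balance, but the grand mean over many seeds
        # must vanish within Monte-Carlo error
        spec = _small_spec()
        means = [generate_line_profile(_small_spec(seed=s)).values.mean() for s in range(4000)]
        means = np.asarray(means)
        se = means.std(ddof=1) / np.sqrt(means.size)
        assert abs(means.mean()) < 3 * se

    def test_independent_seeds_uncorrelated(self):
        rs = []
        for s in range(500):
            a = generate_line_profile(_small_spec(seed=2 * s)).values
            b = generate_line_profile(_small_spec(seed=2 * s + 1)).values
            rs.append(np.corrcoef(a, b)[0, 1])
        rs = np.asarray(rs)
        ci = 3 * rs.std(ddof=1) / np.sqrt(rs.size)
        assert abs(rs.mean()) < ci

    def test_invalid_spec_rejected(self):
        with pytest.raises(Exception):
            StimulusSpec(passband_cpd=0.75, stopband_cpd=0.375)
        with pytest.raises(Exception):
            StimulusSpec(rms_contrast=1.5)
        with pytest.raises(Exception):
            StimulusSpec(aperture_deg=-1)


class TestLowpass:
    # profile length chosen so 0.2, 0.5625 and 1.0 cpd all fall on DFT bins:
    # n * pitch = 80 deg -> frequency resolution 1/80 cpd
    @pytest.mark.parametrize(
        "freq_cpd,expected_gain",
        [(0.2, 1.0), (1.0, 0.0), (0.5625, 0.5)],  # pass, stop, transition midpoint
    )
    def test_sinusoid_gain(self, freq_cpd, expected_gain):
        spec = StimulusSpec(aperture_deg=80.0, pixel_pitch_deg=0.025, seed=0)
        n = spec.n_samples
        x = np.arange(n) * spec.pixel_pitch_deg
        sine = stimulus.LinePattern(values=np.sin(2 * np.pi * freq_cpd * x),
                                    pitch_deg=spec.pixel_pitch_deg)
        out = lowpass_raised_cosine(sine, spec)
        in_amp = np.abs(np.fft.rfft(sine.values))
        out_amp = np.abs(np.fft.rfft(out.values))
        k = int(np.argmax(in_amp))
        assert out_amp[k] / in_amp[k] == pytest.approx(expected_gain, abs=1e-9)

    def test_transition_midpoint_formula(self):
        # G(f) = (1 + cos(pi (f - 0.375) / 0.375)) / 2 at the band midpoint
        assert raised_cosine_gain(np.array([0.5625]), 0.375, 0.75)[0] == pytest.approx(0.5)

    @given(seed=st.integers(0, 10_000))
    def test_spectral_purity(self, seed):
        spec = StimulusSpec(seed=seed)
        raw = generate_line_profile(spec)
        filt = lowpass_raised_cosine(raw, spec)
        f = np.fft.rfftfreq(raw.values.size, d=spec.pixel_pitch_deg)
        raw_amp = np.abs(np.fft.rfft(raw.values))
        amp = np.abs(np.fft.rfft(filt.values))
        peak = amp.max()
        assert amp[f >= spec.stopband_cpd].max() < 1e-6 * peak
        passband = f <= spec.passband_cpd
        assert np.abs(amp[passband] - raw_amp[passband]).max() < 1e-6 * peak

    def test_too_short_pattern(self):
        spec = StimulusSpec(seed=0)
        short = stimulus.LinePattern(values=np.array([1.0, -1.0]), pitch_deg=0.03)
        with pytest.raises(Exception):
            lowpass_raised_cosine(short, spec)


class TestNormalization:
    def test_alternating_example(self):
        pat = stimulus.LinePattern(values=np.tile([0.1, -0.1], 8), pitch_deg=0.03)
        out = normalize_rms_contrast(pat, 0.30)
        np.testing.assert_allclose(out.values, np.tile([0.3, -0.3], 8))

    def test_filtered_pattern_hits_target(self):
        spec = StimulusSpec(seed=3)
        filt = lowpass_raised_cosine(generate_line_profile(spec), spec)
        out = normalize_rms_contrast(filt, 0.30)
        assert out.rms == pytest.approx(0.30, abs=1e-9)

    @given(target=st.floats(0.05, 0.9), seed=st.integers(0, 500))
    def test_idempotent(self, target, seed):
        pat = generate_line_profile(_small_spec(seed=seed))
        once = normalize_rms_contrast(pat, target)
        twice = normalize_rms_contrast(once, target)
        np.testing.assert_allclose(once.values, twice.values, rtol=1e-12)

    def test_all_zero_rejected(self):
        flat = stimulus.LinePattern(values=np.zeros(16), pitch_deg=0.03)
        with pytest.raises(Exception):
            normalize_rms_contrast(flat, 0.3)


class TestDichopticPair:
    def _pattern(self, seed=4):
        spec = StimulusSpec(seed=seed)
        return normalize_rms_contrast(lowpass_raised_cosine(generate_line_profile(spec), spec), 0.3)

    def test_correlated_identical(self):
        pair = make_dichoptic_pair(self._pattern(), +1)
        np.testing.assert_array_equal(pair.eye_a.values, pair.eye_b.values)
        assert np.corrcoef(pair.eye_a.values, pair.eye_b.values)[0, 1] == pytest.approx(1.0)

    def test_anticorrelated_negated(self):
        pair = make_dichoptic_pair(self._pattern(), -1)
        np.testing.assert_array_equal(pair.eye_b.values, -pair.eye_a.values)
        assert np.corrcoef(pair.eye_a.values, pair.eye_b.values)[0, 1] == pytest.approx(-1.0)

    def test_contrast_reversal_is_involution(self):
        pat = self._pattern()
        back = make_dichoptic_pair(
            make_dichoptic_pair(pat, -1).eye_b, -1
        ).eye_b
        np.testing.assert_array_equal(back.values, pat.values)

    def test_identical_spectra_and_contrast(self):
        pat = self._pattern()
        pc = make_dichoptic_pair(pat, +1)
        pa = make_dichoptic_pair(pat, -1)
        np.testing.assert_allclose(
            np.abs(np.fft.rfft(pa.eye_b.values)), np.abs(np.fft.rfft(pc.eye_b.values))
        )
        assert pa.eye_b.rms == pytest.approx(pc.eye_b.rms)

    def test_invalid_correlation_rejected(self):
        with pytest.raises(Exception):
            make_dichoptic_pair(self._pattern(), 0)


class TestRendering:
    def _pair(self, seed=5, correlation=+1):
        spec = StimulusSpec(seed=seed)
        pat = normalize_rms_contrast(lowpass_raised_cosine(generate_line_profile(spec), spec), 0.3)
        return spec, make_dichoptic_pair(pat, correlation)

    def test_frame_count_and_shift_arithmetic(self):
        spec, pair = self._pair()
        seq = render_frame_sequence(pair, "up", spec)
        assert seq.frames.shape[0] == 29  # round(0.200 s * 144 Hz)
        assert spec.shift_deg_per_frame == pytest.approx(50.0 / 144.0)

    def test_down_is_negated_up(self):
        spec, pair = self._pair()
        up = render_frame_sequence(pair, "up", spec)
        down = render_frame_sequence(pair, "down", spec)
        s_up = stimulus._estimate_cyclic_shift(up.frames[0, :, 0], up.frames[1, :, 0])
        s_dw = stimulus._estimate_cyclic_shift(down.frames[0, :, 0], down.frames[1, :, 0])
        assert s_dw == pytest.approx(-s_up, abs=1e-6)

    def test_drift_speed_recovered(self):
        spec, pair = self._pair()
        seq = render_frame_sequence(pair, "up", spec)
        speed = measure_drift_speed(seq)
        assert speed == pytest.approx(50.0, rel=0.01)

    def test_green_channel_zero(self):
        spec, pair = self._pair(correlation=-1)
        seq = render_frame_sequence(pair, "down", spec)
        rgb = seq.frame_rgb(3, width=8)
        assert (rgb[:, :, 1] == 0).all()

    def test_channels_carry_the_right_eye(self):
        spec, pair = self._pair(correlation=-1)
        seq = render_frame_sequence(pair, "up", spec)
        np.testing.assert_allclose(seq.frames[0, :, 0], pair.eye_a.values, atol=1e-9)
        np.testing.assert_allclose(seq.frames[0, :, 1], pair.eye_b.values, atol=1e-9)

    def test_excessive_drift_rejected(self):
        spec, pair = self._pair()
        fast = StimulusSpec(drift_speed_deg_s=1e6, seed=0)
        with pytest.raises(Exception):
            render_frame_sequence(pair, "up", fast)
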