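import numpy as np
import pytest
from scipy.signal import sosfreqz

from jawdio.audio_io import AudioSegment
from jawdio.cleaning import (
    BandstopSpec,
    bandstop_filter,
    block_envelope,
    informative_mask,
    remove_uninformative,
)
from jawdio.synthetic import BeepSpec, ClassSoundSpec, generate_segment, inject_beep

from conftest import tone_segment


def rms(x) -> float:
    return float(np.sqrt(np.mean(np.asarray(x, dtype=float) ** 2)))


def brute_force_envelope(samples, block_size, n_offsets):
    """Independent interval-overlap enumeration of the retained block means."""
    x = np.abs(np.asarray(samples, dtype=float))
    n = len(x)
    n_blocks = int(np.ceil(n / block_size))
    windows = []
    for k in range(n_offsets):
        offset = (k * block_size) // n_offsets
        for start in range(offset, n, block_size):
            end = min(start + block_size, n)
            if k > 0 and end - start < block_size:
                continue
            windows.append((start, end, x[start:end].mean()))
    retained = np.zeros(n_blocks)
    for b in range(n_blocks):
        b_start, b_end = b * block_size, min((b + 1) * block_size, n)
        for start, end, mean in windows:
            if start < b_end and end > b_start:
                retained[b] = max(retained[b], mean)
    return retained


class TestBandstopFilter:
    def test_beep_band_tone_attenuated_at_least_30db(self):
        spec = BandstopSpec()
        # frequency-response oracle: zero-phase application doubles the
        # magnitude response in dB, so predicted attenuation at 4 kHz is
        # 2 x the single-pass response
        w, h = sosfreqz(spec.sos(), worN=[4000.0], fs=22050)
        predicted_db = 2 * 20 * np.log10(np.abs(h[0]) + 1e-300)
        assert predicted_db <= -30
        seg = tone_segment(4000.0)
        out = bandstop_filter(seg, spec)
        measured_db = 20 * np.log10(rms(out.samples) / rms(seg.samples))
        assert measured_db <= -30

    def test_passband_tone_within_1db(self):
        spec = BandstopSpec()
        w, h = sosfreqz(spec.sos(), worN=[500.0], fs=22050)
        assert abs(2 * 20 * np.log10(np.abs(h[0]))) < 1  # oracle agrees
        seg = tone_segment(500.0)
        out = bandstop_filter(seg, spec)
        change_db = 20 * np.log10(rms(out.samples) / rms(seg.samples))
        assert abs(change_db) <= 1.0

    def test_zero_input_gives_zero_output(self):
        seg = AudioSegment(np.zeros(2000, dtype=np.int16))
        out = bandstop_filter(seg)
        assert not out.samples.any()

    def test_too_short_segment_raises(self):
        with pytest.raises(ValueError, match="too short"):
            bandstop_filter(AudioSegment(np.ones(10, dtype=np.int16)))


class TestBlockEnvelope:
    def test_constant_signal_means(self):
        env = block_envelope(np.full(2200, 200, dtype=np.int16))
        np.testing.assert_allclose(env.block_means, [200.0, 200.0])

    def test_all_zero(self):
        env = block_envelope(np.zeros(3300, dtype=np.int16))
        np.testing.assert_allclose(env.block_means, 0.0)

    def test_straddling_window_contributes_to_quiet_block(self):
        x = np.concatenate(
            [np.full(1100, 500, dtype=np.int16), np.zeros(1100, dtype=np.int16)]
        )
        env = block_envelope(x, n_offsets=4)
        assert env.block_means[1] > 0  # plain mean of that block is 0
        np.testing.assert_allclose(env.block_means, brute_force_envelope(x, 1100, 4))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_block_signals(self, seed):
        rng = np.random.default_rng(seed)
        n_blocks = int(rng.integers(3, 9))
        levels = rng.choice([0, 30, 90, 150, 400], size=n_blocks)
        tail = int(rng.integers(0, 1100))
        x = np.concatenate(
            [np.full(1100, lv, dtype=np.int16) for lv in levels]
            + [np.full(tail, 200, dtype=np.int16)]
        )
        env = block_envelope(x, n_offsets=4)
        np.testing.assert_allclose(env.block_means, brute_force_envelope(x, 1100, 4))


class TestInformativeMask:
    def test_threshold_comparison_keeps_equality(self):
        from jawdio.cleaning import EnvelopeMask

        env = EnvelopeMask(np.array([200.0, 50.0, 100.0]), 1100)
        np.testing.assert_array_equal(
            informative_mask(env, 100).mask, [True, False, True]
        )
        np.testing.assert_array_equal(informative_mask(env, 500).mask, [False] * 3)
        np.testing.assert_array_equal(informative_mask(env, 0).mask, [True] * 3)

    @pytest.mark.parametrize("seed", range(3))
    def test_monotone_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        env = block_envelope(rng.integers(0, 400, 8800).astype(np.int16))
        previous = informative_mask(env, 0).mask
        for threshold in (50, 100, 200, 400):
            current = informative_mask(env, threshold).mask
            assert not np.any(current & ~previous)  # raising never adds a block
            previous = current


class TestRemoveUninformative:
    def test_loud_head_with_long_silent_tail(self):
        # straddling windows keep one zero block adjacent to the loud run,
        # so 3 blocks (3300 samples) survive; oracle computed independently
        x = np.concatenate(
            [np.full(2200, 500, dtype=np.int16), np.zeros(22000, dtype=np.int16)]
        )
        retained = brute_force_envelope(x, 1100, 4)
        expected = sum(1100 for m in retained if m >= 100)
        out = remove_uninformative(AudioSegment(x))
        assert len(out.samples) == expected == 3300
        np.testing.assert_array_equal(out.samples[:2200], x[:2200])

    def test_constant_informative_signal_is_identity(self):
        x = np.full(5500, 200, dtype=np.int16)
        out = remove_uninformative(AudioSegment(x))
        np.testing.assert_array_equal(out.samples, x)

    def test_silence_becomes_empty(self):
        out = remove_uninformative(AudioSegment(np.zeros(4400, dtype=np.int16)))
        assert len(out.samples) == 0

    @pytest.mark.parametrize("seed", range(4))
    def test_idempotent_and_never_grows(self, seed):
        rng = np.random.default_rng(seed)
        levels = rng.choice([0, 20, 80, 120, 500], size=10)
        x = np.concatenate([np.full(1100, lv, dtype=np.int16) for lv in levels])
        once = remove_uninformative(AudioSegment(x))
        twice = remove_uninformative(once)
        assert len(once.samples) <= len(x)
        np.testing.assert_array_equal(twice.samples, once.samples)


class TestBeepRemovalEndToEnd:
    def test_cleaning_removes_beep_band_preserves_low_band(self):
        """Bandstop + block removal strips >= 90% of beep-band spectral
        magnitude while leaving sub-1 kHz magnitude within 10%."""
        spec = ClassSoundSpec(
            "chew", "alfalfa", "tall", mean_amplitude=0.127, mean_duration=1.0
        )
        chew = generate_segment(spec, 21)
        beeped = inject_beep(chew, BeepSpec(level=0.3, rate=4.0), 22)

        def band_mags(segment):
            mags = np.abs(np.fft.rfft(segment.samples.astype(float)))
            freqs = np.fft.rfftfreq(len(segment.samples), d=1 / 22050)
            return (
                mags[(freqs >= 3600) & (freqs < 4500)].sum(),
                mags[freqs < 1000].sum(),
            )

        cleaned = remove_uninformative(bandstop_filter(beeped))
        # at most the quiet fade-out tail block may drop
        assert len(cleaned.samples) >= len(beeped.samples) - 1100
        beep_before, low_before = band_mags(beeped)
        beep_after, low_after = band_mags(cleaned)
        assert beep_after <= 0.1 * beep_before
        assert abs(low_after - low_before) <= 0.1 * low_before
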