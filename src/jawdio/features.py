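"""Mel-frequency featurization of cleaned ingestive-sound segments.

Short-time analysis uses a 512-sample (23 ms) rolling window with a
220-sample (10 ms) hop at 22.05 kHz.  Each frame is windowed, transformed
with a real FFT, and squared to a power spectrum; 26 triangular filters
spaced on the Mel scale (m = 2595 log10(1 + f/700)) pool the power into
bands that are denser below 1 kHz, matching where cow ingestive sounds
carry their energy.  Band energies are expressed in dB with a floor, giving
a T x 26 matrix; variable-length segments are center-cropped or
symmetrically floor-padded to a fixed frame count for the classifiers.

An optional DCT-II over the bands converts the log-Mel matrix to cepstral
coefficients (MFCCs); the default pipeline feeds log-Mel directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dct

from .audio_io import AudioSegment, normalize_amplitude

DEFAULT_T_FIXED = 98  # frames for a 1 s segment: floor((22050-512)/220)+1


@dataclass(frozen=True)
class StftConfig:
    win_length: int = 512
    hop_length: int = 220
    window: str = "hann"
    n_fft: int = 512

    def __post_init__(self) -> None:
        if self.hop_length > self.win_length:
            raise ValueError("hop_length must be <= win_length")
        if self.n_fft < self.win_length:
            raise ValueError("n_fft must be >= win_length")
        if self.window not in ("hann", "rect"):
            raise ValueError(f"unsupported window {self.window!r}")

    def window_values(self) -> np.ndarray:
        if self.window == "hann":
            return np.hanning(self.win_length)
        return np.ones(self.win_length)


@dataclass(frozen=True)
class MelConfig:
    n_mels: int = 26
    f_min: float = 0.0
    f_max: float = 11025.0
    log_floor_db: float = -80.0
    eps: float = 1e-10
    use_dct: bool = False

    def __post_init__(self) -> None:
        if self.n_mels < 1:
            raise ValueError("n_mels must be >= 1")
        if not self.f_min < self.f_max:
            raise ValueError("f_min must be < f_max")


@dataclass
class MelSpectrogram:
    """T x n_mels dB-scaled band energies plus frame timing and provenance."""

    values: np.ndarray
    frame_times: np.ndarray
    stft_config: StftConfig
    mel_config: MelConfig

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


def hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def frame_count(n_samples: int, cfg: StftConfig) -> int:
    """floor((N - win)/hop) + 1, after padding short inputs to one window."""
    n = max(n_samples, cfg.win_length)
    return (n - cfg.win_length) // cfg.hop_length + 1


def frame_signal(samples: np.ndarray, cfg: StftConfig | None = None) -> np.ndarray:
    """Slice a signal into overlapping frames of win_length.

    Inputs shorter than one window are zero-padded at the end to a single
    frame.  Returns a (T, win_length) float array of normalized amplitudes.
    """
    cfg = cfg or StftConfig()
    x = normalize_amplitude(samples)
    if len(x) < cfg.win_length:
        x = np.pad(x, (0, cfg.win_length - len(x)))
    t = frame_count(len(samples), cfg)
    idx = np.arange(cfg.win_length)[None, :] + cfg.hop_length * np.arange(t)[:, None]
    return x[idx]


def power_spectrogram(frames: np.ndarray, cfg: StftConfig | None = None) -> np.ndarray:
    """Window each frame, real-FFT, squared magnitude: (T, n_fft//2 + 1)."""
    cfg = cfg or StftConfig()
    win = cfg.window_values()
    padded = frames * win
    if cfg.n_fft > cfg.win_length:
        padded = np.pad(padded, ((0, 0), (0, cfg.n_fft - cfg.win_length)))
    spectrum = np.fft.rfft(padded, n=cfg.n_fft, axis=1)
    return np.abs(spectrum) ** 2


def mel_filterbank(
    cfg: MelConfig | None = None, rate: int = 22050, n_fft: int = 512
) -> np.ndarray:
    """Triangular Mel filters mapped onto FFT bins: (n_mels, n_fft//2 + 1)."""
    cfg = cfg or MelConfig()
    if cfg.f_max > rate / 2:
        raise ValueError("f_max exceeds the Nyquist frequency")
    n_bins = n_fft // 2 + 1
    mel_edges = np.linspace(
        hz_to_mel(cfg.f_min), hz_to_mel(cfg.f_max), cfg.n_mels + 2
    )
    hz_edges = np.asarray(mel_to_hz(mel_edges))
    bin_freqs = np.arange(n_bins) * rate / n_fft
    fb = np.zeros((cfg.n_mels, n_bins))
    for i in range(cfg.n_mels):
        left, center, right = hz_edges[i], hz_edges[i + 1], hz_edges[i + 2]
        up = (bin_freqs - left) / (center - left)
        down = (right - bin_freqs) / (right - center)
        fb[i] = np.maximum(0.0, np.minimum(up, down))
    if not np.all(fb.sum(axis=1) > 0):
        raise ValueError(
            f"{cfg.n_mels} filters exceed the frequency resolution of "
            f"{n_bins} FFT bins: some filters cover no bin"
        )
    return fb


def filter_centers_hz(cfg: MelConfig | None = None) -> np.ndarray:
    cfg = cfg or MelConfig()
    mel_edges = np.linspace(hz_to_mel(cfg.f_min), hz_to_mel(cfg.f_max), cfg.n_mels + 2)
    return np.asarray(mel_to_hz(mel_edges))[1:-1]


def log_mel_spectrogram(
    segment: AudioSegment,
    stft_cfg: StftConfig | None = None,
    mel_cfg: MelConfig | None = None,
) -> MelSpectrogram:
    """dB Mel-band energies of a segment, shape (T, n_mels)."""
    stft_cfg = stft_cfg or StftConfig()
    mel_cfg = mel_cfg or MelConfig()
    if len(segment.samples) == 0:
        raise ValueError("cannot featurize an empty segment")
    frames = frame_signal(segment.samples, stft_cfg)
    power = power_spectrogram(frames, stft_cfg)
    fb = mel_filterbank(mel_cfg, rate=segment.rate, n_fft=stft_cfg.n_fft)
    banded = power @ fb.T
    values = 10.0 * np.log10(banded + mel_cfg.eps)
    values = np.maximum(values, mel_cfg.log_floor_db)
    if mel_cfg.use_dct:
        values = dct(values, type=2, axis=1, norm="ortho")
    times = (
        np.arange(values.shape[0]) * stft_cfg.hop_length + stft_cfg.win_length / 2
    ) / segment.rate
    return MelSpectrogram(values, times, stft_cfg, mel_cfg)


def to_fixed_input(mel: MelSpectrogram, t_fixed: int = DEFAULT_T_FIXED) -> np.ndarray:
    """Center-crop or symmetrically floor-pad to (t_fixed, n_mels)."""
    if t_fixed < 1:
        raise ValueError("t_fixed must be >= 1")
    values = mel.values
    t = values.shape[0]
    if t == t_fixed:
        return values.copy()
    if t > t_fixed:
        start = (t - t_fixed) // 2
        return values[start : start + t_fixed].copy()
    pad_total = t_fixed - t
    before = pad_total // 2
    after = pad_total - before
    fill = mel.mel_config.log_floor_db if not mel.mel_config.use_dct else 0.0
    return np.pad(values, ((before, after), (0, 0)), constant_values=fill)
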