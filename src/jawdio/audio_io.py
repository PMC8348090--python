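"""WAV segment and manifest I/O, amplitude normalization, and the ANM spectrum.

Ingestive-sound segments are mono, 16-bit PCM at 22.05 kHz.  Two amplitude
conventions coexist and are kept deliberately distinct:

* ``normalize_amplitude`` divides the signed samples by 2**16 — the literal
  normalization used before spectral analysis, with range [-0.5, 0.5).
* the segment-level amplitude *descriptor* (see :mod:`jawdio.evaluation`)
  is peak-to-peak range / 2**16, which lies in [0, 1] and matches the scale
  on which per-behavior amplitudes of cow ingestive sounds are reported.

The ANM ("absolute normalized magnitude") spectrum is the absolute real-FFT
of the normalized amplitudes, rescaled to sum to one, so it is invariant to
any positive gain applied to the recording.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

RATE = 22050
BEHAVIORS = ("bite", "chew", "chew_bite")
SPECIES = ("alfalfa", "tall_fescue")
HEIGHTS = ("tall", "short")

MANIFEST_COLUMNS = ["file", "behavior", "forage_species", "forage_height", "duration_s"]

INT16_MIN, INT16_MAX = -32768, 32767


class ManifestSchemaError(ValueError):
    """A manifest is missing columns or contains invalid rows."""


@dataclass
class AudioSegment:
    """A mono 16-bit segment of one ingestive event, with optional labels."""

    samples: np.ndarray
    rate: int = RATE
    behavior: str | None = None
    forage_species: str | None = None
    forage_height: str | None = None
    source_path: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 1:
            raise ValueError("AudioSegment samples must be one-dimensional")
        if self.samples.dtype != np.int16:
            if self.samples.size and (
                self.samples.min() < INT16_MIN or self.samples.max() > INT16_MAX
            ):
                raise ValueError("samples outside the 16-bit range [-32768, 32767]")
            self.samples = self.samples.astype(np.int16)
        if self.behavior is not None and self.behavior not in BEHAVIORS:
            raise ValueError(f"unknown behavior {self.behavior!r}")
        if self.forage_species is not None and self.forage_species not in SPECIES:
            raise ValueError(f"unknown forage species {self.forage_species!r}")
        if self.forage_height is not None and self.forage_height not in HEIGHTS:
            raise ValueError(f"unknown forage height {self.forage_height!r}")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate

    def with_samples(self, samples: np.ndarray) -> "AudioSegment":
        return replace(self, samples=np.asarray(samples))


@dataclass
class ANMSpectrum:
    """Absolute normalized magnitude spectrum: |rfft| rescaled to sum to one."""

    magnitudes: np.ndarray
    bin_freqs: np.ndarray
    m: int = field(default=0)

    def __post_init__(self) -> None:
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        self.bin_freqs = np.asarray(self.bin_freqs, dtype=float)
        if not self.m:
            self.m = len(self.magnitudes)

    def band_energy(self, low_hz: float, high_hz: float) -> float:
        """Sum of normalized magnitudes whose bin frequency lies in [low, high)."""
        sel = (self.bin_freqs >= low_hz) & (self.bin_freqs < high_hz)
        return float(self.magnitudes[sel].sum())


def read_wav(path: str | Path, *, resample: bool = False) -> AudioSegment:
    """Read a RIFF/PCM WAV file as a mono 22.05 kHz 16-bit segment.

    Multi-channel audio is averaged to mono.  A sampling rate other than
    22 050 Hz raises unless ``resample=True``, in which case the signal is
    resampled with polyphase filtering.  Non-16-bit sample depth is converted
    with a warning.
    """
    rate, data = wavfile.read(str(path))
    orig_dtype = data.dtype
    if data.ndim == 2:
        data = data.mean(axis=1)
    if orig_dtype != np.int16:
        warnings.warn(
            f"{path}: sample depth {orig_dtype} converted to 16-bit", stacklevel=2
        )
        if np.issubdtype(orig_dtype, np.floating):
            data = np.clip(np.rint(data * 32768.0), INT16_MIN, INT16_MAX)
        elif orig_dtype == np.int32:
            data = data / 65536
        elif orig_dtype == np.uint8:
            data = (np.asarray(data, dtype=float) - 128) * 256
        else:
            data = np.clip(data, INT16_MIN, INT16_MAX)
    data = np.asarray(np.rint(data), dtype=np.int16) if data.dtype != np.int16 else data
    if rate != RATE:
        if not resample:
            raise ValueError(
                f"{path}: sampling rate {rate} Hz != {RATE} Hz (pass resample=True)"
            )
        from scipy.signal import resample_poly
        from math import gcd

        g = gcd(RATE, rate)
        res = resample_poly(data.astype(float), RATE // g, rate // g)
        data = np.clip(np.rint(res), INT16_MIN, INT16_MAX).astype(np.int16)
        rate = RATE
    return AudioSegment(samples=data, rate=rate, source_path=str(path))


def write_wav(path: str | Path, segment: AudioSegment) -> None:
    wavfile.write(str(path), segment.rate, np.asarray(segment.samples, dtype=np.int16))


def normalize_amplitude(samples: np.ndarray) -> np.ndarray:
    """Divide 16-bit samples by 2**16 (range [-0.5, 0.5))."""
    return np.asarray(samples, dtype=float) / 65536.0


def anm_spectrum(segment: AudioSegment) -> ANMSpectrum:
    """Absolute normalized magnitude spectrum of a segment.

    Real-FFT of the normalized amplitudes, absolutized, then divided by the
    total so the magnitudes sum to one.  The FFT length equals the segment
    length (no zero padding); an all-zero segment has no spectrum to
    normalize and raises.
    """
    x = normalize_amplitude(segment.samples)
    if len(x) == 0 or not np.any(x):
        raise ValueError("ANM spectrum undefined for an all-zero (silent) segment")
    mags = np.abs(np.fft.rfft(x))
    total = mags.sum()
    mags = mags / total
    freqs = np.fft.rfftfreq(len(x), d=1.0 / segment.rate)
    return ANMSpectrum(magnitudes=mags, bin_freqs=freqs, m=len(mags))


def validate_manifest(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestSchemaError(f"manifest missing columns: {missing}")
    df = df[MANIFEST_COLUMNS].copy()
    bad_rows = []
    for i, row in df.iterrows():
        if row["behavior"] not in BEHAVIORS:
            bad_rows.append((i, f"behavior {row['behavior']!r}"))
        elif row["forage_species"] not in SPECIES:
            bad_rows.append((i, f"forage_species {row['forage_species']!r}"))
        elif row["forage_height"] not in HEIGHTS:
            bad_rows.append((i, f"forage_height {row['forage_height']!r}"))
        elif not row["duration_s"] > 0:
            bad_rows.append((i, f"duration_s {row['duration_s']!r} not > 0"))
    if bad_rows:
        detail = "; ".join(f"row {i}: {msg}" for i, msg in bad_rows[:10])
        raise ManifestSchemaError(f"invalid manifest rows: {detail}")
    if df["file"].duplicated().any():
        dupes = df.loc[df["file"].duplicated(), "file"].tolist()[:5]
        raise ManifestSchemaError(f"duplicate file paths in manifest: {dupes}")
    return df


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"file": str})
    return validate_manifest(df)


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    validate_manifest(manifest).to_csv(path, index=False)
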