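"""Data cleaning: bandstop removal of device beeps, low-power block removal.

Recording devices superimpose short beeps with center frequencies between
3.6 and 4.5 kHz on the ingestive audio; since cow ingestive sounds live
mostly below 1 kHz, a fixed Butterworth bandstop over that band removes the
beeps while leaving the signal of interest intact.  The filter is applied
forward-backward (zero phase) so impulsive bite transients are not smeared.

Uninformative (low-power) stretches are removed on the raw 16-bit scale:
absolute samples are averaged over 1100-sample blocks, with several
staggered window offsets per block, keeping only the maximal mean per block;
blocks whose maximal mean falls below a threshold of 100 are dropped
outright, the remainder concatenated with no padding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .audio_io import INT16_MAX, INT16_MIN, RATE, AudioSegment

DEFAULT_BLOCK_SIZE = 1100
DEFAULT_THRESHOLD = 100.0
DEFAULT_N_OFFSETS = 4


@dataclass(frozen=True)
class BandstopSpec:
    stop_low: float = 3600.0
    stop_high: float = 4500.0
    order: int = 4
    design: str = "butterworth"

    def __post_init__(self) -> None:
        if not 0 < self.stop_low < self.stop_high < RATE / 2:
            raise ValueError(
                f"stopband must satisfy 0 < low < high < {RATE / 2} Hz"
            )
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if self.design != "butterworth":
            raise ValueError(f"unsupported filter design {self.design!r}")

    def sos(self) -> np.ndarray:
        return butter(
            self.order,
            (self.stop_low, self.stop_high),
            btype="bandstop",
            fs=RATE,
            output="sos",
        )


@dataclass
class EnvelopeMask:
    """Per-block retained means and keep/drop decisions."""

    block_means: np.ndarray
    block_size: int
    threshold: float | None = None
    mask: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))

    def __post_init__(self) -> None:
        self.block_means = np.asarray(self.block_means, dtype=float)
        if self.threshold is not None and len(self.mask) == 0:
            self.mask = self.block_means >= self.threshold


def bandstop_filter(segment: AudioSegment, spec: BandstopSpec | None = None) -> AudioSegment:
    """Zero-phase bandstop over the beep band, requantized to int16."""
    spec = spec or BandstopSpec()
    sos = spec.sos()
    # sosfiltfilt needs padding headroom on both ends
    min_len = 3 * (sos.shape[0] * 2 + 1)
    if len(segment.samples) <= min_len:
        raise ValueError(
            f"segment of {len(segment.samples)} samples too short for a "
            f"zero-phase order-{spec.order} filter (needs > {min_len})"
        )
    filtered = sosfiltfilt(sos, segment.samples.astype(float))
    out = np.clip(np.rint(filtered), INT16_MIN, INT16_MAX).astype(np.int16)
    return segment.with_samples(out)


def block_envelope(
    samples: np.ndarray,
    block_size: int = DEFAULT_BLOCK_SIZE,
    n_offsets: int = DEFAULT_N_OFFSETS,
) -> EnvelopeMask:
    """Per-block maxima of staggered-window means of |samples|.

    Windows of ``block_size`` start at offsets k*block_size/n_offsets
    (k = 0..n_offsets-1) and step by ``block_size``; each non-overlapping
    block retains the maximum mean over every window overlapping it.  A tail
    shorter than ``block_size`` is its own block, averaged over its actual
    length.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    if n_offsets < 1:
        raise ValueError("n_offsets must be >= 1")
    x = np.abs(np.asarray(samples, dtype=float))
    n = len(x)
    if n == 0:
        return EnvelopeMask(np.array([]), block_size)
    n_blocks = -(-n // block_size)  # ceil
    retained = np.zeros(n_blocks)
    for k in range(n_offsets):
        offset = (k * block_size) // n_offsets
        for start in range(offset, n, block_size):
            end = min(start + block_size, n)
            if k > 0 and end - start < block_size:
                continue  # partial staggered windows are not meaningful means
            mean = x[start:end].mean()
            first = start // block_size
            last = (end - 1) // block_size
            for b in range(first, last + 1):
                retained[b] = max(retained[b], mean)
    return EnvelopeMask(retained, block_size)


def informative_mask(
    envelope: EnvelopeMask, threshold: float = DEFAULT_THRESHOLD
) -> EnvelopeMask:
    """Keep blocks whose retained mean is >= threshold (equality kept)."""
    return EnvelopeMask(
        envelope.block_means, envelope.block_size, threshold=threshold
    )


def remove_uninformative(
    segment: AudioSegment,
    block_size: int = DEFAULT_BLOCK_SIZE,
    threshold: float = DEFAULT_THRESHOLD,
    n_offsets: int = DEFAULT_N_OFFSETS,
) -> AudioSegment:
    """Drop low-power blocks and concatenate the rest (no padding)."""
    env = block_envelope(segment.samples, block_size, n_offsets)
    masked = informative_mask(env, threshold)
    kept = [
        segment.samples[b * block_size : (b + 1) * block_size]
        for b in range(len(masked.mask))
        if masked.mask[b]
    ]
    if kept:
        out = np.concatenate(kept)
    else:
        out = np.array([], dtype=np.int16)
    return segment.with_samples(out)
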