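"""Comparison encoders: CWT time-frequency scalograms and time-waveform plots.

The scalogram encoder supports the six mother wavelets used for the
time-frequency baseline (cgau8, cmor, fbsp, gaus8, mexh, morl); coefficient
magnitudes over a logarithmic scale grid covering 0.5-40 Hz are normalized,
colorized and resized exactly like the recurrence images. The waveform
encoder rasterizes the amplitude-vs-time polyline (1 px, no anti-aliasing,
no axes) onto a white square canvas.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pywt

from .preprocess import WORKING_FS, ECGSegment
from .recurrence_imaging import (EncodedImage, _resize_rgb, colorize,
                                 normalize_matrix)

#: supported mother-wavelet tags -> pywt names (complex families need
#: explicit bandwidth/center-frequency parameters in pywt >= 1.x)
SUPPORTED_WAVELETS = {
    "cgau8": "cgau8",
    "cmor": "cmor1.5-1.0",
    "fbsp": "fbsp2-1.5-1.0",
    "gaus8": "gaus8",
    "mexh": "mexh",
    "morl": "morl",
}


def default_scales(wavelet: str, fs: float = WORKING_FS, n_scales: int = 64,
                   f_min: float = 0.5, f_max: float = 40.0) -> np.ndarray:
    """Log-spaced CWT scales whose center frequencies span [f_min, f_max] Hz.

    scale = fc * fs / f, with fc the wavelet center frequency in
    cycles/sample, so increasing scale means decreasing frequency; the
    returned grid is sorted increasing (high to low frequency).
    """
    name = SUPPORTED_WAVELETS.get(wavelet, wavelet)
    fc = pywt.central_frequency(name)
    freqs = np.logspace(np.log10(f_max), np.log10(f_min), n_scales)
    return fc * fs / freqs


@dataclass(frozen=True)
class CWTParams:
    """Scalogram parameters; scales default to the 0.5-40 Hz grid."""

    wavelet: str = "morl"
    scales: Optional[tuple] = None
    fs: float = WORKING_FS
    out_size: int = 299
    colormap: str = "rp-bgyr"

    def __post_init__(self):
        if self.wavelet not in SUPPORTED_WAVELETS:
            raise ValueError(
                f"unsupported wavelet {self.wavelet!r}; supported: "
                f"{sorted(SUPPORTED_WAVELETS)}")
        if self.scales is not None:
            s = np.asarray(self.scales, dtype=float)
            if np.any(s <= 0) or np.any(np.diff(s) <= 0):
                raise ValueError("scales must be positive and increasing")

    def scale_grid(self) -> np.ndarray:
        if self.scales is not None:
            return np.asarray(self.scales, dtype=float)
        return default_scales(self.wavelet, fs=self.fs)


def _segment_samples(segment: Union[ECGSegment, np.ndarray]) -> np.ndarray:
    if isinstance(segment, ECGSegment):
        return segment.samples
    return np.asarray(segment, dtype=float).ravel()


def cwt_magnitude(samples: np.ndarray, params: CWTParams) -> np.ndarray:
    """CWT coefficient magnitudes, shape (n_scales, n_samples)."""
    name = SUPPORTED_WAVELETS[params.wavelet]
    coefs, _ = pywt.cwt(samples, params.scale_grid(), name,
                        sampling_period=1.0 / params.fs)
    return np.abs(coefs)


def cwt_image(segment: Union[ECGSegment, np.ndarray],
              params: CWTParams = CWTParams(),
              source: Optional[dict] = None) -> EncodedImage:
    """Time-frequency scalogram image of one segment."""
    samples = _segment_samples(segment)
    mag = cwt_magnitude(samples, params)
    rgb = colorize(normalize_matrix(mag))
    out = _resize_rgb(rgb, params.out_size)
    src = dict(source or {})
    src.setdefault("encoder", f"cwt:{params.wavelet}")
    return EncodedImage(pixels=out, source=src)


def _draw_line(canvas: np.ndarray, r0: int, c0: int, r1: int, c1: int) -> None:
    """Bresenham line of black pixels; 1 px thick, no anti-aliasing."""
    dr, dc = abs(r1 - r0), abs(c1 - c0)
    sr = 1 if r0 < r1 else -1
    sc = 1 if c0 < c1 else -1
    err = (dc if dc > dr else -dr) / 2
    r, c = r0, c0
    while True:
        canvas[r, c, :] = 0.0
        if r == r1 and c == c1:
            break
        e2 = err
        if e2 > -dc:
            err -= dr
            c += sc
        if e2 < dr:
            err += dc
            r += sr


def waveform_image(segment: Union[ECGSegment, np.ndarray],
                   out_size: int = 299,
                   source: Optional[dict] = None) -> EncodedImage:
    """Amplitude-vs-time polyline on a white canvas; no axes, ticks or text.

    The vertical range is the segment min/max padded by 5%; a constant
    segment renders as a horizontal line at mid-height.
    """
    samples = _segment_samples(segment)
    n = samples.size
    if n < 2:
        raise ValueError("waveform rendering needs at least 2 samples")
    lo, hi = samples.min(), samples.max()
    if hi == lo:
        lo, hi = lo - 0.5, hi + 0.5
    else:
        margin = 0.05 * (hi - lo)
        lo, hi = lo - margin, hi + margin

    canvas = np.ones((out_size, out_size, 3))
    cols = np.round(np.arange(n) * (out_size - 1) / (n - 1)).astype(int)
    # row 0 at the top: high amplitudes map to small row indices
    rows = np.round((hi - samples) / (hi - lo) * (out_size - 1)).astype(int)
    for i in range(n - 1):
        _draw_line(canvas, rows[i], cols[i], rows[i + 1], cols[i + 1])
    src = dict(source or {})
    src.setdefault("encoder", "waveform")
    return EncodedImage(pixels=canvas, source=src)
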