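"""Call spectrograms with a fixed analysis geometry.

Spectrograms use 43 ms Hann windows with 80 % overlap, magnitude (not
power) scaling, and are truncated to the 0–10 kHz analysis band shared by
all datasets.  :func:`prepare_input` converts a spectrogram into the
fixed-size, normalized matrix the auto-encoder consumes;
:func:`peak_frequency` measures the call-level spectral peak used as the
``Peak`` predictor of the classification tree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from pilotcalls.contour import MAX_FREQ_HZ

#: default auto-encoder input geometry (frequency bins x time frames)
DEFAULT_TARGET_SHAPE = (128, 128)


@dataclass
class Spectrogram:
    """Time-frequency magnitude matrix with explicit axes."""

    magnitudes: np.ndarray  # (n_freq_bins, n_frames), magnitude scale
    freq_axis_hz: np.ndarray
    time_axis_s: np.ndarray
    window_s: float
    overlap_frac: float

    def __post_init__(self) -> None:
        if self.magnitudes.shape != (self.freq_axis_hz.size, self.time_axis_s.size):
            raise ValueError("spectrogram axes do not match matrix dimensions")
        if not np.all(np.isfinite(self.magnitudes)) or np.any(self.magnitudes < 0):
            raise ValueError("magnitudes must be finite and non-negative")
        if self.freq_axis_hz[-1] > MAX_FREQ_HZ:
            raise ValueError(f"frequency axis exceeds the {MAX_FREQ_HZ:g} Hz analysis band")


def _clip_and_rate(voc, sample_rate_hz):
    """Accept either a Vocalization-like object or a raw sample array."""
    if hasattr(voc, "clip") and hasattr(voc, "sample_rate_hz"):
        return np.asarray(voc.clip, dtype=float), float(voc.sample_rate_hz)
    if sample_rate_hz is None:
        raise ValueError("sample_rate_hz required when passing a raw sample array")
    return np.asarray(voc, dtype=float), float(sample_rate_hz)


def compute_spectrogram(voc, sample_rate_hz=None, window_s: float = 0.043,
                        overlap_frac: float = 0.8) -> Spectrogram:
    """Short-time magnitude spectrum of one call clip.

    Frames are taken without padding, so the frame count equals
    ``floor((N - W) / hop) + 1`` with ``W = round(window_s * fs)`` and
    ``hop = round(W * (1 - overlap_frac))``.  Bins above 10 kHz are
    dropped.  The FFT size is the next power of two >= ``W``.
    """
    clip, fs = _clip_and_rate(voc, sample_rate_hz)
    if clip.size == 0:
        raise ValueError("empty clip")
    nperseg = int(round(window_s * fs))
    hop = int(round(nperseg * (1 - overlap_frac)))
    if hop < 1:
        raise ValueError("overlap_frac too close to 1 for this window")
    if clip.size < nperseg:
        raise ValueError(
            f"clip of {clip.size} samples is shorter than one {nperseg}-sample window; "
            "zero-pad the clip or use prepare_input on a longer excerpt"
        )
    nfft = 1 << (nperseg - 1).bit_length()
    freqs, times, sxx = signal.spectrogram(
        clip, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg - hop,
        nfft=nfft, detrend=False, mode="magnitude", scaling="spectrum",
    )
    keep = freqs <= MAX_FREQ_HZ
    return Spectrogram(sxx[keep], freqs[keep], times, window_s, overlap_frac)


#: Gaussian smoothing of the prepared matrix, (freq bins, time frames).
#: Widens the thin F0 ridge so that calls of one type whose fundamentals
#: differ by natural (or jittered) frequency scaling still overlap in
#: pixel space; without it a fully connected auto-encoder sees nearly
#: orthogonal images for same-type calls and the embedding fragments.
DEFAULT_SMOOTH_SIGMA = (3.0, 2.0)


def prepare_input(spec: Spectrogram | np.ndarray,
                  target_shape: tuple[int, int] = DEFAULT_TARGET_SHAPE,
                  smooth_sigma: tuple[float, float] = DEFAULT_SMOOTH_SIGMA) -> np.ndarray:
    """Normalize a spectrogram into the fixed-size auto-encoder input.

    The magnitude matrix is log1p-compressed, min-max scaled to [0, 1]
    per call, its frequency axis linearly resampled to ``target_shape[0]``
    bins, its time axis centrally padded/cropped to ``target_shape[1]``
    frames, then Gaussian-smoothed by ``smooth_sigma`` and rescaled to
    [0, 1].  All-zero input yields all-zero output.  A matrix that
    already satisfies the output contract (target shape, minimum exactly
    0 and maximum exactly 1, or all zero) is returned unchanged, which
    makes the operation idempotent.
    """
    mat = spec.magnitudes if isinstance(spec, Spectrogram) else np.asarray(spec, dtype=float)
    n_bins, n_frames = target_shape
    if mat.shape == target_shape:
        lo, hi = mat.min(), mat.max()
        if (lo == 0.0 and hi == 1.0) or hi == 0.0:
            return mat.astype(float).copy()

    def _minmax(x):
        hi, lo = x.max(), x.min()
        return (x - lo) / (hi - lo) if hi > lo else np.zeros_like(x)

    out = _minmax(np.log1p(np.maximum(mat, 0.0)))
    # frequency axis: linear interpolation onto the target bin grid
    if out.shape[0] != n_bins:
        src = np.linspace(0.0, 1.0, out.shape[0])
        dst = np.linspace(0.0, 1.0, n_bins)
        out = np.array([np.interp(dst, src, col) for col in out.T]).T
    # time axis: central pad/crop
    t = out.shape[1]
    if t < n_frames:
        pad = n_frames - t
        left = pad // 2
        out = np.pad(out, ((0, 0), (left, pad - left)))
    elif t > n_frames:
        start = (t - n_frames) // 2
        out = out[:, start:start + n_frames]
    if smooth_sigma is not None and max(smooth_sigma) > 0:
        out = _minmax(ndimage.gaussian_filter(out, sigma=smooth_sigma))
    return out


def peak_frequency(spec: Spectrogram) -> float:
    """Frequency of the spectral peak of the whole call.

    The magnitudes are summed over frames and the frequency of the
    maximizing bin is returned; ties break toward the lower frequency.
    """
    profile = spec.magnitudes.sum(axis=1)
    if not np.any(profile > 0):
        raise ValueError("peak frequency undefined for an all-zero spectrogram")
    return float(spec.freq_axis_hz[int(np.argmax(profile))])
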