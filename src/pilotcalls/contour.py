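"""Fundamental-frequency (F0) contours: data model, file I/O and the
harmonic-halving correction.

A contour is an ordered sequence of ``(time_s, freq_hz)`` samples of the
fundamental of one vocalization.  Silent pauses inside a call appear as
gaps in the time axis (no samples), not as zero-frequency points.  The
analysis band is capped at 10 kHz throughout the package, so contour
frequencies must lie strictly inside ``(0, 10000)`` Hz.

Annotators sometimes trace the first harmonic instead of the fundamental
when the latter is faint; :func:`halve_harmonic` divides every frequency
by two to move such a trace back onto F0, and
:func:`check_harmonic_support` quantifies whether a trace has spectral
energy at twice its frequency (expected when the trace sits on the true
fundamental of a harmonic call).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MAX_FREQ_HZ = 10_000.0


@dataclass
class F0Contour:
    """Ordered (time, frequency) samples of one call's fundamental."""

    call_id: str
    times_s: np.ndarray
    freqs_hz: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        if self.times_s.shape != self.freqs_hz.shape or self.times_s.ndim != 1:
            raise ValueError(f"contour {self.call_id!r}: times and freqs must be 1-D and equal length")
        if self.times_s.size < 2:
            raise ValueError(f"contour {self.call_id!r}: needs at least 2 points")
        if not np.all(np.isfinite(self.times_s)) or not np.all(np.isfinite(self.freqs_hz)):
            raise ValueError(f"contour {self.call_id!r}: non-finite values")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError(f"contour {self.call_id!r}: times must be strictly increasing")
        if np.any(self.freqs_hz <= 0) or np.any(self.freqs_hz >= MAX_FREQ_HZ):
            raise ValueError(f"contour {self.call_id!r}: frequencies must lie in (0, {MAX_FREQ_HZ:g}) Hz")

    @property
    def duration_s(self) -> float:
        """Onset-to-offset duration, internal silent gaps included."""
        return float(self.times_s[-1] - self.times_s[0])

    def __len__(self) -> int:
        return self.times_s.size


def read_contours(path) -> list[F0Contour]:
    """Read contours from a CSV with columns ``call_id,time_s,freq_hz``.

    Rows are grouped by ``call_id`` and sorted by time within each call;
    input row order is irrelevant.  Duplicate timestamps within a call or
    frequencies outside the analysis band raise ``ValueError``.
    """
    df = pd.read_csv(path)
    required = {"call_id", "time_s", "freq_hz"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: contour CSV must have columns {sorted(required)}")
    contours = []
    for call_id, grp in df.groupby("call_id", sort=True):
        grp = grp.sort_values("time_s", kind="mergesort")
        times = grp["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(times) == 0):
            raise ValueError(f"{path}: duplicate timestamp in contour {call_id!r}")
        contours.append(F0Contour(str(call_id), times, grp["freq_hz"].to_numpy(dtype=float)))
    return contours


def write_contours(contours, path) -> None:
    """Write contours to CSV (``call_id,time_s,freq_hz``, 6-decimal seconds/Hz).

    The 6-decimal fixed format makes write/read round-trips lossless at
    the precision annotation tools provide.
    """
    with open(path, "w") as fh:
        fh.write("call_id,time_s,freq_hz\n")
        for c in contours:
            for t, f in zip(c.times_s, c.freqs_hz):
                fh.write(f"{c.call_id},{t:.6f},{f:.6f}\n")


def halve_harmonic(contour: F0Contour) -> F0Contour:
    """Divide every frequency by two, leaving times (and gaps) untouched.

    Used when a contour was traced on the first harmonic rather than the
    fundamental.
    """
    return F0Contour(contour.call_id, contour.times_s.copy(), contour.freqs_hz / 2.0)


def check_harmonic_support(contour: F0Contour, spec, tol_frac: float = 0.05,
                           support_factor: float = 4.0) -> float:
    """Fraction of contour points with spectral energy at twice their frequency.

    For each point, the spectrogram frame nearest in time is inspected in
    the band ``2*F0 * (1 ± tol_frac)``; the point counts as supported when
    the maximum magnitude in that band exceeds ``support_factor`` times
    the frame's median magnitude (the factor keeps the extreme order
    statistic of plain noise bins below the bar).  A fraction near 1 indicates the trace sits on the
    fundamental of a harmonic call; a fraction near 0 suggests the trace
    follows the first harmonic (so :func:`halve_harmonic` applies) — or
    that the call simply has no second harmonic, a documented blind spot
    of this check.

    Returns 0.0 with a warning when ``2*F0`` is above the analysis band
    for every point.
    """
    if not (0 < tol_frac < 1):
        raise ValueError("tol_frac must be in (0, 1)")
    band_top = float(spec.freq_axis_hz[-1])
    targets = 2.0 * contour.freqs_hz
    if np.all(targets > band_top):
        warnings.warn(
            f"contour {contour.call_id!r}: 2*F0 above the analysis band for all points; "
            "harmonic support cannot be assessed",
            stacklevel=2,
        )
        return 0.0
    n_tested = 0
    n_supported = 0
    for t, target in zip(contour.times_s, targets):
        if target > band_top:
            continue
        j = int(np.argmin(np.abs(spec.time_axis_s - t)))
        frame = spec.magnitudes[:, j]
        lo, hi = target * (1 - tol_frac), target * (1 + tol_frac)
        sel = (spec.freq_axis_hz >= lo) & (spec.freq_axis_hz <= hi)
        if not np.any(sel):
            continue
        n_tested += 1
        if frame[sel].max() > support_factor * np.median(frame):
            n_supported += 1
    return n_supported / n_tested if n_tested else 0.0
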