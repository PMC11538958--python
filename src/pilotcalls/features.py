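"""Acoustic features of F0 contours: the eight classification-tree
predictors plus auxiliary frequency statistics.

Structural definitions
----------------------
* A **segment** is a unit within a vocalization separated from its
  neighbour by a short silent gap (shorter than 0.1 s; a pause of 0.5 s
  or more would split the vocalization itself, so such gaps are invalid
  inside one contour).
* An **element** is a unit within a segment separated by an abrupt
  frequency shift with no silent gap.  The shift is operationalized as a
  relative jump ``|df| / min(f)`` above ``jump_frac`` between samples no
  more than ``max_dt_s`` apart.
* An **inflection** is a reversal in the sign of the contour's slope,
  counted on a median-smoothed contour within elements only — never
  across silent gaps or element steps, which are discontinuities rather
  than slope reversals.  Slopes below ``min_slope_hz_per_s`` in magnitude
  are treated as zero and cannot create a reversal; this suppresses
  annotator jitter on flat parts.

All detector thresholds are keyword-configurable; the defaults are the
package's operating point and are recorded with any exported feature
table.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from pilotcalls.contour import F0Contour
from pilotcalls import spectro

#: silent pauses longer than this split segments (annotation pauses
#: shorter than this are treated as continuous drawing)
GAP_MIN_S = 0.02
#: a pause this long or longer should have split the vocalization itself
GAP_INVALID_S = 0.5
#: element boundary: relative frequency jump threshold ...
JUMP_FRAC = 0.25
#: ... within at most this much time
JUMP_MAX_DT_S = 0.02
#: median-smoothing window (points) for inflection counting
SMOOTH_WIN_PTS = 5
#: inflection counting breaks the slope sequence only at quasi-instantaneous
#: steps (an element boundary proper), not at every jump the element rule's
#: looser 20 ms window would accept — otherwise a steep reversal sampled at
#: ~10 ms spacing would be swallowed
INFLECTION_BREAK_DT_S = 0.005
#: slope dead-zone for inflection counting, Hz/s
MIN_SLOPE_HZ_PER_S = 100.0


@dataclass
class CallFeatures:
    """The eight tree predictors plus auxiliary frequency statistics."""

    call_id: str
    dur_s: float
    bw_hz: float
    peak_hz: float | None
    range_ratio: float
    trend_ratio: float
    n_inflections: int
    n_segments: int
    n_elements: int
    f_min_hz: float
    f_max_hz: float
    f_mean_hz: float
    f_start_hz: float
    f_end_hz: float

    def __post_init__(self) -> None:
        if self.dur_s <= 0:
            raise ValueError(f"{self.call_id}: non-positive duration")
        if not (self.f_min_hz <= self.f_mean_hz <= self.f_max_hz):
            raise ValueError(f"{self.call_id}: mean frequency outside [min, max]")
        if self.range_ratio < 1 or self.trend_ratio <= 0:
            raise ValueError(f"{self.call_id}: invalid ratio features")


def detect_segments(contour: F0Contour, gap_min_s: float = GAP_MIN_S,
                    gap_invalid_s: float = GAP_INVALID_S) -> list[tuple[np.ndarray, np.ndarray]]:
    """Split a contour into segments at silent pauses longer than ``gap_min_s``.

    Returns a list of ``(times, freqs)`` arrays, one per segment.  An
    internal pause of ``gap_invalid_s`` (0.5 s) or more is an error: by
    the detection convention such a pause separates two distinct
    vocalizations, so it cannot occur inside one contour.
    """
    dts = np.diff(contour.times_s)
    if np.any(dts >= gap_invalid_s):
        raise ValueError(
            f"contour {contour.call_id!r}: internal silent gap >= {gap_invalid_s} s; "
            "a pause that long separates distinct vocalizations and cannot occur inside one call"
        )
    breaks = np.flatnonzero(dts > gap_min_s) + 1
    segments = []
    for idx in np.split(np.arange(len(contour)), breaks):
        segments.append((contour.times_s[idx], contour.freqs_hz[idx]))
    return segments


def _element_breaks(times: np.ndarray, freqs: np.ndarray,
                    jump_frac: float, max_dt_s: float) -> np.ndarray:
    """Indices i where an element boundary lies between samples i-1 and i."""
    df = np.abs(np.diff(freqs))
    dt = np.diff(times)
    ref = np.minimum(freqs[:-1], freqs[1:])
    return np.flatnonzero((df / ref > jump_frac) & (dt <= max_dt_s)) + 1


def detect_elements(segments, jump_frac: float = JUMP_FRAC,
                    max_dt_s: float = JUMP_MAX_DT_S):
    """Count elements per segment and in total.

    An element boundary is declared between consecutive samples of a
    segment when the relative frequency jump exceeds ``jump_frac`` within
    at most ``max_dt_s``.  Returns ``(per_segment_counts, total)``.
    """
    per_segment = []
    for times, freqs in segments:
        per_segment.append(1 + len(_element_breaks(times, freqs, jump_frac, max_dt_s)))
    return per_segment, int(sum(per_segment))


def _running_median(x: np.ndarray, win: int) -> np.ndarray:
    if win <= 1 or x.size < 3:
        return x
    return pd.Series(x).rolling(win, center=True, min_periods=1).median().to_numpy()


def count_inflections(contour: F0Contour, smooth_win_pts: int = SMOOTH_WIN_PTS,
                      min_slope_hz_per_s: float = MIN_SLOPE_HZ_PER_S,
                      gap_min_s: float = GAP_MIN_S, jump_frac: float = JUMP_FRAC,
                      break_dt_s: float = INFLECTION_BREAK_DT_S) -> int:
    """Number of slope-sign reversals of the (smoothed) contour.

    The slope sequence is broken at silent gaps and at quasi-instantaneous
    frequency steps (jumps above ``jump_frac`` within ``break_dt_s``):
    a step between elements is a discontinuity, not a slope reversal.
    Within each run the frequency series is median-smoothed over
    ``smooth_win_pts`` points, slopes with magnitude below
    ``min_slope_hz_per_s`` are zeroed, and reversals are counted as sign
    changes between consecutive non-zero slopes.  Set
    ``smooth_win_pts=1`` to disable smoothing.
    """
    total = 0
    for times, freqs in detect_segments(contour, gap_min_s=gap_min_s):
        breaks = _element_breaks(times, freqs, jump_frac, break_dt_s)
        for idx in np.split(np.arange(times.size), breaks):
            t, f = times[idx], freqs[idx]
            if t.size < 3:
                continue
            f = _running_median(f, smooth_win_pts)
            slopes = np.diff(f) / np.diff(t)
            signs = np.sign(slopes)
            signs[np.abs(slopes) < min_slope_hz_per_s] = 0
            signs = signs[signs != 0]
            total += int(np.count_nonzero(np.diff(signs)))
    return total


def compute_features(contour: F0Contour, spec=None, *, gap_min_s: float = GAP_MIN_S,
                     jump_frac: float = JUMP_FRAC, jump_max_dt_s: float = JUMP_MAX_DT_S,
                     smooth_win_pts: int = SMOOTH_WIN_PTS,
                     min_slope_hz_per_s: float = MIN_SLOPE_HZ_PER_S) -> CallFeatures:
    """Measure all features of one call.

    ``dur_s`` is onset to offset, internal silent gaps included;
    ``f_mean_hz`` is the time-weighted (trapezoidal, per segment) mean of
    F0 so that irregular annotation density does not bias it;
    ``range_ratio`` = max/min frequency; ``trend_ratio`` = start/end
    frequency; ``bw_hz`` = max − min exactly.  ``peak_hz`` comes from the
    spectrogram when one is supplied, else ``None``.
    """
    segments = detect_segments(contour, gap_min_s=gap_min_s)
    _, n_elements = detect_elements(segments, jump_frac=jump_frac, max_dt_s=jump_max_dt_s)
    n_inflections = count_inflections(
        contour, smooth_win_pts=smooth_win_pts, min_slope_hz_per_s=min_slope_hz_per_s,
        gap_min_s=gap_min_s, jump_frac=jump_frac)

    f = contour.freqs_hz
    integral = 0.0
    support = 0.0
    for times, freqs in segments:
        if times.size > 1:
            integral += float(np.trapezoid(freqs, times))
            support += float(times[-1] - times[0])
    f_mean = integral / support if support > 0 else float(f.mean())
    f_mean = float(np.clip(f_mean, f.min(), f.max()))  # guard round-off at the edges

    return CallFeatures(
        call_id=contour.call_id,
        dur_s=contour.duration_s,
        bw_hz=float(f.max() - f.min()),
        peak_hz=spectro.peak_frequency(spec) if spec is not None else None,
        range_ratio=float(f.max() / f.min()),
        trend_ratio=float(f[0] / f[-1]),
        n_inflections=n_inflections,
        n_segments=len(segments),
        n_elements=n_elements,
        f_min_hz=float(f.min()),
        f_max_hz=float(f.max()),
        f_mean_hz=float(f_mean),
        f_start_hz=float(f[0]),
        f_end_hz=float(f[-1]),
    )


FEATURE_COLUMNS = ["call_id", "dur_s", "bw_hz", "peak_hz", "range_ratio", "trend_ratio",
                   "n_inflections", "n_segments", "n_elements",
                   "f_min_hz", "f_max_hz", "f_mean_hz", "f_start_hz", "f_end_hz"]


def features_table(features) -> pd.DataFrame:
    """Assemble :class:`CallFeatures` records into the canonical table."""
    return pd.DataFrame([asdict(ft) for ft in features], columns=FEATURE_COLUMNS)
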