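"""Recording and label-track ingestion.

Label tracks follow the Audacity text dialect: one call per line,
TAB-separated ``start_s<TAB>end_s<TAB>label`` with seconds from file
start.  Two labelled signals count as distinct vocalizations only when at
least 0.5 s of silence separates them; :func:`merge_events` enforces that
convention.  Clips are resampled to a common 22 050 Hz analysis rate so
that the analysis band is capped at (just above) 10 kHz for every
dataset, whatever its original sampling rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.io import wavfile

#: minimum silence separating two distinct vocalizations, seconds
MIN_SEPARATION_S = 0.5
#: common analysis sampling rate, Hz (Nyquist 11 025 Hz > 10 kHz band cap)
ANALYSIS_RATE_HZ = 22_050


@dataclass(frozen=True)
class LabelEvent:
    """One annotated time interval ``[start_s, end_s)`` in a recording."""

    start_s: float
    end_s: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (math.isfinite(self.start_s) and math.isfinite(self.end_s)):
            raise ValueError("label times must be finite")
        if not 0 <= self.start_s < self.end_s:
            raise ValueError(f"invalid label interval [{self.start_s}, {self.end_s})")


@dataclass
class Vocalization:
    """A per-call audio clip cut from a source recording."""

    call_id: str
    dataset: str
    clip: np.ndarray
    sample_rate_hz: float
    start_s: float
    end_s: float
    source_file: str = ""


def read_wav(path):
    """Read a WAV file as ``(sample_rate_hz, float64 samples)``.

    Integer PCM is scaled to [-1, 1]; multichannel data keeps its
    (n_samples, n_channels) layout.
    """
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(np.float64)
    return rate, data


def write_wav(path, sample_rate_hz: int, samples: np.ndarray) -> None:
    """Write mono float32 PCM."""
    wavfile.write(path, int(sample_rate_hz), np.asarray(samples, dtype=np.float32))


def read_label_track(path) -> list[LabelEvent]:
    """Parse an Audacity-style label track into sorted :class:`LabelEvent`.

    Lines need at least two TAB-separated numeric columns; a third label
    column is optional.  Parse and validation errors cite the 1-based
    line number.
    """
    events = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected at least 2 TAB-separated columns")
            try:
                start, end = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric time field") from exc
            label = parts[2] if len(parts) > 2 else ""
            try:
                events.append(LabelEvent(start, end, label))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return sorted(events, key=lambda e: (e.start_s, e.end_s))


def merge_events(events, min_gap_s: float = MIN_SEPARATION_S) -> list[LabelEvent]:
    """Merge consecutive events separated by less than ``min_gap_s`` of silence.

    Implements the detection convention that two signals are distinct
    vocalizations only if at least 0.5 s separates them.  Merging is
    transitive (a chain of closely spaced events collapses into one
    spanning event) and idempotent.  Labels of merged events are joined
    with ``+``.
    """
    events = sorted(events, key=lambda e: (e.start_s, e.end_s))
    if not events:
        return []
    merged = [events[0]]
    for ev in events[1:]:
        prev = merged[-1]
        if ev.start_s - prev.end_s < min_gap_s:
            labels = [s for s in (prev.label, ev.label) if s]
            merged[-1] = LabelEvent(prev.start_s, max(prev.end_s, ev.end_s),
                                    "+".join(labels) if prev.label != ev.label else prev.label)
        else:
            merged.append(ev)
    return merged


def extract_vocalizations(audio: np.ndarray, sample_rate_hz: float, events,
                          dataset: str, *, analysis_rate_hz: int = ANALYSIS_RATE_HZ,
                          channel: int = 0, source_file: str = "",
                          call_ids=None) -> list[Vocalization]:
    """Cut one clip per event and resample it to the analysis rate.

    Multichannel audio is reduced to ``channel``.  Resampling uses
    polyphase filtering, whose anti-alias low-pass removes content above
    the target Nyquist (11 025 Hz), so every clip's usable band is capped
    just above the 10 kHz analysis limit.  Events extending past the end
    of the audio raise ``ValueError``.
    """
    audio = np.asarray(audio, dtype=float)
    if audio.ndim == 2:
        audio = audio[:, channel]
    total_s = audio.size / sample_rate_hz
    if call_ids is not None and len(call_ids) != len(events):
        raise ValueError("call_ids must match events in length")
    vocs = []
    for i, ev in enumerate(events):
        if ev.end_s > total_s + 0.5 / sample_rate_hz:
            raise ValueError(
                f"event [{ev.start_s}, {ev.end_s}) {ev.label!r} extends past the "
                f"{total_s:.3f} s recording"
            )
        i0 = int(round(ev.start_s * sample_rate_hz))
        i1 = int(round(ev.end_s * sample_rate_hz))
        clip = audio[i0:i1]
        if int(sample_rate_hz) != int(analysis_rate_hz):
            g = math.gcd(int(analysis_rate_hz), int(sample_rate_hz))
            clip = signal.resample_poly(clip, int(analysis_rate_hz) // g, int(sample_rate_hz) // g)
        cid = call_ids[i] if call_ids is not None else (ev.label or f"{dataset}_{i:04d}")
        vocs.append(Vocalization(cid, dataset, clip, float(analysis_rate_hz),
                                 ev.start_s, ev.end_s, source_file))
    return vocs


def write_manifest(vocs, path) -> None:
    """Write the vocalization manifest CSV (`call_id,dataset,source_file,start_s,end_s`)."""
    with open(path, "w") as fh:
        fh.write("call_id,dataset,source_file,start_s,end_s\n")
        for v in vocs:
            fh.write(f"{v.call_id},{v.dataset},{v.source_file},{v.start_s:.6f},{v.end_s:.6f}\n")
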