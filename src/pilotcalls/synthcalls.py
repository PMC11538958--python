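"""Synthetic pilot-whale-like call generator.

Renders labelled datasets — waveforms, Audacity-style label tracks,
ground-truth contours and structural counts — so that every downstream
stage (embedding, clustering, feature extraction, statistics, tree) can
be validated offline against a planted repertoire.

A call is described by a :class:`ContourPrototype`: an ordered list of
pieces of its fundamental-frequency (F0) contour.  Tonal pieces
(``constant``, ``linear-sweep``, ``parabolic``) carry the frequency
course; an ``element-boundary`` piece encodes an instantaneous frequency
step with no silent gap (separating two elements of one segment); a
``segment-gap`` piece encodes a short silent pause (< 0.5 s, separating
two segments of one vocalization).  A ``parabolic`` piece starts and ends
at ``f_start_hz`` with its extremum ``f_end_hz`` at the midpoint, so it
contributes exactly one slope reversal (inflection).

Waveforms are harmonic stacks (harmonic ``k`` at amplitude ``1/k``) with
continuous phase per segment and raised-cosine fades, embedded in white
Gaussian noise scaled so that the in-band SNR over the call support
matches the requested value.  The amplitude model is a stand-in for
pulsed-call structure, not a claim about pilot-whale sound production.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from pilotcalls.contour import F0Contour, write_contours
from pilotcalls.audio_io import write_wav

logger = logging.getLogger(__name__)

TONAL_KINDS = {"constant", "linear-sweep", "parabolic"}
PIECE_KINDS = TONAL_KINDS | {"element-boundary", "segment-gap"}

#: contour sampling density, points per second (>= 100 required downstream)
POINTS_PER_S = 200
#: time offset across an element boundary (instantaneous step), seconds
BOUNDARY_DT_S = 0.002


@dataclass(frozen=True)
class Piece:
    """One piece of an F0 contour prototype."""

    kind: str
    duration_s: float = 0.0
    f_start_hz: float = 0.0
    f_end_hz: float = 0.0


@dataclass
class ContourPrototype:
    """A call type: ordered contour pieces plus harmonic count."""

    type_id: str
    pieces: list
    n_harmonics: int = 1

    def __post_init__(self) -> None:
        if self.n_harmonics < 1:
            raise ValueError(f"{self.type_id}: n_harmonics must be >= 1")
        if not self.pieces:
            raise ValueError(f"{self.type_id}: prototype has no pieces")
        total = 0.0
        for i, p in enumerate(self.pieces):
            if p.kind not in PIECE_KINDS:
                raise ValueError(f"{self.type_id}: piece {i} has invalid kind {p.kind!r}")
            if p.kind == "segment-gap":
                if not (0 < p.duration_s < 0.5):
                    raise ValueError(
                        f"{self.type_id}: piece {i}: segment gaps must be shorter than 0.5 s "
                        "(longer pauses separate distinct vocalizations)")
                if i == 0 or i == len(self.pieces) - 1:
                    raise ValueError(f"{self.type_id}: piece {i}: gap cannot start or end a call")
                total += p.duration_s
            elif p.kind == "element-boundary":
                if i == 0 or i == len(self.pieces) - 1:
                    raise ValueError(f"{self.type_id}: piece {i}: boundary cannot start or end a call")
                if self.pieces[i - 1].kind not in TONAL_KINDS or self.pieces[i + 1].kind not in TONAL_KINDS:
                    raise ValueError(f"{self.type_id}: piece {i}: boundary must join two tonal pieces")
            else:
                if p.duration_s <= 0:
                    raise ValueError(f"{self.type_id}: piece {i}: non-positive duration")
                for f in (p.f_start_hz, p.f_end_hz or p.f_start_hz):
                    if not (0 < f < 10_000):
                        raise ValueError(f"{self.type_id}: piece {i}: frequency {f} outside (0, 10000) Hz")
                total += p.duration_s
        if not (0.05 <= total <= 5.0):
            raise ValueError(f"{self.type_id}: total duration {total:.3f} s outside [0.05, 5.0] s")


@dataclass(frozen=True)
class StructuralCounts:
    """Planted truth for one rendered call."""

    n_segments: int
    n_elements: int
    n_inflections: int


@dataclass
class GroundTruthRecord:
    call_id: str
    type_id: str
    dataset: str
    counts: StructuralCounts


@dataclass
class SynthSpec:
    """Full description of a synthetic multi-dataset rendering run.

    ``dataset_assignment`` maps ``type_id`` to a dataset name or to
    ``"mixed"`` (calls of a mixed type are spread over all datasets).
    ``inter_call_gap_s`` must be at least 0.5 s so rendered calls remain
    distinct vocalizations under the detection convention.
    """

    prototypes: list
    calls_per_type: int = 30
    freq_jitter_frac: float = 0.05
    time_jitter_frac: float = 0.05
    snr_db: float = 20.0
    sample_rate_hz: int = 22_050
    inter_call_gap_s: float = 1.0
    dataset_assignment: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.calls_per_type < 1:
            raise ValueError("calls_per_type must be >= 1")
        if not math.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")
        if self.inter_call_gap_s < 0.5:
            raise ValueError("inter_call_gap_s must be >= 0.5 s (distinct-vocalization rule)")
        if self.dataset_assignment is not None:
            ids = {p.type_id for p in self.prototypes}
            unknown = set(self.dataset_assignment) - ids
            if unknown:
                raise ValueError(f"dataset_assignment references unknown types {sorted(unknown)}")

    @property
    def datasets(self) -> list:
        if not self.dataset_assignment:
            return ["synth"]
        names = sorted(set(self.dataset_assignment.values()) - {"mixed"})
        return names or ["synth"]


def _piece_slope_signs(piece: Piece) -> list:
    """Analytic slope-sign tokens of a tonal piece (for planted truth)."""
    if piece.kind == "constant":
        return [0]
    if piece.kind == "linear-sweep":
        return [int(np.sign(piece.f_end_hz - piece.f_start_hz))]
    if piece.kind == "parabolic":
        s = int(np.sign(piece.f_end_hz - piece.f_start_hz))
        return [s, -s]
    raise ValueError(piece.kind)


def _true_counts(pieces) -> StructuralCounts:
    """Segment/element/inflection truth from piece semantics alone.

    Independent of any sampled contour: segments = 1 + number of gaps,
    elements = segments + number of boundaries, and inflections are the
    sign changes in the analytic slope-sign sequence of each element run
    (zero slopes ignored).
    """
    n_segments = 1 + sum(p.kind == "segment-gap" for p in pieces)
    n_elements = n_segments + sum(p.kind == "element-boundary" for p in pieces)
    n_inflections = 0
    run: list = []
    for p in list(pieces) + [Piece("element-boundary")]:
        if p.kind in TONAL_KINDS:
            run.extend(_piece_slope_signs(p))
        else:
            signs = [s for s in run if s != 0]
            n_inflections += sum(1 for a, b in zip(signs, signs[1:]) if a != b)
            run = []
    return StructuralCounts(n_segments, n_elements, n_inflections)


def _sample_piece(piece: Piece, t0: float, time_scale: float, freq_scale: float):
    """Sample one tonal piece on the contour grid, endpoints included."""
    d = piece.duration_s * time_scale
    n = max(1, int(round(d * POINTS_PER_S)))
    t = t0 + np.linspace(0.0, d, n + 1)
    x = np.linspace(0.0, 1.0, n + 1)
    fs, fe = piece.f_start_hz * freq_scale, piece.f_end_hz * freq_scale
    if piece.kind == "constant":
        f = np.full(n + 1, fs)
    elif piece.kind == "linear-sweep":
        f = fs + (fe - fs) * x
    else:  # parabolic: start/end at fs, extremum fe at midpoint
        f = fs + (fe - fs) * (1.0 - (2.0 * x - 1.0) ** 2)
    return t, f


def render_contour(proto: ContourPrototype, freq_scale: float = 1.0,
                   time_scale: float = 1.0, call_id: str | None = None):
    """Sample a prototype into an :class:`F0Contour` plus planted truth.

    Jitter is applied multiplicatively: ``freq_scale`` scales every
    frequency and ``time_scale`` every duration and gap, so the
    structural counts are scale-invariant.  The contour is sampled at
    200 points/s; an element boundary appears as a 2 ms time offset with
    an instantaneous frequency step, a segment gap as an absent time
    range.
    """
    times: list = []
    freqs: list = []
    t_cursor = 0.0
    for i, piece in enumerate(proto.pieces):
        if piece.kind == "segment-gap":
            t_cursor += piece.duration_s * time_scale
            continue
        if piece.kind == "element-boundary":
            t_cursor += BOUNDARY_DT_S
            continue
        t, f = _sample_piece(piece, t_cursor, time_scale, freq_scale)
        if times and times[-1] is not None and len(times) and t[0] <= times[-1] + 1e-12:
            t, f = t[1:], f[1:]  # shared junction sample with the previous tonal piece
        times.extend(t.tolist())
        freqs.extend(f.tolist())
        t_cursor = times[-1]
    contour = F0Contour(call_id or proto.type_id, np.array(times), np.array(freqs))
    return contour, _true_counts(proto.pieces)


def _harmonic_signal(contour: F0Contour, n_harmonics: int, sample_rate_hz: float,
                     gap_min_s: float = 0.02, fade_s: float = 0.005):
    """Unit-amplitude harmonic stack for one contour.

    Returns ``(samples, support_mask, (band_lo, band_hi))`` where samples
    span [t_first, t_last] of the contour at the audio rate.  Phase is
    the cumulative integral of the instantaneous frequency, restarted at
    each segment; each segment gets raised-cosine fades (>= 5 ms where
    the segment allows).  Harmonics that would cross Nyquist anywhere are
    dropped with a logged warning.
    """
    fs = float(sample_rate_hz)
    nyq = fs / 2.0
    t0 = contour.times_s[0]
    n_total = int(round((contour.times_s[-1] - t0) * fs)) + 1
    out = np.zeros(n_total)
    support = np.zeros(n_total, dtype=bool)
    f_max = float(contour.freqs_hz.max())
    kept = [k for k in range(1, n_harmonics + 1) if k * f_max < nyq]
    for k in range(1, n_harmonics + 1):
        if k not in kept:
            logger.warning("%s: harmonic %d exceeds Nyquist (%.0f Hz) and was dropped",
                           contour.call_id, k, nyq)
    breaks = np.flatnonzero(np.diff(contour.times_s) > gap_min_s) + 1
    for idx in np.split(np.arange(len(contour)), breaks):
        ts, fr = contour.times_s[idx], contour.freqs_hz[idx]
        i0 = int(round((ts[0] - t0) * fs))
        i1 = int(round((ts[-1] - t0) * fs)) + 1
        tt = t0 + np.arange(i0, i1) / fs
        inst = np.interp(tt, ts, fr)
        phase = 2.0 * np.pi * np.cumsum(inst) / fs
        seg = np.zeros(i1 - i0)
        for k in kept:
            seg += np.sin(k * phase) / k
        n_fade = min(int(round(fade_s * fs)), max(1, (i1 - i0) // 4))
        env = np.ones(i1 - i0)
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_fade) / n_fade)) if n_fade else np.array([])
        env[:n_fade] = ramp
        env[i1 - i0 - n_fade:] = ramp[::-1]
        out[i0:i1] = seg * env
        support[i0:i1] = True
    kmax = max(kept) if kept else 1
    band = (0.8 * float(contour.freqs_hz.min()), min(nyq, 1.1 * kmax * f_max))
    return out, support, band


def _signal_gain(sig: np.ndarray, support: np.ndarray, band, snr_db: float, nyq: float) -> float:
    """Amplitude gain making the in-band SNR over the call support equal snr_db
    against unit-variance white noise (whose in-band power is bw/nyq)."""
    p_sig = float(np.mean(sig[support] ** 2))
    p_noise_band = (band[1] - band[0]) / nyq
    return math.sqrt(10.0 ** (snr_db / 10.0) * p_noise_band / p_sig)


@dataclass
class RenderedWaveform:
    samples: np.ndarray
    sample_rate_hz: float
    pad_s: float
    support_mask: np.ndarray
    band_hz: tuple
    snr_db: float


def render_waveform(contour: F0Contour, n_harmonics: int, snr_db: float,
                    sample_rate_hz: float, rng: np.random.Generator,
                    pad_s: float = 0.25) -> RenderedWaveform:
    """Render one call as harmonic stack plus calibrated white noise.

    The clip spans the contour padded by ``pad_s`` of noise on each side.
    Noise has unit variance; the signal is scaled so the in-band SNR over
    the call support equals ``snr_db``.
    """
    sig, support, band = _harmonic_signal(contour, n_harmonics, sample_rate_hz)
    n_pad = int(round(pad_s * sample_rate_hz))
    gain = _signal_gain(sig, support, band, snr_db, sample_rate_hz / 2.0)
    samples = rng.standard_normal(sig.size + 2 * n_pad)
    samples[n_pad:n_pad + sig.size] += gain * sig
    mask = np.zeros(samples.size, dtype=bool)
    mask[n_pad:n_pad + sig.size] = support
    return RenderedWaveform(samples, float(sample_rate_hz), pad_s, mask, band, snr_db)


def measure_inband_snr(samples: np.ndarray, sample_rate_hz: float,
                       support_mask: np.ndarray, band_hz) -> float:
    """Estimate the in-band SNR (dB) of a rendered clip.

    Welch band power is computed over contiguous call-support runs and
    over contiguous noise-only runs; the noise contribution is subtracted
    from the call-band power before forming the ratio.  Serves as the
    independent check of the generator's SNR calibration.
    """
    def _band_power(x):
        nper = min(1024, x.size)
        f, p = sps.welch(x, fs=sample_rate_hz, nperseg=nper)
        sel = (f >= band_hz[0]) & (f <= band_hz[1])
        return float(np.trapezoid(p[sel], f[sel]))

    def _runs(mask):
        edges = np.flatnonzero(np.diff(mask.astype(int))) + 1
        chunks = np.split(np.arange(mask.size), edges)
        return [c for c in chunks if mask[c[0]] and c.size >= 256]

    p_call = [( _band_power(samples[c]), c.size) for c in _runs(support_mask)]
    p_noise = [(_band_power(samples[c]), c.size) for c in _runs(~support_mask)]
    if not p_call or not p_noise:
        raise ValueError("need both call-support and noise-only regions to measure SNR")
    pc = sum(p * n for p, n in p_call) / sum(n for _, n in p_call)
    pn = sum(p * n for p, n in p_noise) / sum(n for _, n in p_noise)
    return 10.0 * math.log10(max(pc - pn, 1e-30) / pn)


def _jitter_scale(rng: np.random.Generator, frac: float) -> float:
    if frac <= 0:
        return 1.0
    return 1.0 + float(np.clip(rng.normal(0.0, frac), -2.5 * frac, 2.5 * frac))


def _assignment_counts(spec: SynthSpec) -> dict:
    """Per-dataset list of (prototype, n_calls) honouring mixed types."""
    datasets = spec.datasets
    per_ds = {name: [] for name in datasets}
    for proto in spec.prototypes:
        target = (spec.dataset_assignment or {}).get(proto.type_id, "mixed")
        if target != "mixed":
            per_ds[target].append((proto, spec.calls_per_type))
            continue
        base, extra = divmod(spec.calls_per_type, len(datasets))
        for j, name in enumerate(datasets):
            n = base + (1 if j < extra else 0)
            if n:
                per_ds[name].append((proto, n))
    return per_ds


@dataclass
class DatasetBundle:
    dataset: str
    wav_path: str
    label_path: str
    truth_path: str
    contour_path: str
    truth: list
    contours: list


def render_dataset(spec: SynthSpec, out_dir) -> dict:
    """Render every dataset bundle of ``spec`` into ``out_dir``.

    Per dataset ``name`` the bundle holds ``name.wav`` (mono float32),
    ``name_labels.txt`` (Audacity label track, 6-decimal seconds),
    ``name_truth.csv`` (planted per-call structure) and
    ``name_contours.csv`` (planted F0 contours in file time).  Each
    bundle uses its own RNG stream seeded from ``spec.seed`` plus the
    dataset index, so bundles regenerate independently and the whole run
    is byte-deterministic.
    """
    os.makedirs(out_dir, exist_ok=True)
    per_ds = _assignment_counts(spec)
    fs = float(spec.sample_rate_hz)
    bundles = {}
    for ds_index, dataset in enumerate(spec.datasets):
        rng = np.random.default_rng(spec.seed + ds_index)
        placed = []  # (t_offset, contour, gain, sig, support)
        truth = []
        contours = []
        t_cursor = spec.inter_call_gap_s
        for proto, n_calls in per_ds[dataset]:
            for j in range(n_calls):
                call_id = f"{dataset}_{proto.type_id}_{j:03d}"
                f_scale = _jitter_scale(rng, spec.freq_jitter_frac)
                t_scale = _jitter_scale(rng, spec.time_jitter_frac)
                contour, counts = render_contour(proto, f_scale, t_scale, call_id)
                contour = F0Contour(call_id, contour.times_s + t_cursor, contour.freqs_hz)
                sig, support, band = _harmonic_signal(contour, proto.n_harmonics, fs)
                gain = _signal_gain(sig, support, band, spec.snr_db, fs / 2.0)
                placed.append((contour.times_s[0], sig * gain, support))
                truth.append(GroundTruthRecord(call_id, proto.type_id, dataset, counts))
                contours.append(contour)
                t_cursor = contour.times_s[-1] + spec.inter_call_gap_s
        n_total = int(round((t_cursor) * fs)) + 1
        samples = rng.standard_normal(n_total)
        for t_off, sig, _ in placed:
            i0 = int(round(t_off * fs))
            samples[i0:i0 + sig.size] += sig

        wav_path = os.path.join(out_dir, f"{dataset}.wav")
        label_path = os.path.join(out_dir, f"{dataset}_labels.txt")
        truth_path = os.path.join(out_dir, f"{dataset}_truth.csv")
        contour_path = os.path.join(out_dir, f"{dataset}_contours.csv")
        write_wav(wav_path, spec.sample_rate_hz, samples)
        with open(label_path, "w") as fh:
            for c in contours:
                fh.write(f"{c.times_s[0]:.6f}\t{c.times_s[-1]:.6f}\t{c.call_id}\n")
        with open(truth_path, "w") as fh:
            fh.write("call_id,type_id,dataset,n_segments,n_elements,n_inflections\n")
            for rec in truth:
                k = rec.counts
                fh.write(f"{rec.call_id},{rec.type_id},{rec.dataset},"
                         f"{k.n_segments},{k.n_elements},{k.n_inflections}\n")
        write_contours(contours, contour_path)
        bundles[dataset] = DatasetBundle(dataset, wav_path, label_path, truth_path,
                                         contour_path, truth, contours)
    return bundles


def default_prototypes() -> list:
    """The default planted repertoire: 10 call types spanning 1-4 segments,
    1-4 elements and 0-9 inflections, fundamentals roughly 1-8 kHz and
    durations 0.3-1.36 s, with harmonic stacks of 1-3 partials."""
    P = Piece
    return [
        ContourPrototype("t01_const", [P("constant", 0.60, 2000, 2000)], 3),
        ContourPrototype("t02_up", [P("linear-sweep", 0.50, 1000, 3000)], 3),
        ContourPrototype("t03_down", [P("linear-sweep", 0.30, 5200, 3600)], 1),
        ContourPrototype("t04_hill", [P("parabolic", 0.90, 2500, 4200)], 2),
        ContourPrototype("t05_zigzag", [
            P("linear-sweep", 0.15, 1500, 2500), P("linear-sweep", 0.15, 2500, 1500),
            P("linear-sweep", 0.15, 1500, 2500), P("linear-sweep", 0.15, 2500, 1500)], 3),
        ContourPrototype("t06_twoseg", [
            P("linear-sweep", 0.30, 3000, 4600), P("segment-gap", 0.08),
            P("linear-sweep", 0.30, 4600, 3000)], 2),
        ContourPrototype("t07_threeel", [
            P("constant", 0.20, 3000, 3000), P("element-boundary"),
            P("constant", 0.20, 3900, 3900), P("element-boundary"),
            P("linear-sweep", 0.25, 3000, 4800)], 2),
        ContourPrototype("t08_pulses", [
            P("constant", 0.15, 6200, 6200), P("segment-gap", 0.06),
            P("constant", 0.15, 6200, 6200), P("segment-gap", 0.06),
            P("constant", 0.15, 6200, 6200), P("segment-gap", 0.06),
            P("constant", 0.15, 6200, 6200)], 1),
        ContourPrototype("t09_fastzig", [
            P("linear-sweep", 0.08, 5000 + 1500 * (i % 2), 5000 + 1500 * ((i + 1) % 2))
            for i in range(10)], 1),
        ContourPrototype("t10_complex", [
            P("parabolic", 0.30, 1800, 1000), P("segment-gap", 0.05),
            P("linear-sweep", 0.20, 1200, 2100), P("element-boundary"),
            P("linear-sweep", 0.20, 2800, 2100)], 3),
    ]


def default_synth_spec(seed: int = 0, calls_per_type: int = 30,
                       snr_db: float = 20.0) -> SynthSpec:
    """The default study conditions: 10 planted types x 30 calls at 20 dB
    in-band SNR with 5 % multiplicative frequency/duration jitter, split
    over two datasets with two shared ("mixed") types."""
    protos = default_prototypes()
    assignment = {
        "t01_const": "siteA", "t02_up": "siteA", "t04_hill": "siteA", "t09_fastzig": "siteA",
        "t03_down": "siteB", "t06_twoseg": "siteB", "t08_pulses": "siteB", "t10_complex": "siteB",
        "t05_zigzag": "mixed", "t07_threeel": "mixed",
    }
    return SynthSpec(prototypes=protos, calls_per_type=calls_per_type,
                     freq_jitter_frac=0.05, time_jitter_frac=0.05, snr_db=snr_db,
                     sample_rate_hz=22_050, inter_call_gap_s=1.0,
                     dataset_assignment=assignment, seed=seed)
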