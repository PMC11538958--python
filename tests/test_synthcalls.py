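"""Generator checks: piece semantics, SNR calibration, determinism."""

import numpy as np
import pytest

from pilotcalls import synthcalls as sc
from pilotcalls.synthcalls import ContourPrototype, Piece, SynthSpec


class TestRenderContour:
    def test_constant_piece_identity_case(self):
        proto = ContourPrototype("c", [Piece("constant", 1.0, 3000, 3000)])
        contour, truth = sc.render_contour(proto)
        assert np.allclose(contour.freqs_hz, 3000)
        assert (truth.n_segments, truth.n_elements, truth.n_inflections) == (1, 1, 0)
        assert contour.duration_s == pytest.approx(1.0)
        # sampled densely enough for downstream detectors
        assert len(contour) >= 100

    def test_element_boundary_forces_two_elements(self):
        proto = ContourPrototype("e", [
            Piece("constant", 0.3, 2000, 2000), Piece("element-boundary"),
            Piece("linear-sweep", 0.3, 4000, 6000)])
        _, truth = sc.render_contour(proto)
        assert (truth.n_segments, truth.n_elements) == (1, 2)

    def test_segment_gap_forces_two_segments(self):
        proto = ContourPrototype("g", [
            Piece("linear-sweep", 0.2, 2000, 4000), Piece("segment-gap", 0.08),
            Piece("linear-sweep", 0.2, 4000, 2000)])
        contour, truth = sc.render_contour(proto)
        assert truth.n_segments == 2
        gaps = np.diff(contour.times_s)
        assert gaps.max() == pytest.approx(0.08, abs=1e-9)

    def test_parabolic_piece_contributes_one_inflection(self):
        proto = ContourPrototype("p", [Piece("parabolic", 0.5, 2000, 3500)])
        _, truth = sc.render_contour(proto)
        assert truth.n_inflections == 1

    def test_invalid_piece_kind_names_index(self):
        with pytest.raises(ValueError, match="piece 1"):
            ContourPrototype("bad", [Piece("constant", 0.3, 2000, 2000),
                                     Piece("wiggle", 0.1, 100, 200)])

    def test_jitter_scales_frequencies_and_times(self):
        proto = ContourPrototype("j", [Piece("linear-sweep", 0.4, 2000, 4000)])
        base, _ = sc.render_contour(proto)
        jit, _ = sc.render_contour(proto, freq_scale=1.1, time_scale=0.9)
        assert jit.freqs_hz.max() == pytest.approx(1.1 * base.freqs_hz.max())
        assert jit.duration_s == pytest.approx(0.9 * base.duration_s, rel=0.02)


class TestRenderWaveform:
    def test_pure_tone_dominates_expected_bin(self):
        from pilotcalls.spectro import compute_spectrogram, peak_frequency
        proto = ContourPrototype("c", [Piece("constant", 1.0, 3000, 3000)])
        contour, _ = sc.render_contour(proto)
        rw = sc.render_waveform(contour, 1, 60.0, 22050, np.random.default_rng(0))
        spec = compute_spectrogram(rw.samples, 22050)
        assert peak_frequency(spec) == pytest.approx(3000, abs=25)

    @pytest.mark.parametrize("snr_db", [0.0, 10.0, 20.0, 40.0])
    def test_snr_calibration_within_1db(self, snr_db):
        """Welch-based in/out-of-band power estimate is the independent
        oracle for the generator's SNR calibration."""
        proto = sc.default_prototypes()[1]
        contour, _ = sc.render_contour(proto)
        rw = sc.render_waveform(contour, proto.n_harmonics, snr_db, 22050,
                                np.random.default_rng(7), pad_s=0.5)
        measured = sc.measure_inband_snr(rw.samples, 22050, rw.support_mask, rw.band_hz)
        assert measured == pytest.approx(snr_db, abs=1.0)

    def test_gap_is_at_noise_floor(self):
        """RMS inside a segment gap matches the known unit noise variance."""
        proto = ContourPrototype("g", [
            Piece("constant", 0.3, 3000, 3000), Piece("segment-gap", 0.08),
            Piece("constant", 0.3, 3000, 3000)])
        contour, _ = sc.render_contour(proto)
        rw = sc.render_waveform(contour, 1, 20.0, 22050, np.random.default_rng(3), pad_s=0.3)
        fs = 22050
        g0 = int((0.3 + 0.31) * fs)
        g1 = int((0.3 + 0.37) * fs)
        gap_rms_db = 20 * np.log10(np.sqrt(np.mean(rw.samples[g0:g1] ** 2)))
        assert abs(gap_rms_db) < 3.0  # noise sigma is 1 -> 0 dB

    def test_harmonic_above_nyquist_dropped_not_error(self, caplog):
        proto = ContourPrototype("h", [Piece("constant", 0.2, 8000, 8000)])
        contour, _ = sc.render_contour(proto)
        with caplog.at_level("WARNING"):
            rw = sc.render_waveform(contour, 3, 20.0, 22050, np.random.default_rng(0))
        assert "dropped" in caplog.text
        assert np.all(np.isfinite(rw.samples))


class TestRenderDataset:
    def test_counts_and_bundle_exclusivity(self, tmp_path):
        protos = sc.default_prototypes()[:2]
        spec = SynthSpec(prototypes=protos, calls_per_type=3, seed=5,
                         dataset_assignment={"t01_const": "a", "t02_up": "b"})
        bundles = sc.render_dataset(spec, tmp_path)
        assert set(bundles) == {"a", "b"}
        for name, b in bundles.items():
            assert len(b.truth) == 3
            assert {r.type_id for r in b.truth} == ({"t01_const"} if name == "a" else {"t02_up"})
            with open(b.label_path) as fh:
                assert len(fh.readlines()) == 3

    def test_byte_identical_rerun(self, tmp_path):
        spec = sc.default_synth_spec(seed=11, calls_per_type=2)
        b1 = sc.render_dataset(spec, tmp_path / "one")
        b2 = sc.render_dataset(spec, tmp_path / "two")
        for ds in b1:
            for attr in ("wav_path", "label_path", "truth_path", "contour_path"):
                p1, p2 = getattr(b1[ds], attr), getattr(b2[ds], attr)
                assert open(p1, "rb").read() == open(p2, "rb").read(), attr

    def test_labels_match_contour_supports(self, small_bundle):
        from pilotcalls.audio_io import read_label_track
        _, bundles = small_bundle
        hop = 0.043 * 0.2
        for b in bundles.values():
            events = read_label_track(b.label_path)
            by_id = {c.call_id: c for c in b.contours}
            assert len(events) == len(b.contours)
            for ev in events:
                c = by_id[ev.label]
                assert ev.start_s == pytest.approx(c.times_s[0], abs=hop)
                assert ev.end_s == pytest.approx(c.times_s[-1], abs=hop)

    def test_inter_call_gap_respected(self, small_bundle):
        spec, bundles = small_bundle
        for b in bundles.values():
            starts = np.array([c.times_s[0] for c in b.contours])
            ends = np.array([c.times_s[-1] for c in b.contours])
            order = np.argsort(starts)
            gaps = starts[order][1:] - ends[order][:-1]
            assert np.all(gaps >= spec.inter_call_gap_s - 1e-9)


class TestSpecValidation:
    def test_gap_too_long_rejected(self):
        with pytest.raises(ValueError, match="0.5"):
            ContourPrototype("g", [Piece("constant", 0.3, 1000, 1000),
                                   Piece("segment-gap", 0.6),
                                   Piece("constant", 0.3, 1000, 1000)])

    def test_small_inter_call_gap_rejected(self):
        with pytest.raises(ValueError, match="inter_call_gap"):
            SynthSpec(prototypes=sc.default_prototypes()[:1], inter_call_gap_s=0.3)

    def test_default_prototypes_span_documented_ranges(self):
        truths = [sc.render_contour(p)[1] for p in sc.default_prototypes()]
        assert {t.n_segments for t in truths} >= {1, 2, 4}
        assert {t.n_elements for t in truths} >= {1, 2, 3, 4}
        assert max(t.n_inflections for t in truths) == 9
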