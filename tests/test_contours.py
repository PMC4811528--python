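"""Contour I/O, spectrogram peak tracking, trigger emulation, dedup."""

import itertools

import numpy as np
import pytest
from scipy.signal import chirp

from conftest import make_trace
from mousesong.contours import (
    ContourTrace,
    RecordingEvent,
    SpectroConfig,
    TriggerConfig,
    dedup_events,
    emulate_trigger,
    extract_contour,
    read_contour_table,
    write_contour_table,
)
from mousesong.errors import FormatError, ValidationError


class TestContourCSV:
    def test_identity_parse(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text(
            "event_id,channel,time_ms,freq_khz,amp_db\n"
            "e1,0,0.0,70.0,-40.0\ne1,0,0.1,70.5,-41.0\ne1,0,0.2,71.0,-39.0\n"
        )
        events = read_contour_table(p)
        assert len(events) == 1
        (trace,) = events[0].traces
        assert len(trace) == 3
        np.testing.assert_allclose(trace.f, [70.0, 70.5, 71.0])

    def test_shuffled_times_raise_naming_event(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "event_id,channel,time_ms,freq_khz,amp_db\n"
            "e7,0,0.2,70.0,-40.0\ne7,0,0.0,70.0,-40.0\n"
        )
        with pytest.raises(ValidationError, match="e7"):
            read_contour_table(p)

    def test_missing_column_is_format_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("event_id,channel,time_ms\ne1,0,0.0\n")
        with pytest.raises(FormatError, match="freq_khz"):
            read_contour_table(p)

    def test_round_trip_to_6_decimals(self, tmp_path, rng):
        t = np.cumsum(rng.uniform(0.05, 0.1, size=40))
        trace = make_trace(t, 60 + rng.normal(0, 2, 40),
                           -40 + rng.normal(0, 1, 40), event_id="ev")
        ev = RecordingEvent(start=t[0], end=t[-1] + 1, traces=[trace])
        path = write_contour_table([ev], tmp_path / "rt.csv")
        (back,) = read_contour_table(path)
        np.testing.assert_allclose(back.traces[0].t, trace.t, atol=1e-6)
        np.testing.assert_allclose(back.traces[0].f, trace.f, atol=1e-6)
        np.testing.assert_allclose(back.traces[0].a, trace.a, atol=1e-6)

    def test_empty_event_list_writes_header_only(self, tmp_path):
        path = write_contour_table([], tmp_path / "empty.csv")
        assert path.read_text().strip() == "event_id,channel,time_ms,freq_khz,amp_db"


class TestExtractContour:
    cfg = SpectroConfig()

    def test_config_derived_quantities(self):
        # 85% overlap of a 256-sample window; padding reaches <= 0.49 kHz bins
        assert self.cfg.hop == 38
        assert self.cfg.nfft == 1024
        assert self.cfg.bin_width_khz <= self.cfg.target_resolution_khz

    def test_pure_tone_within_one_bin(self):
        fs = self.cfg.sample_rate
        t = np.arange(int(0.05 * fs)) / fs
        trace = extract_contour(np.sin(2 * np.pi * 70e3 * t), self.cfg)
        assert len(trace) > 100
        assert np.abs(trace.f - 70.0).max() <= self.cfg.bin_width_khz

    def test_chirp_slope_within_10pct(self):
        fs = self.cfg.sample_rate
        t = np.arange(int(0.02 * fs)) / fs
        w = chirp(t, f0=60e3, f1=80e3, t1=0.02)  # 1 kHz/ms
        trace = extract_contour(w, self.cfg)
        slope = np.polyfit(trace.t, trace.f, 1)[0]
        assert abs(slope - 1.0) < 0.1

    def test_silence_yields_empty_trace(self):
        trace = extract_contour(np.zeros(8192), self.cfg)
        assert len(trace) == 0

    def test_too_short_waveform_raises(self):
        with pytest.raises(ValidationError):
            extract_contour(np.zeros(100), self.cfg)


def _whistle_frames(t0, dur, step=0.076, f=70.0):
    n = int(dur / step) + 1
    t = t0 + np.arange(n) * step
    return t, np.full(n, f)


def _stream(*whistles):
    ts, fs = [], []
    for t0, dur in whistles:
        t, f = _whistle_frames(t0, dur)
        ts.append(t)
        fs.append(f)
    t = np.concatenate(ts)
    return make_trace(t, np.concatenate(fs))


class TestTrigger:
    def test_short_whistle_opens_no_event(self):
        assert emulate_trigger(_stream((500, 5))) == []

    def test_pre_trigger_sets_event_start(self):
        (ev,) = emulate_trigger(_stream((500, 12)))
        assert ev.start == pytest.approx(300.0)

    def test_whistles_within_hold_share_one_event(self):
        events = emulate_trigger(_stream((500, 20), (1320, 20)))
        assert len(events) == 1

    def test_whistles_beyond_hold_split(self):
        events = emulate_trigger(_stream((500, 20), (2000, 20)))
        assert len(events) == 2

    def test_events_never_overlap_and_cover_all_whistles(self, rng):
        whistles = []
        t = 100.0
        for _ in range(30):
            dur = rng.uniform(5, 40)
            whistles.append((t, dur))
            t += dur + rng.uniform(50, 3000)
        events = emulate_trigger(_stream(*whistles))
        for a, b in zip(events, events[1:]):
            assert a.end <= b.start
        for t0, dur in whistles:
            if dur < TriggerConfig().min_dur:
                continue
            hits = [e for e in events if e.start <= t0 < e.end]
            assert len(hits) == 1


def _event(start, end, channel=1):
    t = np.linspace(start, end, 5)
    tr = make_trace(t, channel_id=channel)
    return RecordingEvent(start=start, end=end, traces=[tr], channel_id=channel)


class TestDedup:
    def test_longer_of_overlapping_pair_survives(self):
        a = _event(0, 120, channel=1)
        b = _event(50, 140, channel=2)  # 90 ms, overlaps
        kept = dedup_events([a], [b])
        assert kept == [a]

    def test_disjoint_events_both_kept(self):
        kept = dedup_events([_event(0, 100, 1)], [_event(500, 600, 2)])
        assert len(kept) == 2

    def test_equal_length_tie_keeps_lower_channel(self):
        a = _event(0, 100, channel=1)
        b = _event(0, 100, channel=2)
        kept = dedup_events([a], [b])
        assert [e.channel_id for e in kept] == [1]

    def test_deterministic_under_input_permutation(self):
        ch1 = [_event(0, 100, 1), _event(300, 420, 1)]
        ch2 = [_event(50, 150, 2), _event(310, 400, 2)]
        ref = [(e.start, e.end, e.channel_id)
               for e in dedup_events(ch1, ch2)]
        for p1 in itertools.permutations(ch1):
            for p2 in itertools.permutations(ch2):
                got = [(e.start, e.end, e.channel_id)
                       for e in dedup_events(list(p1), list(p2))]
                assert got == ref

    def test_idempotent(self):
        ch1 = [_event(0, 100, 1), _event(300, 420, 1)]
        ch2 = [_event(50, 150, 2), _event(600, 700, 2)]
        once = dedup_events(ch1, ch2)
        again = dedup_events([e for e in once if e.channel_id == 1],
                             [e for e in once if e.channel_id == 2])
        assert [(e.start, e.channel_id) for e in again] == \
               [(e.start, e.channel_id) for e in once]
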