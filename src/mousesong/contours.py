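"""Peak-frequency contours: extraction, recorder-trigger emulation, I/O.

A contour is the time course of the loudest spectrogram pixel per STFT
column — the representation the recording workflow exports to CSV and the
segmenter consumes.  The recorder itself is a whistle-triggered device: it
opens a recording event when a sound of sufficient duration appears inside
the ultrasonic band and holds the event open for a fixed time after the
last detected whistle.  Because two microphones hang over each arena
compartment, loud calls near the separation wall are captured twice;
``dedup_events`` keeps the longer of two simultaneous captures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import ShortTimeFFT
from scipy.signal.windows import hann

from mousesong.errors import FormatError, ValidationError

CONTOUR_COLUMNS = ["event_id", "channel", "time_ms", "freq_khz", "amp_db"]


@dataclass
class ContourTrace:
    """Time-ordered (time ms, frequency kHz, amplitude dB) frames.

    Frame spacing is set by the STFT hop and is approximately constant
    within a trace; gaps appear where the signal fell below the noise
    floor or the recorder was idle.
    """

    t: np.ndarray
    f: np.ndarray
    a: np.ndarray
    channel_id: int = 0
    event_id: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if not (self.t.shape == self.f.shape == self.a.shape):
            raise ValidationError("t, f, a must have identical shapes")

    def validate(self) -> "ContourTrace":
        if len(self.t) and np.any(np.diff(self.t) <= 0):
            raise ValidationError(
                f"non-monotone time within trace of event {self.event_id!r}"
            )
        if np.any(self.f <= 0):
            raise ValidationError(
                f"non-positive frequency in event {self.event_id!r}"
            )
        return self

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Span from first to last frame, ms."""
        return float(self.t[-1] - self.t[0]) if len(self.t) else 0.0

    def slice(self, idx: slice | np.ndarray) -> "ContourTrace":
        return ContourTrace(self.t[idx], self.f[idx], self.a[idx],
                            self.channel_id, self.event_id)


@dataclass(frozen=True)
class SpectroConfig:
    """Spectrogram settings of the recording workflow.

    256-point FFT with a Hann window at 85% overlap on a 500 kHz stream;
    the spectrum is zero-padded until the bin width drops to at most
    ``target_resolution_khz`` (0.49 kHz, reached at nfft = 1024).
    """

    sample_rate: float = 500_000.0
    fft_len: int = 256
    window: str = "hann"
    overlap: float = 0.85
    target_resolution_khz: float = 0.49

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap < 1.0:
            raise ValidationError("overlap must lie in [0, 1)")
        if self.target_resolution_khz > self.sample_rate / self.fft_len / 1000.0:
            raise ValidationError(
                "target resolution coarser than the unpadded bin width"
            )

    @property
    def hop(self) -> int:
        """STFT frame advance in samples."""
        return int(round((1.0 - self.overlap) * self.fft_len))

    @property
    def frame_step_ms(self) -> float:
        return self.hop / self.sample_rate * 1000.0

    @property
    def nfft(self) -> int:
        """Smallest power of two whose bin width is <= the target resolution."""
        n = self.fft_len
        while self.sample_rate / n / 1000.0 > self.target_resolution_khz:
            n *= 2
        return n

    @property
    def bin_width_khz(self) -> float:
        return self.sample_rate / self.nfft / 1000.0


@dataclass(frozen=True)
class TriggerConfig:
    """Whistle-trigger rules of the recorder.

    A recording event is opened by an in-band sound of at least ``min_dur``
    ms, starts ``pre_trigger`` ms before it, and stays open until
    ``post_hold`` ms after the last detected whistle.  ``run_gap`` is the
    largest silent gap inside one whistle (the device's own hold time is
    unpublished; the syllable gap is the natural choice).
    """

    band_lo: float = 20.0
    band_hi: float = 250.0
    min_dur: float = 10.0
    pre_trigger: float = 200.0
    post_hold: float = 1000.0
    run_gap: float = 10.0

    def __post_init__(self) -> None:
        if self.band_lo >= self.band_hi:
            raise ValidationError("band_lo must be below band_hi")
        for name in ("min_dur", "pre_trigger", "post_hold", "run_gap"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


@dataclass
class RecordingEvent:
    """One triggered recording: a time window plus the contours inside it."""

    start: float
    end: float
    traces: list[ContourTrace] = field(default_factory=list)
    channel_id: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError("event start must precede end")

    @property
    def duration(self) -> float:
        return self.end - self.start


# ---------------------------------------------------------------------------
# CSV dialect


def read_contour_table(path: str | Path) -> list[RecordingEvent]:
    """Read a contour CSV (``event_id,channel,time_ms,freq_khz,amp_db``).

    Rows are grouped into one :class:`RecordingEvent` per (event_id,
    channel) and time-sorted order is enforced, not repaired: shuffled
    times indicate a corrupt export and raise :class:`ValidationError`.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in CONTOUR_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    events: list[RecordingEvent] = []
    for (eid, ch), grp in df.groupby(["event_id", "channel"], sort=True):
        trace = ContourTrace(
            grp["time_ms"].to_numpy(float),
            grp["freq_khz"].to_numpy(float),
            grp["amp_db"].to_numpy(float),
            channel_id=int(ch),
            event_id=str(eid),
        ).validate()
        events.append(
            RecordingEvent(start=trace.t[0], end=trace.t[-1] + 1e-9,
                           traces=[trace], channel_id=int(ch))
        )
    return events


def write_contour_table(events: list[RecordingEvent], path: str | Path) -> Path:
    """Write events back to the contour CSV dialect (round-trips with read)."""
    path = Path(path)
    rows = []
    for ev in events:
        for tr in ev.traces:
            rows.append(pd.DataFrame({
                "event_id": tr.event_id,
                "channel": tr.channel_id,
                "time_ms": tr.t,
                "freq_khz": tr.f,
                "amp_db": tr.a,
            }))
    if rows:
        out = pd.concat(rows, ignore_index=True)
    else:
        out = pd.DataFrame(columns=CONTOUR_COLUMNS)
    out.to_csv(path, index=False, float_format="%.6f")
    return path


# ---------------------------------------------------------------------------
# Extraction


def extract_contour(
    waveform: np.ndarray,
    cfg: SpectroConfig = SpectroConfig(),
    band_lo_khz: float = 20.0,
    band_hi_khz: float = 250.0,
    noise_floor_db: float = 20.0,
    median_filter: bool = False,
    channel_id: int = 0,
    event_id: str = "",
) -> ContourTrace:
    """Track the loudest in-band spectrogram pixel per STFT column.

    A column contributes a frame only when its in-band peak rises at least
    ``noise_floor_db`` above the median in-band level of that column —
    silent stretches produce no frames rather than noise contours.  The
    optional 3-frame median filter stands in for the manual correction pass
    of an interactive workflow; it is off by default.
    """
    waveform = np.asarray(waveform, dtype=float)
    if waveform.size < cfg.fft_len:
        raise ValidationError("waveform shorter than one FFT window")
    stft = ShortTimeFFT(
        hann(cfg.fft_len, sym=False), hop=cfg.hop, fs=cfg.sample_rate,
        mfft=cfg.nfft, scale_to="magnitude",
    )
    S = np.abs(stft.stft(waveform))
    freqs_khz = stft.f / 1000.0
    times_ms = stft.t(waveform.size) * 1000.0
    band = (freqs_khz >= band_lo_khz) & (freqs_khz <= band_hi_khz)
    Sb = S[band]
    fb = freqs_khz[band]
    with np.errstate(divide="ignore"):
        Sb_db = 20.0 * np.log10(Sb)
    peak_idx = np.argmax(Sb_db, axis=0)
    cols = np.arange(Sb.shape[1])
    peak_db = Sb_db[peak_idx, cols]
    med_db = np.median(Sb_db, axis=0)
    keep = np.isfinite(peak_db) & (peak_db >= med_db + noise_floor_db)
    # edge columns see zero-padded signal; their windows extend outside the data
    inside = (times_ms >= 0) & (times_ms <= waveform.size / cfg.sample_rate * 1000.0)
    keep &= inside
    f = fb[peak_idx[keep]]
    t = times_ms[keep]
    a = peak_db[keep]
    if median_filter and f.size >= 3:
        from scipy.ndimage import median_filter as _medf
        f = _medf(f, size=3, mode="nearest")
    return ContourTrace(t, f, a, channel_id=channel_id, event_id=event_id)


# ---------------------------------------------------------------------------
# Trigger emulation


def _whistle_runs(trace: ContourTrace, cfg: TriggerConfig,
                  frame_step: float) -> list[tuple[float, float]]:
    """Maximal in-band frame runs; (start, end) with end one frame step past
    the last frame so a single frame still has positive duration."""
    in_band = (trace.f >= cfg.band_lo) & (trace.f <= cfg.band_hi)
    t = trace.t[in_band]
    runs = []
    if t.size == 0:
        return runs
    start = t[0]
    prev = t[0]
    for ti in t[1:]:
        if ti - prev > cfg.run_gap:
            runs.append((start, prev + frame_step))
            start = ti
        prev = ti
    runs.append((start, prev + frame_step))
    return runs


def emulate_trigger(
    trace: ContourTrace,
    cfg: TriggerConfig = TriggerConfig(),
    frame_step_ms: float | None = None,
) -> list[RecordingEvent]:
    """Split a long frame stream into the events the recorder would save.

    Whistles shorter than ``min_dur`` never open an event.  Each event
    begins ``pre_trigger`` ms before its first qualifying whistle (clipped
    at 0) and ends ``post_hold`` ms after its last; whistles falling inside
    an open event extend it, so calls closer than ``post_hold`` share one
    event.  Events never overlap by construction.
    """
    trace.validate()
    if len(trace) == 0:
        return []
    if frame_step_ms is None:
        steps = np.diff(trace.t)
        frame_step_ms = float(np.median(steps[steps <= cfg.run_gap])) \
            if np.any(steps <= cfg.run_gap) else SpectroConfig().frame_step_ms
    runs = _whistle_runs(trace, cfg, frame_step_ms)
    qual = [(s, e) for s, e in runs if e - s >= cfg.min_dur]
    events: list[RecordingEvent] = []
    cur: list[float] | None = None
    for s, e in qual:
        if cur is not None and s <= cur[1]:
            cur[1] = max(cur[1], e + cfg.post_hold)
        else:
            if cur is not None:
                events.append(_window_event(trace, cur[0], cur[1]))
            cur = [max(0.0, s - cfg.pre_trigger), e + cfg.post_hold]
    if cur is not None:
        events.append(_window_event(trace, cur[0], cur[1]))
    return events


def _window_event(trace: ContourTrace, start: float, end: float) -> RecordingEvent:
    mask = (trace.t >= start) & (trace.t < end)
    sub = trace.slice(mask)
    sub.event_id = f"{trace.event_id}:{start:.0f}" if trace.event_id else f"{start:.0f}"
    return RecordingEvent(start=start, end=end, traces=[sub],
                          channel_id=trace.channel_id)


# ---------------------------------------------------------------------------
# Cross-channel deduplication


def _overlaps(a: RecordingEvent, b: RecordingEvent) -> bool:
    return min(a.end, b.end) - max(a.start, b.start) > 0


def dedup_events(
    events_ch1: list[RecordingEvent],
    events_ch2: list[RecordingEvent],
) -> list[RecordingEvent]:
    """Resolve double captures between the two microphones of one side.

    For every temporally overlapping cross-channel pair only the longer
    event survives; on an exact duration tie the lower channel id wins so
    the outcome is independent of input order.  Idempotent.
    """
    drop1 = set()
    drop2 = set()
    for i, a in enumerate(events_ch1):
        for j, b in enumerate(events_ch2):
            if not _overlaps(a, b):
                continue
            if a.duration > b.duration:
                drop2.add(j)
            elif a.duration < b.duration:
                drop1.add(i)
            elif a.channel_id <= b.channel_id:
                drop2.add(j)
            else:
                drop1.add(i)
    kept = [e for i, e in enumerate(events_ch1) if i not in drop1]
    kept += [e for j, e in enumerate(events_ch2) if j not in drop2]
    kept.sort(key=lambda e: (e.start, e.channel_id))
    return kept
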