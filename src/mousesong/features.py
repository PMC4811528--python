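"""Per-syllable and per-song spectro-temporal parameters.

The syllable parameter set is the one used throughout the analysis:
duration (sylDur, ms), start frequency (staFreq, the first contour frame),
minimum frequency (minFreq), frequency bandwidth (freqBand = max - min),
frequency center of gravity (freqCOG, amplitude-weighted mean frequency),
overall slope (kHz/ms, least-squares fit of frequency on time), and counts
of the two kinds of frequency modulation: sudden jumps between consecutive
frames and turning points (reversals of the contour's slope).  At song
level: song duration (soDur), number of syllables, and the syllable rate,
which is undefined for one-syllable songs and excluded from rate analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mousesong.contours import ContourTrace
from mousesong.errors import DegenerateSyllableError, ValidationError
from mousesong.segmentation import Song, Syllable

UP = "up"
DOWN = "down"
UP_DOWN = "up-down"
DOWN_UP = "down-up"


@dataclass(frozen=True)
class FeatureConfig:
    """Thresholds of the modulation detectors.

    jump_threshold_khz
        Smallest frame-to-frame frequency step counted as a jump.  "Sudden"
        is not quantified anywhere; 10 kHz sits far above frame jitter and
        far below the rendered jump magnitudes.
    smooth_window
        Moving-average length (frames) applied before turn detection so
        that frame jitter does not read as slope reversals.
    min_slope_khz_ms, min_seg_dur_ms
        A slope reversal only counts as a turning point when both flanking
        monotone stretches are at least this steep and this long.
    slope_mode
        'lsq' fits frequency on time by least squares (robust to jitter);
        'endpoint' uses (last - first) / duration.
    """

    jump_threshold_khz: float = 10.0
    smooth_window: int = 5
    min_slope_khz_ms: float = 0.1
    min_seg_dur_ms: float = 1.0
    slope_mode: str = "lsq"

    def __post_init__(self) -> None:
        if self.jump_threshold_khz <= 0:
            raise ValidationError("jump threshold must be positive")
        if self.slope_mode not in ("lsq", "endpoint"):
            raise ValidationError("slope_mode must be 'lsq' or 'endpoint'")


@dataclass
class SyllableFeatures:
    sylDur: float
    staFreq: float
    minFreq: float
    freqBand: float
    freqCOG: float
    slope: float
    jump_list: list[tuple[float, str]] = field(default_factory=list)
    turn_list: list[tuple[float, str]] = field(default_factory=list)

    @property
    def jumps(self) -> int:
        return len(self.jump_list)

    @property
    def turns(self) -> int:
        return len(self.turn_list)

    def as_dict(self) -> dict:
        return {
            "sylDur": self.sylDur, "staFreq": self.staFreq,
            "minFreq": self.minFreq, "freqBand": self.freqBand,
            "freqCOG": self.freqCOG, "slope": self.slope,
            "jumps": self.jumps, "turns": self.turns,
        }


@dataclass
class SongFeatures:
    soDur: float
    n_syls: int
    sylRate: float | None

    def as_dict(self) -> dict:
        return {"soDur": self.soDur, "n_syls": self.n_syls,
                "sylRate": self.sylRate}


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or x.size < 3:
        return x
    w = min(window, x.size)
    kernel = np.ones(w)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def detect_jumps(
    trace: ContourTrace,
    jump_threshold: float = 10.0,
    cfg: FeatureConfig | None = None,
) -> list[tuple[float, str]]:
    """Sudden frequency discontinuities between consecutive frames.

    Returns (position, direction) per jump, position being the midpoint of
    the two frames as a fraction of syllable duration and direction the
    sign of the step.
    """
    if cfg is not None:
        jump_threshold = cfg.jump_threshold_khz
    if len(trace) < 2:
        raise DegenerateSyllableError("jump detection needs >= 2 frames")
    df = np.diff(trace.f)
    dur = trace.t[-1] - trace.t[0]
    idx = np.flatnonzero(np.abs(df) >= jump_threshold)
    out = []
    for i in idx:
        mid = 0.5 * (trace.t[i] + trace.t[i + 1])
        pos = (mid - trace.t[0]) / dur if dur > 0 else 0.0
        out.append((float(pos), UP if df[i] > 0 else DOWN))
    return out


def _monotone_runs(t: np.ndarray, f: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs of constant slope sign, as (start_idx, end_idx, sign).

    Zero-slope intervals extend the current run without changing its sign.
    """
    signs = np.sign(np.diff(f))
    runs: list[list[int]] = []  # [start, end, sign]
    for i, s in enumerate(signs):
        if not runs:
            runs.append([i, i + 1, int(s)])
        elif s == 0 or runs[-1][2] == 0 or s == runs[-1][2]:
            runs[-1][1] = i + 1
            if runs[-1][2] == 0:
                runs[-1][2] = int(s)
        else:
            runs.append([i, i + 1, int(s)])
    return [tuple(r) for r in runs]


def detect_turns(
    trace: ContourTrace,
    cfg: FeatureConfig = FeatureConfig(),
    jump_list: list[tuple[float, str]] | None = None,
) -> list[tuple[float, str]]:
    """Turning points: reversals of the contour's slope.

    The contour is smoothed, split at jump positions (a jump is not a
    turn), and a turning point is recorded at each slope sign change whose
    flanking monotone stretches both last >= ``min_seg_dur_ms`` with
    overall |slope| >= ``min_slope_khz_ms``.  Returns (position, pattern)
    with pattern 'up-down' or 'down-up'.
    """
    if len(trace) < 3:
        return []
    if jump_list is None:
        jump_list = detect_jumps(trace, cfg=cfg)
    dur = trace.t[-1] - trace.t[0]
    onset = trace.t[0]
    # segment boundaries at the jump discontinuities
    df = np.diff(trace.f)
    jump_idx = np.flatnonzero(np.abs(df) >= cfg.jump_threshold_khz) + 1
    turns: list[tuple[float, str]] = []
    for seg in np.split(np.arange(len(trace)), jump_idx):
        if seg.size < 3:
            continue
        t = trace.t[seg]
        f = _moving_average(trace.f[seg], cfg.smooth_window)
        runs = _monotone_runs(t, f)
        sig = []
        for s, e, sign in runs:
            if sign == 0:
                continue
            length = t[e] - t[s]
            slope = (f[e] - f[s]) / length if length > 0 else 0.0
            if length >= cfg.min_seg_dur_ms and abs(slope) >= cfg.min_slope_khz_ms:
                sig.append((s, e, sign))
        for (s1, e1, g1), (s2, e2, g2) in zip(sig, sig[1:]):
            if g1 != g2:
                boundary = 0.5 * (t[e1] + t[s2])
                pos = (boundary - onset) / dur if dur > 0 else 0.0
                turns.append((float(pos), UP_DOWN if g1 > 0 else DOWN_UP))
    return turns


def compute_syllable_features(
    syl: Syllable, cfg: FeatureConfig = FeatureConfig()
) -> SyllableFeatures:
    """All syllable parameters from one segmented syllable.

    freqCOG is the amplitude-weighted mean frequency (linear-amplitude
    weights, i.e. 10^(dB/20)); when amplitudes are missing it falls back to
    the plain mean.  Raises for single-frame syllables, which carry no
    usable spectral shape.
    """
    tr = syl.trace
    if len(tr) < 2:
        raise DegenerateSyllableError(
            f"syllable at {syl.onset:.1f} ms has fewer than 2 frames"
        )
    t, f, a = tr.t, tr.f, tr.a
    dur = float(t[-1] - t[0])
    if np.all(np.isfinite(a)):
        w = np.power(10.0, a / 20.0)
        cog = float(np.sum(w * f) / np.sum(w))
    else:
        cog = float(np.mean(f))
    if cfg.slope_mode == "endpoint":
        slope = float((f[-1] - f[0]) / dur)
    else:
        slope = float(np.polyfit(t, f, 1)[0])
    jump_list = detect_jumps(tr, cfg=cfg)
    turn_list = detect_turns(tr, cfg=cfg, jump_list=jump_list)
    return SyllableFeatures(
        sylDur=dur,
        staFreq=float(f[0]),
        minFreq=float(f.min()),
        freqBand=float(f.max() - f.min()),
        freqCOG=cog,
        slope=slope,
        jump_list=jump_list,
        turn_list=turn_list,
    )


def compute_song_features(song: Song) -> SongFeatures:
    """Song duration, syllable count and rate.

    soDur runs from the first syllable onset to the last syllable offset.
    The syllable rate n/(soDur in s) is only defined for songs of at least
    two syllables; rate analyses drop one-syllable songs.
    """
    so_dur = song.offset - song.onset
    n = song.n_syllables
    rate = n / (so_dur / 1000.0) if n >= 2 and so_dur > 0 else None
    return SongFeatures(soDur=float(so_dur), n_syls=n, sylRate=rate)


def song_feature_frame(songs: list[Song], cfg: FeatureConfig = FeatureConfig()):
    """Long-format table: one row per syllable with song ids attached."""
    import pandas as pd

    rows = []
    for si, song in enumerate(songs):
        for syl in song.syllables:
            feats = compute_syllable_features(syl, cfg)
            row = {"song": si, "onset": syl.onset, "offset": syl.offset}
            row.update(feats.as_dict())
            rows.append(row)
    return pd.DataFrame(rows)
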