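"""Temporal segmentation of contours into syllables and songs.

Mouse USV is organized hierarchically: continuous stretches of sound are
syllables, and bouts of syllables form songs.  Following the convention of
Holy & Guo with gap lengths adjusted for this recording setup, frames
separated by more than 10 ms belong to different syllables, and syllables
separated by more than 500 ms belong to different songs.  Both comparisons
are strict (a gap of exactly the threshold does not split), measured from
the offset of the earlier unit to the onset of the later one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mousesong.contours import ContourTrace
from mousesong.errors import ValidationError

SYLLABLE_GAP_MS = 10.0
SONG_GAP_MS = 500.0


@dataclass
class Syllable:
    """A continuous vocal unit: a slice of a contour with no internal gap
    exceeding the syllable gap."""

    trace: ContourTrace
    onset: float
    offset: float

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValidationError("syllable offset must exceed onset")

    @property
    def n_frames(self) -> int:
        return len(self.trace)


@dataclass
class Song:
    """An ordered bout of syllables whose inter-syllable gaps stay within
    the song gap."""

    syllables: list[Syllable] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.syllables:
            raise ValidationError("a song holds at least one syllable")

    @property
    def onset(self) -> float:
        return self.syllables[0].onset

    @property
    def offset(self) -> float:
        return self.syllables[-1].offset

    @property
    def n_syllables(self) -> int:
        return len(self.syllables)


def split_syllables(
    trace: ContourTrace, syllable_gap: float = SYLLABLE_GAP_MS
) -> list[Syllable]:
    """Partition a contour at inter-frame gaps strictly greater than
    ``syllable_gap`` ms.  Frames are conserved; an empty trace yields an
    empty list.  Onset/offset are the first/last frame times of the slice.
    """
    trace.validate()
    n = len(trace)
    if n == 0:
        return []
    gaps = np.diff(trace.t)
    breaks = np.flatnonzero(gaps > syllable_gap) + 1
    out: list[Syllable] = []
    for chunk in np.split(np.arange(n), breaks):
        sub = trace.slice(chunk)
        onset = float(sub.t[0])
        # a single frame is given one nominal frame of duration
        offset = float(sub.t[-1]) if len(sub) > 1 else onset + 1e-6
        out.append(Syllable(trace=sub, onset=onset, offset=offset))
    return out


def group_songs(
    syllables: list[Syllable], song_gap: float = SONG_GAP_MS
) -> list[Song]:
    """Group time-sorted syllables into songs at offset-to-onset gaps
    strictly greater than ``song_gap`` ms.  Syllables are conserved."""
    if not syllables:
        return []
    for prev, nxt in zip(syllables, syllables[1:]):
        if nxt.onset < prev.onset:
            raise ValidationError("syllables must be time-sorted")
    songs: list[Song] = []
    current = [syllables[0]]
    for syl in syllables[1:]:
        if syl.onset - current[-1].offset > song_gap:
            songs.append(Song(current))
            current = [syl]
        else:
            current.append(syl)
    songs.append(Song(current))
    return songs
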