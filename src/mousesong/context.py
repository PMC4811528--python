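"""Behavioral context: arena regions, encounter types, count tables.

The arena is split into scored regions per compartment: food region (FR),
nest region (NR), contact region (CR) with the contact window (CW) as a
sub-zone, the contact corners (CC) where the two compartments meet, and
the male-bedding spot (MB) present in the final night.  Each song is
annotated with the region its emitter occupied at song onset.  Songs sung
at the contact window are further classified by what the partner was
doing: both at the window is a face-to-face encounter, partner elsewhere
in the contact region is non-face-to-face, partner further away is a
solitary situation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from mousesong.errors import FormatError, UncoveredTimeError, ValidationError

REGION_LABELS = ("FR", "NR", "CR", "CW", "CC", "MB")
#: Region columns of the per-night count table; CW songs roll up into CR.
COUNT_REGIONS = ("FR", "NR", "CC", "CR")
ENCOUNTER_LABELS = ("solitary", "non_face", "face")

OCCUPANCY_COLUMNS = ["animal_id", "start_ms", "end_ms", "region"]


@dataclass
class OccupancyTrack:
    """Where one animal was when: non-overlapping half-open intervals
    [start, end) labeled with regions, emulating manual video scoring."""

    animal_id: str
    intervals: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=lambda iv: iv[0])
        prev_end = None
        for start, end, region in self.intervals:
            if region not in REGION_LABELS:
                raise ValidationError(f"unknown region label {region!r}")
            if end <= start:
                raise ValidationError("interval end must exceed start")
            if prev_end is not None and start < prev_end:
                raise ValidationError(
                    f"overlapping intervals in track {self.animal_id!r}"
                )
            prev_end = end

    def region_at(self, t: float) -> str:
        """Region containing time t under the half-open convention; a
        boundary time belongs to the later interval."""
        for start, end, region in self.intervals:
            if start <= t < end:
                return region
        raise UncoveredTimeError(
            f"track {self.animal_id!r} does not cover t = {t} ms"
        )

    def covers(self, t: float) -> bool:
        return any(s <= t < e for s, e, _ in self.intervals)


@dataclass
class PairNightCounts:
    """Songs per region for one pair in one night — one row of the study's
    count table.

    ``total`` is the night sum; ``mb`` holds male-bedding songs listed
    separately from the region columns.  ``repetition_total`` is the night
    sum of the pair's second experimental trial where one was run.
    Excluded nights (e.g. a pair that opened the contact window early)
    carry a reason and are dropped from summaries.
    """

    pair_id: str
    night: int
    counts: dict[str, int] = field(default_factory=dict)
    mb: int = 0
    excluded: bool = False
    exclusion_reason: str = ""
    repetition_total: int | None = None

    def __post_init__(self) -> None:
        if self.night not in (1, 2, 3, 4):
            raise ValidationError(f"night must be 1-4, got {self.night}")
        for region, n in self.counts.items():
            if region not in COUNT_REGIONS:
                raise ValidationError(f"unknown count region {region!r}")
            if n < 0:
                raise ValidationError("counts must be non-negative")

    @property
    def total(self) -> int:
        """Night sum over the four region columns (male bedding excluded,
        as in the printed table)."""
        return sum(self.counts.values())


def _onset(song) -> float:
    return song.onset if hasattr(song, "onset") else float(song)


def locate_song(song, track: OccupancyTrack) -> str:
    """Region of the emitter at song onset (deterministic even when a song
    straddles a region change)."""
    return track.region_at(_onset(song))


def classify_encounter(song, emitter_track: OccupancyTrack,
                       partner_track: OccupancyTrack) -> str | None:
    """Encounter type for a song sung at the contact window.

    face when the partner is at the window too, non_face when the partner
    is elsewhere in the contact region, solitary otherwise.  Returns None
    when the emitter is not at the window — the classification does not
    apply.
    """
    t = _onset(song)
    if emitter_track.region_at(t) != "CW":
        return None
    partner = partner_track.region_at(t)
    if partner == "CW":
        return "face"
    if partner == "CR":
        return "non_face"
    return "solitary"


def tabulate_pair_night_counts(
    labeled_songs: pd.DataFrame,
    exclusions: dict[tuple[str, int], str] | None = None,
) -> list[PairNightCounts]:
    """Aggregate labeled songs (columns pair, night, region) into per-pair
    per-night region counts.  CW songs count toward CR and MB songs toward
    the male-bedding tally.  ``exclusions`` maps (pair, night) to a reason;
    excluded rows keep their flag but their counts are zeroed so summaries
    cannot pick them up.
    """
    required = {"pair", "night", "region"}
    missing = required - set(labeled_songs.columns)
    if missing:
        raise ValidationError(f"labeled songs missing column(s) {sorted(missing)}")
    bad = labeled_songs[
        labeled_songs["pair"].isna() | labeled_songs["night"].isna()
    ]
    if len(bad):
        raise ValidationError("songs with unknown pair/night present")
    exclusions = exclusions or {}
    out: list[PairNightCounts] = []
    for (pair, night), grp in labeled_songs.groupby(["pair", "night"], sort=True):
        region = grp["region"].replace({"CW": "CR"})
        counts = {r: int((region == r).sum()) for r in COUNT_REGIONS}
        mb = int((region == "MB").sum())
        key = (pair, int(night))
        if key in exclusions:
            out.append(PairNightCounts(pair, int(night), {}, mb=0,
                                       excluded=True,
                                       exclusion_reason=exclusions[key]))
        else:
            out.append(PairNightCounts(pair, int(night), counts, mb=mb))
    return out


def counts_frame(rows: list[PairNightCounts]) -> pd.DataFrame:
    """Long-format count table (`pair,night,region,count,excluded,repetition`)
    — the export consumed by mixed-model software."""
    recs = []
    for r in rows:
        for region in COUNT_REGIONS:
            recs.append({
                "pair": r.pair_id, "night": r.night, "region": region,
                "count": r.counts.get(region, 0), "excluded": r.excluded,
                "repetition": r.repetition_total,
            })
    return pd.DataFrame(recs)


def read_occupancy_table(path: str | Path) -> dict[str, OccupancyTrack]:
    """Read the occupancy CSV (``animal_id,start_ms,end_ms,region``) into
    one track per animal."""
    df = pd.read_csv(path)
    missing = [c for c in OCCUPANCY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    tracks = {}
    for aid, grp in df.groupby("animal_id", sort=True):
        tracks[str(aid)] = OccupancyTrack(
            str(aid),
            [(float(s), float(e), str(r)) for s, e, r in
             zip(grp["start_ms"], grp["end_ms"], grp["region"])],
        )
    return tracks


def write_occupancy_table(tracks: dict[str, OccupancyTrack],
                          path: str | Path) -> Path:
    path = Path(path)
    recs = [
        {"animal_id": tr.animal_id, "start_ms": s, "end_ms": e, "region": r}
        for tr in tracks.values() for s, e, r in tr.intervals
    ]
    pd.DataFrame(recs, columns=OCCUPANCY_COLUMNS).to_csv(path, index=False)
    return path
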