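"""Packaged count table of the arena study.

Twelve female pairs, recorded over three (pairs MS_01..MS_06, which also
received male bedding in night 3) or four nights (MS_07..MS_12, male
bedding in night 4).  Per night and pair the table holds the number of
songs in each context region (FR, NR, CC, CR).  Footnotes carried along:
MS_02 opened the contact window prematurely in night 3 and that night is
excluded; three pairs sang at the male bedding (MS_07: 1, MS_10: 5,
MS_11: 8 songs), listed outside the region columns; five pairs ran a
second three-night trial whose per-night totals are stored as
``repetition_total``.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from mousesong.context import COUNT_REGIONS, PairNightCounts


def load_table1_fixture() -> list[PairNightCounts]:
    """The packaged per-pair per-night song counts with all footnote flags."""
    ref = resources.files("mousesong.data").joinpath("pair_night_counts.csv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path)
    rows: list[PairNightCounts] = []
    for rec in df.itertuples(index=False):
        excluded = bool(rec.excluded)
        counts = {} if excluded else {
            r: int(getattr(rec, r)) for r in COUNT_REGIONS
        }
        rep = None if pd.isna(rec.repetition_total) else int(rec.repetition_total)
        rows.append(PairNightCounts(
            pair_id=str(rec.pair),
            night=int(rec.night),
            counts=counts,
            mb=int(rec.mb),
            excluded=excluded,
            exclusion_reason="" if pd.isna(rec.exclusion_reason)
            else str(rec.exclusion_reason),
            repetition_total=rep,
        ))
    return rows
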