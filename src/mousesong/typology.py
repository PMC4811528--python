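"""Rule-based syllable taxonomy: 14 types, 13 after merging for counts.

High-frequency syllables (mean frequency >= 45 kHz) are discriminated by
the number and orientation of their frequency modulations.  Simple
syllables carry no jumps or turns and split by overall slope into
Simple-Flat (SFL), Simple-Up (SUP) and Simple-Down (SDN).  Turn syllables
carry slope reversals but no jumps: Turn-Up-Down (TUD), Turn-Down-Up (TDU)
and Turn-Multi (TRS, two or more turns).  Jump syllables carry at least one
sudden frequency jump and classify by jump count, direction and position:
Jump-Early-Up/Down (JEU/JED) and Jump-Late-Up/Down (JLU/JLD) for one jump
before/after the syllable midpoint, two-jump syllables by direction pattern
(J2UD/J2DU, merged into the Two-Jump category JMP for count statistics
because each subtype alone is rare), and Jump-Multi (JPS) for three or
more.  Syllables whose frequency center of gravity falls below 45 kHz form
their own Low-Frequency-Syllable type (LFS) regardless of modulation — the
empirical frequency distribution is dichotomous with a split at 45 kHz and
the low mode departs from typical mouse USV shape.

Jumps take priority over turns in mixed syllables, matching the
Jump/Turn/Simple hierarchy.
"""

from __future__ import annotations

from dataclasses import dataclass

from mousesong.errors import ValidationError
from mousesong.features import DOWN, UP, SyllableFeatures

SYLLABLE_LABELS = (
    "SFL", "SUP", "SDN",              # Simple
    "TUD", "TDU", "TRS",              # Turn
    "JEU", "JED", "JLU", "JLD",       # one jump, early/late x up/down
    "J2UD", "J2DU",                   # two jumps, by direction pattern
    "JPS",                            # three or more jumps
    "LFS",                            # low-frequency
)

MERGED_LABELS = (
    "SFL", "SUP", "SDN", "TUD", "TDU", "TRS",
    "JEU", "JED", "JLU", "JLD", "JMP", "JPS", "LFS",
)

_MERGE = {"J2UD": "JMP", "J2DU": "JMP"}


@dataclass(frozen=True)
class TypingConfig:
    """Decision boundaries of the classifier.

    lfs_cutoff_khz
        The low/high-frequency dichotomy sits at 45 kHz.
    early_late_boundary
        A single jump before this fraction of the syllable duration is
        "early", at or after it "late"; 0.5 (the midpoint) by default.
    flat_threshold_khz_ms
        |slope| below this renders a modulation-free syllable Simple-Flat.
    """

    lfs_cutoff_khz: float = 45.0
    early_late_boundary: float = 0.5
    flat_threshold_khz_ms: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.early_late_boundary < 1:
            raise ValidationError("early/late boundary must lie in (0, 1)")


def classify_syllable(
    feat: SyllableFeatures, cfg: TypingConfig = TypingConfig()
) -> str:
    """Assign exactly one of the 14 labels to a feature vector.

    The tree is total: the low-frequency check comes first, then jumps,
    then turns, then the simple slope classes.
    """
    if feat.freqCOG < cfg.lfs_cutoff_khz:
        return "LFS"
    if feat.jumps >= 3:
        return "JPS"
    if feat.jumps == 2:
        first_dir = feat.jump_list[0][1]
        return "J2UD" if first_dir == UP else "J2DU"
    if feat.jumps == 1:
        pos, direction = feat.jump_list[0]
        early = pos < cfg.early_late_boundary
        if direction == UP:
            return "JEU" if early else "JLU"
        return "JED" if early else "JLD"
    if feat.turns >= 2:
        return "TRS"
    if feat.turns == 1:
        return "TUD" if feat.turn_list[0][1] == "up-down" else "TDU"
    if abs(feat.slope) < cfg.flat_threshold_khz_ms:
        return "SFL"
    return "SUP" if feat.slope > 0 else "SDN"


def merge_label(label: str) -> str:
    """Display label after merging the rare two-jump subtypes into JMP."""
    return _MERGE.get(label, label)


def merge_types_for_counts(type_counts: dict[str, int]) -> dict[str, int]:
    """Fold J2UD and J2DU into the Two-Jump category (JMP) for count
    statistics; every other label passes through.  Totals are conserved."""
    out: dict[str, int] = {}
    for label, n in type_counts.items():
        if n < 0:
            raise ValidationError(f"negative count for {label}")
        key = merge_label(label)
        out[key] = out.get(key, 0) + n
    return out
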