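"""Core data containers shared across the pipeline.

A two-color spotted array is represented as a :class:`Hybridization`: a
spot-level table (one row per printed spot, with per-channel foreground and
background pixel summaries) plus the dye orientation of the comparison and a
batch label.  Spot tables are ordinary :class:`pandas.DataFrame` objects with
a fixed column vocabulary (:data:`SPOT_COLUMNS`) so that every stage of the
pipeline can read and write them losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: Chromosome arm vocabulary.  "Other" marks probes not mapped to the
#: assembled reference genome; mapped percentages exclude it.
ARMS = ("X", "2L", "2R", "3L", "3R", "4", "Other")

#: Five-state chromatin "color" vocabulary used as a per-gene label.
CHROMATIN_COLORS = ("YELLOW", "RED", "BLUE", "GREEN", "BLACK")

#: Required columns of a spot-level table.  Grid indices are 1-based
#: (GenePix convention); x/y are slide coordinates in micrometers with an
#: arbitrary origin.  ``frac_fg_gt_bg2sd`` is the fraction of foreground
#: pixels whose intensity exceeds the background median + 2 background SDs.
SPOT_COLUMNS = [
    "probe_id",
    "block",
    "row",
    "col",
    "x",
    "y",
    "fg_median_ch1",
    "fg_pixels_ch1",
    "frac_fg_gt_bg2sd_ch1",
    "bg_median_ch1",
    "bg_sd_ch1",
    "fg_median_ch2",
    "fg_pixels_ch2",
    "frac_fg_gt_bg2sd_ch2",
    "bg_median_ch2",
    "bg_sd_ch2",
]

_NUMERIC_SPOT_COLUMNS = SPOT_COLUMNS[1:]


@dataclass
class SpotRecord:
    """One printed spot with per-channel pixel summary statistics."""

    probe_id: str
    block: int
    row: int
    col: int
    x: float
    y: float
    fg_median_ch1: float
    fg_pixels_ch1: int
    frac_fg_gt_bg2sd_ch1: float
    bg_median_ch1: float
    bg_sd_ch1: float
    fg_median_ch2: float
    fg_pixels_ch2: int
    frac_fg_gt_bg2sd_ch2: float
    bg_median_ch2: float
    bg_sd_ch2: float

    def validate(self) -> None:
        for name in (
            "fg_median_ch1", "bg_median_ch1", "bg_sd_ch1",
            "fg_median_ch2", "bg_median_ch2", "bg_sd_ch2",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"negative intensity in {name}")
        for name in ("fg_pixels_ch1", "fg_pixels_ch2"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative pixel count in {name}")
        for name in ("frac_fg_gt_bg2sd_ch1", "frac_fg_gt_bg2sd_ch2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class Hybridization:
    """One two-color array: spot table + dye orientation + batch label.

    ``orientation`` is +1 when genotype A is labeled in channel 1 and
    genotype B in channel 2, and -1 for the dye swap.
    """

    array_id: str
    batch: str
    orientation: int
    spots: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.orientation not in (+1, -1):
            raise ValueError(f"orientation must be +1 or -1, got {self.orientation}")
        if len(self.spots) < 1:
            raise ValueError("hybridization must contain at least one spot")
        missing = [c for c in SPOT_COLUMNS if c not in self.spots.columns]
        if missing:
            raise ValueError(f"spot table missing columns: {missing}")
        key = self.spots[["block", "row", "col"]]
        if key.duplicated().any():
            raise ValueError("duplicate (block, row, col) grid position")

    @property
    def n_spots(self) -> int:
        return len(self.spots)


def validate_spot_table(spots: pd.DataFrame) -> None:
    """Check ranges of a whole spot table at once (vector form of
    :meth:`SpotRecord.validate`)."""
    for name in _NUMERIC_SPOT_COLUMNS:
        if name.startswith(("fg_median", "bg_median", "bg_sd", "fg_pixels")):
            if (spots[name] < 0).any():
                raise ValueError(f"negative values in {name}")
        if name.startswith("frac_fg_gt_bg2sd"):
            bad = (spots[name] < 0) | (spots[name] > 1)
            if bad.any():
                raise ValueError(f"values outside [0, 1] in {name}")
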