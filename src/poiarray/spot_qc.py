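"""Spot-level quality control for two-color arrays.

Three criteria decide whether a spot is kept:

1. at least 70% of foreground pixels exceed the background median + 2
   background SDs, in at least one channel;
2. the median foreground intensity is at least three times the median
   background intensity, in at least one channel;
3. the spot has more than 30 foreground pixels (strict), evaluated on both
   channels' pixel counts.

The percentage and ratio thresholds are inclusive ("70%" means >= 0.70,
"three times" means >= 3.0); the pixel-count threshold is strict.  A zero
background median with positive foreground passes criterion 2 (the ratio is
infinite).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import Hybridization, SpotRecord, validate_spot_table

FRAC_THRESHOLD = 0.70
FG_BG_RATIO = 3.0
MIN_FG_PIXELS = 30  # strict: pixel count must exceed this


@dataclass
class QcDecision:
    passed: bool
    crit1_ch1: bool
    crit1_ch2: bool
    crit2_ch1: bool
    crit2_ch2: bool
    crit3: bool


def _decisions_frame(spots: pd.DataFrame) -> pd.DataFrame:
    c1a = spots["frac_fg_gt_bg2sd_ch1"] >= FRAC_THRESHOLD
    c1b = spots["frac_fg_gt_bg2sd_ch2"] >= FRAC_THRESHOLD
    c2a = spots["fg_median_ch1"] >= FG_BG_RATIO * spots["bg_median_ch1"]
    c2b = spots["fg_median_ch2"] >= FG_BG_RATIO * spots["bg_median_ch2"]
    # bg == 0, fg == 0 is a dead spot: ratio undefined, criterion not met
    c2a &= ~((spots["bg_median_ch1"] == 0) & (spots["fg_median_ch1"] == 0))
    c2b &= ~((spots["bg_median_ch2"] == 0) & (spots["fg_median_ch2"] == 0))
    c3 = np.minimum(spots["fg_pixels_ch1"], spots["fg_pixels_ch2"]) > MIN_FG_PIXELS
    return pd.DataFrame({
        "crit1_ch1": c1a, "crit1_ch2": c1b,
        "crit2_ch1": c2a, "crit2_ch2": c2b,
        "crit3": c3,
        "passed": (c1a | c1b) & (c2a | c2b) & c3,
    })


def evaluate_spot(spot) -> QcDecision:
    """QC decision for a single spot (a :class:`SpotRecord`, mapping or
    Series with the spot-table fields)."""
    if isinstance(spot, SpotRecord):
        spot.validate()
        row = pd.DataFrame([vars(spot)])
    else:
        row = pd.DataFrame([dict(spot)])
        validate_spot_table(row)
    d = _decisions_frame(row).iloc[0]
    return QcDecision(
        passed=bool(d["passed"]),
        crit1_ch1=bool(d["crit1_ch1"]), crit1_ch2=bool(d["crit1_ch2"]),
        crit2_ch1=bool(d["crit2_ch1"]), crit2_ch2=bool(d["crit2_ch2"]),
        crit3=bool(d["crit3"]),
    )


def evaluate_spots(spots: pd.DataFrame) -> pd.DataFrame:
    """Vectorized QC over a whole spot table; same semantics as
    :func:`evaluate_spot` row by row."""
    validate_spot_table(spots)
    return _decisions_frame(spots)


def filter_hybridization(hyb: Hybridization):
    """Keep only passing spots, preserving order.

    Returns the filtered hybridization and a report dict with per-criterion
    pass counts.  An array in which no spot passes yields an empty spot
    table and a warning entry in the report.
    """
    d = evaluate_spots(hyb.spots)
    kept = hyb.spots.loc[d["passed"].to_numpy()].reset_index(drop=True)
    report = {
        "array_id": hyb.array_id,
        "n_spots": int(len(hyb.spots)),
        "n_passed": int(d["passed"].sum()),
        "n_fail_crit1": int((~(d["crit1_ch1"] | d["crit1_ch2"])).sum()),
        "n_fail_crit2": int((~(d["crit2_ch1"] | d["crit2_ch2"])).sum()),
        "n_fail_crit3": int((~d["crit3"]).sum()),
        "warning": "" if d["passed"].any() else "no spots passed QC",
    }
    if len(kept) == 0:
        # bypass the >=1 spot invariant: an all-failing array is reported,
        # not silently dropped
        filtered = Hybridization.__new__(Hybridization)
        filtered.array_id = hyb.array_id
        filtered.batch = hyb.batch
        filtered.orientation = hyb.orientation
        filtered.spots = kept
        return filtered, report
    return (
        Hybridization(array_id=hyb.array_id, batch=hyb.batch,
                      orientation=hyb.orientation, spots=kept),
        report,
    )
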