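"""Turning window statistics into selected-sweep regions.

A window is called "selected" when it sits simultaneously in the top-q
empirical tails of both windowed Fst and the log2 diversity ratio
(default q = 0.05).  Both tails are computed over the same retained-window
set: windows dropped for too few variants or an undefined ratio are in
neither quantile denominator.  Selected windows that overlap or touch are
merged into maximal regions carrying the maximum of each statistic.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, intersect_intervals


@dataclass
class SweepRegion:
    interval: GenomicInterval
    max_fst: float
    max_log2_ratio: float
    n_windows: int


def top_quantile_threshold(values, q: float = 0.05) -> float:
    """Cutoff such that values >= cutoff form the top-q tail.

    Empirical ``1 - q`` quantile with linear interpolation between order
    statistics (the common statistical-software default); selection is by
    ``>= cutoff`` so ties at the cutoff are kept.
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("top_quantile_threshold needs at least one finite value")
    if not 0.0 < q <= 1.0:
        raise ValueError("q must be in (0, 1]")
    return float(np.quantile(vals, 1.0 - q))


def call_selected_windows(rows: pd.DataFrame, q: float = 0.05) -> list[SweepRegion]:
    """Select windows in the top-q of both Fst and log2 ratio; merge them.

    ``rows`` is a window table from :func:`sweepibd.popgen.sweep_table`.
    Overlapping or book-ended selected windows merge into one region.
    """
    usable = rows[np.isfinite(rows["fst"]) & np.isfinite(rows["log2_ratio"])]
    if usable.empty:
        return []
    cut_fst = top_quantile_threshold(usable["fst"], q)
    cut_ratio = top_quantile_threshold(usable["log2_ratio"], q)
    sel = usable[(usable["fst"] >= cut_fst) & (usable["log2_ratio"] >= cut_ratio)]
    sel = sel.sort_values(["chrom", "start"])

    regions: list[SweepRegion] = []
    cur: dict | None = None
    for row in sel.itertuples(index=False):
        if (
            cur is not None
            and row.chrom == cur["chrom"]
            and row.start <= cur["end"]  # overlap or book-ended
        ):
            cur["end"] = max(cur["end"], row.end)
            cur["max_fst"] = max(cur["max_fst"], row.fst)
            cur["max_log2_ratio"] = max(cur["max_log2_ratio"], row.log2_ratio)
            cur["n"] += 1
        else:
            if cur is not None:
                regions.append(_close_region(cur))
            cur = {
                "chrom": row.chrom,
                "start": row.start,
                "end": row.end,
                "max_fst": row.fst,
                "max_log2_ratio": row.log2_ratio,
                "n": 1,
            }
    if cur is not None:
        regions.append(_close_region(cur))
    return regions


def _close_region(cur: dict) -> SweepRegion:
    return SweepRegion(
        interval=GenomicInterval(
            cur["chrom"], int(cur["start"]), int(cur["end"]), score=cur["max_fst"]
        ),
        max_fst=float(cur["max_fst"]),
        max_log2_ratio=float(cur["max_log2_ratio"]),
        n_windows=cur["n"],
    )


def selected_regions_multi(
    regions_a: Sequence[SweepRegion], regions_b: Sequence[SweepRegion]
) -> list[GenomicInterval]:
    """Base-pair intersection of two contrasts' selected regions."""
    return intersect_intervals(
        [r.interval for r in regions_a], [r.interval for r in regions_b]
    )


def combine_contrasts(
    regions_by_contrast: Sequence[Sequence[SweepRegion]],
) -> list[SweepRegion]:
    """Regions selected in every contrast, with statistics joined by max.

    The interval set is the base-pair intersection across contrasts; each
    resulting interval carries the maximum Fst / log2 ratio of the
    overlapping source regions (window count likewise maxed).
    """
    if not regions_by_contrast:
        return []
    if len(regions_by_contrast) == 1:
        return list(regions_by_contrast[0])
    intervals = [r.interval for r in regions_by_contrast[0]]
    for other in regions_by_contrast[1:]:
        intervals = intersect_intervals(intervals, [r.interval for r in other])
    out: list[SweepRegion] = []
    for iv in intervals:
        sources = [
            r
            for contrast in regions_by_contrast
            for r in contrast
            if r.interval.overlaps(iv)
        ]
        out.append(
            SweepRegion(
                interval=iv.with_score(max(r.max_fst for r in sources)),
                max_fst=max(r.max_fst for r in sources),
                max_log2_ratio=max(r.max_log2_ratio for r in sources),
                n_windows=max(r.n_windows for r in sources),
            )
        )
    return out
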