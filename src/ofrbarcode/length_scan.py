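"""Mini-barcode search: OFR resolution as a function of end trimming.

Alignment columns are removed from one end in coarse blocks (default 50)
until percent resolution first drops below the running maximum; the scan
then rewinds one coarse step and continues in fine steps (default 10) until
the drop is located.  The threshold t is recomputed at every truncation
because the average length a changes.  The reported x-axis is the mean
ungapped length of the truncated records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptySequenceError, ScanError, TooShortError
from .ofr_core import percent_resolution, resolution_matrix
from .seqdata import BarcodeDataset, SequenceRecord, degap


@dataclass(frozen=True)
class ScanPoint:
    cut_columns: int
    average_retained_length: float
    percent_resolution: float
    mean_discriminating_oligos: float


@dataclass
class LengthScanResult:
    end: str  # "5p" | "3p"
    k: int
    points: list[ScanPoint]

    @property
    def max_percent(self) -> float:
        return max(p.percent_resolution for p in self.points)

    @property
    def min_full_length(self) -> float:
        """Shortest average length that retains the maximum resolution.

        When nothing resolves at any length the full length is reported by
        convention.
        """
        best = self.max_percent
        if best == 0.0:
            return self.points[0].average_retained_length
        return min(
            p.average_retained_length
            for p in self.points
            if abs(p.percent_resolution - best) < 1e-9
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "end": self.end,
                    "cut_columns": p.cut_columns,
                    "average_retained_length": p.average_retained_length,
                    "percent_resolution": p.percent_resolution,
                    "mean_discriminating_oligos": p.mean_discriminating_oligos,
                }
                for p in self.points
            ]
        )


def _truncate(ds: BarcodeDataset, cut: int, end: str) -> BarcodeDataset:
    width = ds.alignment_width
    if end == "5p":
        lo, hi = cut, width
    else:
        lo, hi = 0, width - cut
    recs = [
        SequenceRecord(r.species_id, r.accession_id, r.residues[lo:hi])
        for r in ds.records
    ]
    return BarcodeDataset(recs, aligned=True)


def _evaluate(ds: BarcodeDataset, cut: int, end: str, k: int, mode: str) -> ScanPoint:
    sub = degap(_truncate(ds, cut, end))
    rm = resolution_matrix(sub, k)
    pct = percent_resolution(rm, mode=mode)
    n_disc = [
        len(pr.discriminating_oligos)
        for pr in rm.evidence.values()
        if pr.resolved
    ]
    return ScanPoint(
        cut_columns=cut,
        average_retained_length=sub.average_length,
        percent_resolution=pct,
        mean_discriminating_oligos=float(np.mean(n_disc)) if n_disc else 0.0,
    )


def trim_scan(
    ds: BarcodeDataset,
    k: int,
    end: str = "3p",
    coarse: int = 50,
    fine: int = 10,
    mode: str = "species",
) -> LengthScanResult:
    """Scan resolution against progressive end trimming.

    Pure function: the input dataset is never modified.  Stops when the
    remaining window can no longer support the analysis or when, in the fine
    phase, resolution falls below the maximum seen so far.
    """
    if end not in ("5p", "3p"):
        raise ScanError(f"unknown end {end!r}")
    width = ds.alignment_width
    if width <= coarse:
        raise ScanError(
            f"alignment of {width} columns is shorter than one coarse step"
        )

    def try_eval(cut: int) -> ScanPoint | None:
        if width - cut <= k:
            return None
        try:
            return _evaluate(ds, cut, end, k, mode)
        except (EmptySequenceError, TooShortError):
            return None

    points: list[ScanPoint] = []
    running_max = -1.0
    cut = 0
    drop_base: int | None = None
    while True:
        pt = try_eval(cut)
        if pt is None:
            break
        if points and pt.percent_resolution < running_max - 1e-9:
            drop_base = cut - coarse  # rewind one coarse step
            break
        points.append(pt)
        running_max = max(running_max, pt.percent_resolution)
        cut += coarse
    if drop_base is not None:
        cut = drop_base + fine
        while True:
            pt = try_eval(cut)
            if pt is None:
                break
            points.append(pt)
            if pt.percent_resolution < running_max - 1e-9:
                break
            cut += fine
    if not points:
        raise ScanError("scan produced no evaluable truncation")
    return LengthScanResult(end=end, k=k, points=points)


def min_length_full_resolution(res: LengthScanResult) -> float:
    """Shortest average retained length achieving the scan's maximum percent."""
    if not res.points:
        raise ScanError("empty scan")
    return res.min_full_length
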