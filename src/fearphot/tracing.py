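"""Retrograde-tracing topography: medial-lateral positions, anterior-
posterior profiles, and dual-projection overlap ratios of labeled neurons.

Cells arrive as coordinate tables (region, AP position in mm from bregma,
absolute distance from the midline in um, projection label); image
segmentation is upstream of this package.
"""

from __future__ import annotations

import numpy as np

from .core import CELL_LABELS, CellRecord, ValidationError


def ml_distance_stats(
    cells: list[CellRecord], region: str, labels: tuple[str, ...] = CELL_LABELS
) -> dict[str, dict]:
    """Mean +/- SEM distance from the midline per projection label.

    Single-cell groups get SEM 0 with a ``degenerate`` flag. Requesting a
    label with no cells in the region is an error.
    """
    out: dict[str, dict] = {}
    for label in labels:
        ml = np.array([c.ml_um for c in cells if c.region == region and c.label == label])
        if ml.size == 0:
            raise ValidationError(f"no {label} cells in region {region}")
        sem = float(ml.std(ddof=1) / np.sqrt(ml.size)) if ml.size > 1 else 0.0
        out[label] = {
            "mean_ml_um": float(ml.mean()),
            "sem": sem,
            "n": int(ml.size),
            "degenerate": ml.size == 1,
        }
    return out


def ap_profile(
    cells: list[CellRecord],
    region: str,
    bin_mm: float = 0.12,
    ap_range: tuple[float, float] | None = None,
) -> dict:
    """Per-label histogram of cell counts along the AP axis.

    Bins are half-open [lo, lo + bin_mm). ``ap_range`` defaults to the span
    of the region's cells; an empty region yields all-zero histograms over
    the requested range (which must then be given).
    """
    if bin_mm <= 0:
        raise ValidationError("bin_mm must be positive")
    sel = [c for c in cells if c.region == region]
    if ap_range is None:
        if not sel:
            raise ValidationError(f"no cells in region {region} and no ap_range given")
        lo = min(c.ap_mm for c in sel)
        hi = max(c.ap_mm for c in sel)
    else:
        lo, hi = ap_range
    n_bins = max(1, int(np.ceil((hi - lo) / bin_mm)))
    edges = lo + bin_mm * np.arange(n_bins + 1)
    counts = {}
    for label in CELL_LABELS:
        ap = np.array([c.ap_mm for c in sel if c.label == label])
        # half-open bins via searchsorted: a cell on an edge joins the bin above
        idx = np.searchsorted(edges, ap, side="right") - 1 if ap.size else np.array([], int)
        idx = idx[(idx >= 0) & (idx < n_bins)]
        counts[label] = np.bincount(idx, minlength=n_bins).astype(int)
    return {"edges": edges, "counts": counts}


def overlap_ratio(
    cells: list[CellRecord],
    region: str,
    target: str,
    include_both_in_denominator: bool = True,
) -> float:
    """Fraction of target-projecting neurons that are double-labeled.

    Default convention: n(Both) / (n(target single) + n(Both)) — "projecting
    to the target" includes double-labeled cells. With
    ``include_both_in_denominator`` False the denominator is the
    single-labeled count alone.
    """
    if target not in ("vmPFC", "dmPFC"):
        raise ValidationError("target must be vmPFC or dmPFC")
    sel = [c for c in cells if c.region == region]
    n_both = sum(c.label == "Both" for c in sel)
    n_single = sum(c.label == target for c in sel)
    denom = n_single + n_both if include_both_in_denominator else n_single
    if denom == 0:
        raise ValidationError(f"empty denominator for target {target} in {region}")
    return n_both / denom
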