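"""Lysosome-positioning readouts.

The core statistic is the per-cell clustering ratio: lysosomal-channel
intensity summed inside a circle of fixed physical diameter (default
7 µm) centred on the MTOC, divided by the whole-cell lysosomal intensity.
Per-well summaries of this ratio, normalised to the pooled control wells,
give the lysosomal clustering value whose fold change drives hit calling.
Also here: the peripheral-lysosome cell percentage, lysosome intensity
within aggregate masks (colocalization), and the fraction of pixels above
a threshold used as a ROS readout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .config import AnalysisConfig
from .errors import DataError, ValidationError
from .mtoc import MtocCall
from .segmentation import CROSS, LabelMask


@dataclass
class ClusteringMeasurement:
    """Raw in-circle intensity ratio for one cell, with provenance."""

    cell_label: int
    well_id: str
    raw_ratio: float
    circle_area_px: int
    cell_area_px: int
    excluded: bool = False
    reason: str = ""


@dataclass
class ColocScore:
    """Lysosome intensity within a cell's aggregate area."""

    cell_label: int
    aggregate_area_px: int
    lysosome_intensity_in_aggregate: float
    mean_intensity_in_aggregate: float


def circle_mask(
    center: tuple[float, float],
    diameter_um: float,
    pixel_size_um: float,
    shape: tuple[int, int],
) -> np.ndarray:
    """Boolean disk: pixels whose centre lies within diameter/2 of ``center``.

    Distances are physical (pixel offsets times ``pixel_size_um``); the
    disk is clipped at the image bounds.  A centre outside the image
    yields an empty mask with a warning.  For a circle smaller than one
    pixel spacing the nearest in-bounds pixel is always included, so the
    mask is never empty for an in-bounds centre.
    """
    if diameter_um <= 0:
        raise ValidationError("diameter_um must be > 0")
    h, w = shape
    r0, c0 = center
    if not (0 <= r0 <= h - 1 and 0 <= c0 <= w - 1):
        warnings.warn(
            f"circle centre {center} lies outside image of shape {shape}",
            stacklevel=2,
        )
        return np.zeros(shape, dtype=bool)
    radius_px = (diameter_um / 2.0) / pixel_size_um
    rr = np.arange(h)[:, None] - r0
    cc = np.arange(w)[None, :] - c0
    mask = rr * rr + cc * cc <= radius_px * radius_px
    if not mask.any():
        mask[int(round(r0)), int(round(c0))] = True
    return mask


def clustering_ratio(
    lysosome: np.ndarray,
    cell_mask: np.ndarray,
    mtoc: MtocCall,
    config: AnalysisConfig,
    pixel_size_um: float,
    well_id: str = "",
    nucleus_mask: Optional[np.ndarray] = None,
) -> ClusteringMeasurement:
    """In-circle over whole-cell lysosomal intensity for one cell.

    The numerator region is circle ∩ cell (configurable to the raw
    circle), so the ratio lies in [0, 1] and is invariant to positive
    rescaling of the lysosome channel.  Cells with an undetected MTOC or
    zero whole-cell signal come back excluded with a reason.
    """
    lysosome = np.asarray(lysosome, dtype=float)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    cell_area = int(cell_mask.sum())
    if cell_area == 0:
        raise ValidationError("cell mask is empty")
    if not mtoc.detected:
        return ClusteringMeasurement(
            mtoc.cell_label, well_id, float("nan"), 0, cell_area,
            excluded=True, reason="no MTOC detected",
        )
    denom_mask = cell_mask
    if config.exclude_nucleus_from_denominator and nucleus_mask is not None:
        denom_mask = cell_mask & ~np.asarray(nucleus_mask, dtype=bool)
    denominator = float(lysosome[denom_mask].sum())
    if denominator <= 0:
        return ClusteringMeasurement(
            mtoc.cell_label, well_id, float("nan"), 0, cell_area,
            excluded=True, reason="empty lysosome signal",
        )
    circ = circle_mask(
        mtoc.position, config.circle_diameter_um, pixel_size_um, lysosome.shape
    )
    numerator_mask = circ & cell_mask if config.clip_circle_to_cell else circ
    numerator = float(lysosome[numerator_mask].sum())
    return ClusteringMeasurement(
        mtoc.cell_label,
        well_id,
        numerator / denominator,
        int(circ.sum()),
        cell_area,
    )


def normalize_to_control(
    treated: Sequence[float],
    control: Sequence[float],
    statistic: str = "mean",
) -> float:
    """stat(treated) / stat(control): the shared fold-change contract."""
    stat = {"mean": np.mean, "median": np.median}.get(statistic)
    if stat is None:
        raise ValidationError(f"unknown statistic {statistic!r}")
    control = np.asarray(control, dtype=float)
    control = control[~np.isnan(control)]
    if control.size == 0:
        raise DataError("control group is empty")
    denom = float(stat(control))
    if denom <= 0:
        raise DataError("control statistic must be positive")
    treated = np.asarray(treated, dtype=float)
    treated = treated[~np.isnan(treated)]
    if treated.size == 0:
        return float("nan")
    return float(stat(treated)) / denom


def clustering_value(
    treated_ratios: Sequence[float],
    control_ratios: Sequence[float],
    statistic: str = "mean",
) -> float:
    """Lysosomal clustering value of a well: its per-cell ratio summary
    relative to the pooled control-well summary.  Controls normalised
    against themselves give exactly 1."""
    return normalize_to_control(treated_ratios, control_ratios, statistic)


def peripheral_cell_fraction(
    lysosome: np.ndarray,
    cells: LabelMask,
    central: LabelMask,
    intensity_fraction: float = 0.5,
    exclude_labels: Iterable[int] = (),
) -> tuple[float, dict[int, bool]]:
    """Percentage of cells whose lysosomes sit peripherally.

    A cell counts as having peripheral lysosomes when more than
    ``intensity_fraction`` of its lysosomal intensity falls in the
    peripheral region (cell minus central).  Returns the percentage over
    analyzable cells and the per-cell flags.
    """
    if not 0 < intensity_fraction < 1:
        raise ValidationError("intensity_fraction must lie in (0, 1)")
    lysosome = np.asarray(lysosome, dtype=float)
    excluded = set(exclude_labels)
    flags: dict[int, bool] = {}
    for lab in cells.ids:
        if int(lab) in excluded:
            continue
        cell = cells.mask_of(lab)
        total = float(lysosome[cell].sum())
        if total <= 0:
            continue
        peripheral = cell & ~central.mask_of(lab)
        frac = float(lysosome[peripheral].sum()) / total
        flags[int(lab)] = frac > intensity_fraction
    if not flags:
        raise DataError("no cells")
    pct = 100.0 * sum(flags.values()) / len(flags)
    return pct, flags


def aggregate_colocalization(
    lysosome: np.ndarray,
    aggregate: np.ndarray,
    cells: LabelMask,
    min_aggregate_area_px: int = 5,
) -> list[ColocScore]:
    """Lysosome intensity within each cell's aggregate area.

    The aggregate mask is the per-cell Otsu threshold of the aggregate
    channel, keeping connected components of at least
    ``min_aggregate_area_px`` pixels.  Cells without aggregates yield a
    valid zero record.
    """
    lysosome = np.asarray(lysosome, dtype=float)
    aggregate = np.asarray(aggregate, dtype=float)
    if lysosome.shape != aggregate.shape or lysosome.shape != cells.labels.shape:
        raise ValidationError("channels and cell mask must be co-registered")
    scores: list[ColocScore] = []
    for lab in cells.ids:
        cell = cells.mask_of(lab)
        values = aggregate[cell]
        if np.ptp(values) == 0:
            scores.append(ColocScore(int(lab), 0, 0.0, 0.0))
            continue
        thr = threshold_otsu(values)
        agg = cell & (aggregate > thr)
        comp, n_comp = ndi.label(agg, structure=CROSS)
        if n_comp:
            sizes = np.bincount(comp.ravel())
            small = np.flatnonzero(sizes < min_aggregate_area_px)
            agg[np.isin(comp, small[small > 0])] = False
        area = int(agg.sum())
        if area == 0:
            scores.append(ColocScore(int(lab), 0, 0.0, 0.0))
            continue
        total = float(lysosome[agg].sum())
        scores.append(ColocScore(int(lab), area, total, total / area))
    return scores


def fraction_pixels_above_threshold(raster: np.ndarray, threshold: float) -> float:
    """count(pixels > threshold) / total pixels."""
    raster = np.asarray(raster, dtype=float)
    if raster.size == 0:
        raise ValidationError("empty raster")
    if not np.all(np.isfinite(raster)):
        raise ValidationError("raster must be finite")
    return float(np.count_nonzero(raster > threshold)) / raster.size
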