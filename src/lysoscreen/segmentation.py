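"""Nucleus, whole-cell and central/peripheral region delineation.

Nuclei come from a smoothed, Otsu-thresholded nuclear stain; cells from a
nucleus-seeded watershed over a cytoplasmic composite; the central region
of each cell is obtained by iterative morphological erosion until just
before its area drops below the requested fraction of the cell area, and
the peripheral region is the set difference.  All thresholds are
data-driven, making segmentation invariant to positive rescaling of the
input channels.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu, threshold_triangle
from skimage.segmentation import watershed

from .config import AnalysisConfig
from .errors import ValidationError

# 3x3 cross: the structuring element for central-region erosion and for
# connected-component labelling (4-connectivity).
CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class LabelMask:
    """Labelled raster: 0 = background, k > 0 = object k."""

    labels: np.ndarray
    kind: str  # nucleus | cell | central

    def __post_init__(self) -> None:
        if self.labels.ndim != 2:
            raise ValidationError("label mask must be 2-D")
        if np.any(self.labels < 0):
            raise ValidationError("labels must be nonnegative")
        if self.kind not in ("nucleus", "cell", "central"):
            raise ValidationError(f"unknown mask kind {self.kind!r}")

    @property
    def ids(self) -> np.ndarray:
        """Sorted nonzero labels present in the mask."""
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def mask_of(self, label: int) -> np.ndarray:
        return self.labels == label

    def area_of(self, label: int) -> int:
        return int(np.count_nonzero(self.labels == label))


def _data_threshold(values: np.ndarray, config: AnalysisConfig) -> float:
    if config.threshold_method == "percentile":
        return float(np.percentile(values, config.threshold_percentile))
    return float(threshold_otsu(values))


def _support_threshold(values: np.ndarray, config: AnalysisConfig) -> float:
    """Threshold separating background from cytoplasmic support.

    Fluorescence composites are skewed and often trimodal (background,
    dim cytoplasm, bright organelles); Otsu then cuts above the dim
    cytoplasm and truncates cells.  The triangle method picks the foot of
    the dominant background peak instead, keeping the whole cell body.
    Both are data-driven, hence invariant to positive rescaling.
    """
    if config.threshold_method == "percentile":
        return float(np.percentile(values, config.threshold_percentile))
    return float(threshold_triangle(values))


def segment_nuclei(
    nuclear: np.ndarray,
    config: AnalysisConfig,
    pixel_size_um: float,
) -> LabelMask:
    """Label nuclei in the nuclear-stain channel.

    Gaussian smoothing, Otsu (or percentile) threshold, connected
    components, then removal of objects below the configured minimum
    area.  An all-zero (or constant) image yields an empty mask.
    """
    nuclear = np.asarray(nuclear, dtype=float)
    if nuclear.size == 0:
        raise ValidationError("empty raster")
    smooth = gaussian(nuclear, sigma=2.0, preserve_range=True)
    if np.ptp(smooth) == 0:
        return LabelMask(np.zeros(nuclear.shape, dtype=np.int32), "nucleus")
    thr = _data_threshold(smooth, config)
    fg = smooth > thr
    labels, _ = ndi.label(fg, structure=CROSS)
    min_area_px = config.min_nucleus_area_um2 / pixel_size_um**2
    sizes = np.bincount(labels.ravel())
    keep = np.flatnonzero(sizes >= min_area_px)
    keep = keep[keep > 0]
    out = np.zeros_like(labels, dtype=np.int32)
    for new, old in enumerate(keep, start=1):
        out[labels == old] = new
    return LabelMask(out, "nucleus")


def segment_cells(
    nuclei: LabelMask,
    cytoplasm: np.ndarray,
    config: AnalysisConfig,
) -> LabelMask:
    """Nucleus-seeded watershed delineation of whole-cell territories.

    The cytoplasmic support is the suprathreshold region of the smoothed
    composite (plus every nucleus pixel, so each cell contains its seed);
    watershed on the inverted smoothed intensity assigns every support
    pixel to exactly one nucleus label, preserving numbering.
    """
    cytoplasm = np.asarray(cytoplasm, dtype=float)
    if cytoplasm.shape != nuclei.labels.shape:
        raise ValidationError("cytoplasm raster and nuclei mask differ in shape")
    if len(nuclei.ids) == 0:
        return LabelMask(np.zeros_like(nuclei.labels), "cell")
    smooth = gaussian(cytoplasm, sigma=2.0, preserve_range=True)
    if np.ptp(smooth) == 0:
        support = np.ones_like(smooth, dtype=bool)
    else:
        support = smooth > _support_threshold(smooth, config)
    support |= nuclei.labels > 0
    labels = watershed(-smooth, markers=nuclei.labels, mask=support)
    return LabelMask(labels.astype(np.int32), "cell")


def central_region(cells: LabelMask, fraction: float) -> LabelMask:
    """Delineate, per cell, the given area fraction toward the cell centre.

    Each cell mask is eroded iteratively with a 3x3 cross; the central
    region is the last iterate whose area is still >= fraction x the cell
    area.  ``fraction = 1`` returns the cell mask itself; the peripheral
    region is cell minus central.
    """
    if not 0 < fraction <= 1:
        raise ValidationError("fraction must lie in (0, 1]")
    out = np.zeros_like(cells.labels)
    for lab in cells.ids:
        mask = cells.mask_of(lab)
        target = fraction * mask.sum()
        current = mask
        while True:
            nxt = ndi.binary_erosion(current, structure=CROSS)
            if nxt.sum() < target:
                break
            current = nxt
        out[current] = lab
    return LabelMask(out, "central")


def border_touching_labels(cells: LabelMask) -> set[int]:
    """Labels of cells touching the image border."""
    edge = np.concatenate(
        [
            cells.labels[0, :],
            cells.labels[-1, :],
            cells.labels[:, 0],
            cells.labels[:, -1],
        ]
    )
    return set(int(v) for v in np.unique(edge) if v > 0)
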