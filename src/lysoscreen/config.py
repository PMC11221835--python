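"""Run-wide analysis configuration.

Every tunable parameter of the scoring pipeline lives in one
:class:`AnalysisConfig` that is validated on construction, serialised to
YAML, and logged with each run.  The three parameters the assay fixes are
the 7 µm measurement circle placed on the MTOC, the 1.1-fold hit-calling
threshold, and the 70 % central cell-area fraction used to delineate the
peripheral region; everything else (threshold methods, background radius,
exclusion policy) is an explicit, documented default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

from .errors import ValidationError

_STATISTICS = ("mean", "median")
_THRESHOLD_METHODS = ("otsu", "percentile")


@dataclass
class AnalysisConfig:
    """Parameters of a scoring run.

    Parameters
    ----------
    circle_diameter_um:
        Diameter, in µm, of the circle centred on the MTOC whose lysosomal
        intensity forms the numerator of the clustering ratio.
    hit_fold_threshold:
        Strict fold-change threshold above which a compound is a hit.
    central_area_fraction:
        Fraction of each cell's area delineated toward the cell centre;
        the remainder is the peripheral region.
    control_label:
        Compound label identifying control wells in a plate layout.
    per_well_statistic:
        Summary statistic pooling per-cell ratios within a well
        (``"mean"`` or ``"median"``).
    background_radius_um:
        Rolling-ball (morphological opening) radius for background
        subtraction of the MTOC-marker channel.
    threshold_method:
        Data-driven threshold used for spot picking and masks
        (``"otsu"`` or ``"percentile"``).
    threshold_percentile:
        Percentile used when ``threshold_method == "percentile"``.
    peripheral_intensity_fraction:
        Minimum fraction of a cell's lysosomal intensity that must fall
        in the peripheral region for the cell to count as having
        peripheral lysosomes.
    norm_low_percentile / norm_high_percentile:
        Clipping percentiles of the contrast normalisation applied to the
        MTOC-marker channel.
    min_nucleus_area_um2:
        Objects smaller than this are discarded as debris during nucleus
        segmentation.
    exclude_border_cells:
        Drop cells touching the image border (truncated denominators
        bias the ratio).
    clip_circle_to_cell:
        Restrict the numerator region to circle ∩ cell, guaranteeing a
        ratio in [0, 1].
    exclude_nucleus_from_denominator:
        If set, the whole-cell denominator omits the nuclear region.
    rng_seed:
        Seed recorded for any stochastic step of a run.
    """

    circle_diameter_um: float = 7.0
    hit_fold_threshold: float = 1.1
    central_area_fraction: float = 0.70
    control_label: str = "DMSO"
    per_well_statistic: str = "mean"
    background_radius_um: float = 5.0
    threshold_method: str = "otsu"
    threshold_percentile: float = 99.0
    peripheral_intensity_fraction: float = 0.5
    norm_low_percentile: float = 1.0
    norm_high_percentile: float = 99.9
    min_nucleus_area_um2: float = 3.0
    exclude_border_cells: bool = True
    clip_circle_to_cell: bool = True
    exclude_nucleus_from_denominator: bool = False
    rng_seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in (
            "circle_diameter_um",
            "hit_fold_threshold",
            "background_radius_um",
            "min_nucleus_area_um2",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")
        if not 0 < self.central_area_fraction <= 1:
            raise ValidationError("central_area_fraction must lie in (0, 1]")
        if not 0 < self.peripheral_intensity_fraction < 1:
            raise ValidationError(
                "peripheral_intensity_fraction must lie in (0, 1)"
            )
        if self.per_well_statistic not in _STATISTICS:
            raise ValidationError(
                f"per_well_statistic must be one of {_STATISTICS}"
            )
        if self.threshold_method not in _THRESHOLD_METHODS:
            raise ValidationError(
                f"threshold_method must be one of {_THRESHOLD_METHODS}"
            )
        if not 0 <= self.norm_low_percentile < self.norm_high_percentile <= 100:
            raise ValidationError(
                "normalisation percentiles must satisfy 0 <= low < high <= 100"
            )
        if not 0 < self.threshold_percentile < 100:
            raise ValidationError("threshold_percentile must lie in (0, 100)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=False)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ValidationError("config YAML must map parameter -> value")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(
                f"unknown config keys: {sorted(unknown)}"
            )
        return cls(**raw)
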