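"""Reading and writing of images, plate layouts, and measurement tables.

Images travel as multi-page TIFF (one page per channel); channel roles
(nuclear, tubulin, lysosome, aggregate) are declared in a channel map and
never inferred from page order.  Tables are UTF-8 CSV with a header row;
NaN serialises as an empty cell.  All coordinates are 0-based (row, col)
pixel indices and physical distances use the mandatory pixel size in
µm/pixel.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import DataError, FormatError, ValidationError

CHANNEL_ROLES = ("nuclear", "tubulin", "lysosome", "aggregate")


@dataclass
class FieldImage:
    """One microscope field: co-registered channel rasters plus metadata."""

    field_id: str
    well_id: str
    channels: dict[str, np.ndarray]
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be > 0")
        if not self.channels:
            raise ValidationError("FieldImage needs at least one channel")
        shapes = {role: arr.shape for role, arr in self.channels.items()}
        first = next(iter(shapes.values()))
        for role, shape in shapes.items():
            arr = self.channels[role]
            if arr.ndim != 2:
                raise FormatError(f"channel {role!r} is not a 2-D raster")
            if shape != first:
                raise FormatError(
                    f"channel {role!r} has shape {shape}, expected {first}"
                )
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValidationError(
                    f"channel {role!r} contains negative or non-finite values"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class PlateLayout:
    """Treatment annotation for one plate: well -> compound mapping."""

    rows: pd.DataFrame

    REQUIRED = ("well_id", "compound_id", "is_control")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.rows.columns]
        if missing:
            raise FormatError(f"plate layout missing columns: {missing}")
        dup = self.rows["well_id"][self.rows["well_id"].duplicated()]
        if len(dup):
            raise ValidationError(
                f"duplicate well_ids in layout: {sorted(set(dup))}"
            )
        if not bool(self.rows["is_control"].any()):
            raise DataError("plate layout has no control well")

    @property
    def control_wells(self) -> list[str]:
        return list(self.rows.loc[self.rows["is_control"], "well_id"])

    def compound_of(self, well_id: str) -> str:
        sel = self.rows.loc[self.rows["well_id"] == well_id, "compound_id"]
        if sel.empty:
            raise DataError(f"well {well_id!r} absent from layout")
        return str(sel.iloc[0])


def read_field(
    path: str | Path,
    channel_map: Mapping[str, int],
    pixel_size_um: float,
    field_id: Optional[str] = None,
    well_id: str = "",
) -> FieldImage:
    """Read a multi-page TIFF into a :class:`FieldImage`.

    ``channel_map`` assigns channel roles to 0-based page indices.
    Rasters are copied losslessly; integer data stay integer.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"image file not found: {path}")
    if pixel_size_um <= 0:
        raise ValidationError("pixel_size_um must be > 0")
    with tifffile.TiffFile(path) as tif:
        n_pages = len(tif.pages)
        channels: dict[str, np.ndarray] = {}
        shape = None
        for role, page_idx in channel_map.items():
            if not 0 <= page_idx < n_pages:
                raise FormatError(
                    f"channel {role!r} requests page {page_idx} of a "
                    f"{n_pages}-page file {path.name}"
                )
            arr = tif.pages[page_idx].asarray()
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise FormatError(
                    f"page {page_idx} ({role!r}) has shape {arr.shape}, "
                    f"expected {shape} in {path.name}"
                )
            channels[role] = arr
    return FieldImage(
        field_id=field_id or path.stem,
        well_id=well_id,
        channels=channels,
        pixel_size_um=pixel_size_um,
    )


def write_field(
    field_img: FieldImage,
    path: str | Path,
    channel_order: Optional[Sequence[str]] = None,
) -> dict[str, int]:
    """Write a :class:`FieldImage` as a multi-page TIFF.

    Returns the channel map (role -> page index) used, so the file can be
    read back with :func:`read_field`.
    """
    order = list(channel_order or field_img.channels.keys())
    with tifffile.TiffWriter(str(path)) as tif:
        for role in order:
            tif.write(field_img.channels[role], contiguous=False)
    return {role: i for i, role in enumerate(order)}


def read_plate_layout(path: str | Path) -> PlateLayout:
    """Read a plate layout from CSV or YAML (list of row mappings)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"layout file not found: {path}")
    if path.suffix.lower() in (".yaml", ".yml"):
        raw = yaml.safe_load(path.read_text())
        if not isinstance(raw, list):
            raise FormatError("YAML layout must be a list of row mappings")
        rows = pd.DataFrame(raw)
    else:
        rows = pd.read_csv(path)
    if "is_control" in rows.columns:
        rows["is_control"] = rows["is_control"].astype(bool)
    return PlateLayout(rows)


def write_table(
    rows,
    path: str | Path,
    header_comment: Optional[str] = None,
    columns: Optional[Sequence[str]] = None,
) -> None:
    """Write records to CSV with stable column order and full float precision.

    ``rows`` may be a DataFrame or any list of homogeneous mappings /
    dataclass-like records.  NaN serialises as an empty cell.  ``columns``
    fixes the header for an empty record list.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        df = pd.DataFrame([_as_record(r) for r in rows], columns=columns)
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table` (``#`` lines are comments)."""
    return pd.read_csv(path, comment="#")


def _as_record(row) -> dict:
    if isinstance(row, dict):
        return row
    if hasattr(row, "_asdict"):
        return row._asdict()
    if hasattr(row, "__dataclass_fields__"):
        import dataclasses

        return dataclasses.asdict(row)
    raise ValidationError(f"cannot serialise record of type {type(row)!r}")
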