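"""End-to-end orchestration: score fields, build well tables, run demos.

`score_field` chains segmentation → MTOC detection → clustering ratio for
every cell of a field, recording exclusions (border cells, undetected
MTOC, empty lysosome signal) with reasons.  `run_score` aggregates
per-cell ratios into per-well clustering values normalised against the
pooled control wells of a plate layout.  `run_demo` wires the whole
package together on a miniature synthetic screen.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import synthetic
from .cascade import run_cascade
from .config import AnalysisConfig
from .errors import DataError
from .io import FieldImage, PlateLayout, write_table
from .metrics import ClusteringMeasurement, clustering_ratio, clustering_value
from .mtoc import detect_mtoc
from .segmentation import (
    LabelMask,
    border_touching_labels,
    segment_cells,
    segment_nuclei,
)

logger = logging.getLogger("lysoscreen")


def score_field(
    field: FieldImage,
    config: AnalysisConfig,
) -> list[ClusteringMeasurement]:
    """Per-cell clustering ratios for one field, exclusions included."""
    measurements, _ = score_field_with_context(field, config)
    return measurements


def score_field_with_context(
    field: FieldImage,
    config: AnalysisConfig,
) -> tuple[list[ClusteringMeasurement], LabelMask]:
    """As :func:`score_field`, also returning the cell label mask
    (needed to pair measurements with external per-cell annotations)."""
    px = field.pixel_size_um
    nuclear = field.channels["nuclear"]
    tubulin = field.channels["tubulin"]
    lysosome = field.channels["lysosome"]

    nuclei = segment_nuclei(nuclear, config, px)
    composite = np.asarray(tubulin, dtype=float) + np.asarray(
        lysosome, dtype=float
    )
    cells = segment_cells(nuclei, composite, config)
    border = border_touching_labels(cells) if config.exclude_border_cells else set()
    calls = detect_mtoc(tubulin, cells, config, px)

    measurements: list[ClusteringMeasurement] = []
    for call in calls:
        if call.cell_label in border:
            measurements.append(
                ClusteringMeasurement(
                    call.cell_label,
                    field.well_id,
                    float("nan"),
                    0,
                    cells.area_of(call.cell_label),
                    excluded=True,
                    reason="touches image border",
                )
            )
            continue
        m = clustering_ratio(
            lysosome,
            cells.mask_of(call.cell_label),
            call,
            config,
            px,
            well_id=field.well_id,
            nucleus_mask=nuclei.labels == call.cell_label,
        )
        measurements.append(m)
    return measurements, cells


def run_score(
    fields_by_well: Mapping[str, Sequence[FieldImage]],
    layout: PlateLayout,
    config: AnalysisConfig,
    out_dir: Optional[str | Path] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score a plate of fields into per-cell and per-well tables.

    Control wells (``is_control`` in the layout) are pooled to form the
    normalisation denominator; each well's clustering value is its
    per-cell ratio summary divided by the pooled control summary.  Wells
    in the layout without any field are warned about and skipped; a plate
    whose control wells yield no analyzable cell aborts.
    """
    cell_rows: list[dict] = []
    ratios_by_well: dict[str, list[float]] = {}
    exclusion_counts: dict[str, int] = {}
    for well_id in layout.rows["well_id"]:
        fields = fields_by_well.get(well_id, [])
        if not fields:
            logger.warning("well %s has no image field; skipped", well_id)
            continue
        well_ratios: list[float] = []
        for field in fields:
            for m in score_field(field, config):
                cell_rows.append(
                    {
                        "field_id": field.field_id,
                        "well_id": well_id,
                        "cell_label": m.cell_label,
                        "raw_ratio": m.raw_ratio,
                        "excluded": m.excluded,
                        "reason": m.reason,
                    }
                )
                if m.excluded:
                    exclusion_counts[m.reason] = (
                        exclusion_counts.get(m.reason, 0) + 1
                    )
                else:
                    well_ratios.append(m.raw_ratio)
        ratios_by_well[well_id] = well_ratios

    control_pool = [
        r
        for well in layout.control_wells
        for r in ratios_by_well.get(well, [])
    ]
    if not control_pool:
        raise DataError("no analyzable cells in any control well")
    for reason, n in sorted(exclusion_counts.items()):
        logger.info("excluded %d cells: %s", n, reason)

    well_rows = []
    stat = config.per_well_statistic
    for well_id, ratios in ratios_by_well.items():
        value = (
            clustering_value(ratios, control_pool, stat)
            if ratios
            else float("nan")
        )
        if not ratios:
            logger.warning("well %s has no analyzable cells", well_id)
        well_rows.append(
            {
                "well_id": well_id,
                "compound_id": layout.compound_of(well_id),
                "n_cells": len(ratios),
                "statistic": stat,
                "clustering_value": value,
            }
        )
    per_cell = pd.DataFrame(cell_rows)
    per_well = pd.DataFrame(well_rows)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        header = "lysoscreen scoring run\n" + "config: " + json.dumps(
            config.to_dict()
        )
        write_table(per_cell, out_dir / "per_cell.csv", header_comment=header)
        write_table(per_well, out_dir / "per_well.csv", header_comment=header)
    return per_cell, per_well


def run_demo(
    seed: int = 7,
    out_dir: Optional[str | Path] = None,
    n_compounds: int = 60,
    n_planted_hits: int = 5,
    n_secondary_hits: int = 3,
    n_autofluorescent: int = 1,
) -> dict:
    """Miniature end-to-end screen on synthetic data.

    Generates (i) a clustered-vs-dispersed image well pair, scored through
    the full imaging pipeline, and (ii) a compound table with planted
    primary/secondary hits and auto-fluorescent annotations, run through
    the cascade.  Returns a JSON-serialisable report; identical seeds give
    identical reports.
    """
    rng_seeds = [
        int(s.generate_state(1)[0] & 0x7FFFFFFF)
        for s in np.random.SeedSequence(seed).spawn(4)
    ]

    # imaging arm: one clustered (treated) and one dispersed (control) well
    config = AnalysisConfig(rng_seed=seed)
    spec = synthetic.SyntheticCellSpec(seed=rng_seeds[0])
    treated_field, _ = synthetic.generate_field(
        dataclasses.replace(spec, clustered_fraction=0.8, seed=rng_seeds[0])
    )
    control_field, _ = synthetic.generate_field(
        dataclasses.replace(spec, clustered_fraction=0.2, seed=rng_seeds[1])
    )
    treated_field.well_id = "B02"
    control_field.well_id = "B01"
    layout = PlateLayout(
        pd.DataFrame(
            {
                "well_id": ["B01", "B02"],
                "compound_id": [config.control_label, "demo-compound"],
                "is_control": [True, False],
            }
        )
    )
    _, per_well = run_score(
        {"B01": [control_field], "B02": [treated_field]}, layout, config
    )

    # screen arm: planted-hit tables through the cascade
    primary, primary_truth = synthetic.generate_screen_table(
        n_compounds, n_planted_hits, seed=rng_seeds[2],
        threshold=config.hit_fold_threshold,
    )
    planted_primary = sorted(
        primary_truth.loc[primary_truth["is_hit"], "compound_id"]
    )
    secondary, secondary_truth = synthetic.generate_screen_table(
        len(planted_primary),
        min(n_secondary_hits, len(planted_primary)),
        seed=rng_seeds[3],
        threshold=config.hit_fold_threshold,
        compound_ids=planted_primary,
    )
    planted_secondary = sorted(
        secondary_truth.loc[secondary_truth["is_hit"], "compound_id"]
    )
    flagged = planted_secondary[: min(n_autofluorescent, len(planted_secondary))]
    ledger = run_cascade(
        primary, secondary, flagged, threshold=config.hit_fold_threshold
    )

    values = dict(zip(per_well["well_id"], per_well["clustering_value"]))
    report = {
        "seed": seed,
        "imaging": {
            "control_well_value": values["B01"],
            "treated_well_value": values["B02"],
            "treated_gt_control": bool(values["B02"] > values["B01"]),
        },
        "screen": {
            "n_compounds": n_compounds,
            "planted_primary_hits": planted_primary,
            "planted_secondary_hits": planted_secondary,
            "autofluorescent": list(flagged),
            "ledger": ledger.to_dict(),
            "final_candidates": ledger.final_candidates,
            "recovered_primary_exactly": sorted(ledger.stages[0].passed)
            == planted_primary,
        },
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "demo_report.json").write_text(json.dumps(report, indent=2))
        write_table(per_well, out_dir / "demo_per_well.csv")
    return report
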