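#!/usr/bin/env python
"""Score the simulated imaging plate through the full measurement chain.

Reads the TIFF wells written by 01_simulate_screen.py, runs nucleus/cell
segmentation, MTOC detection and the in-circle clustering ratio per
cell, normalises per-well summaries against the control well, and writes
per-cell and per-well tables under results/.  The clustered well should
score a clustering value well above the 1.1-fold hit threshold.

Run from the repository root after 01_simulate_screen.py.
"""

import json
from pathlib import Path

from lysoscreen import AnalysisConfig, read_field, read_plate_layout, run_score

RESULTS = Path("results")
SCRATCH = Path("scratch/simulated_screen")


def main() -> None:
    if not SCRATCH.exists():
        raise SystemExit("run analysis/01_simulate_screen.py first")
    channel_map = json.loads((SCRATCH / "channel_map.json").read_text())
    layout = read_plate_layout(SCRATCH / "plate_layout.csv")
    config = AnalysisConfig()

    fields_by_well: dict[str, list] = {}
    for path in sorted(SCRATCH.glob("*.tif")):
        well = path.stem.split("_")[0]
        fields_by_well.setdefault(well, []).append(
            read_field(path, channel_map, pixel_size_um=0.325, well_id=well)
        )

    per_cell, per_well = run_score(
        fields_by_well, layout, config, out_dir=RESULTS / "imaging"
    )
    print(per_well.to_string(index=False))
    n_excluded = int(per_cell["excluded"].sum())
    print(f"{len(per_cell)} cells scored, {n_excluded} excluded")
    values = dict(zip(per_well["well_id"], per_well["clustering_value"]))
    fold = values["B02"] / values["B01"]
    print(f"treated/control clustering-value fold change: {fold:.2f} "
          f"({'above' if fold > config.hit_fold_threshold else 'below'} "
          f"the {config.hit_fold_threshold}-fold hit threshold)")


if __name__ == "__main__":
    main()
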