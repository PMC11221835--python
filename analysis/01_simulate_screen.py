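#!/usr/bin/env python
"""Simulate every input of the screening campaign, with ground truth.

Produces, under scratch/simulated_screen/ (regenerable raw inputs):
the primary-screen fold-change table (1200 compounds, 63 planted hits),
the secondary flux table for the primary hits (15 planted passers),
autofluorescence and confirmation annotations, flow-cytometry event
tables for a control and a treated sample, and imaging fields (TIFF) for
a clustered/dispersed well pair.  Downstream drivers (02-04) consume
these and write their summaries under results/.

Run from the repository root:  python analysis/01_simulate_screen.py
"""

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from lysoscreen import (
    SyntheticCellSpec,
    generate_field,
    generate_flow_events,
    generate_screen_table,
    write_field,
    write_table,
)

SEED = 20240703
RESULTS = Path("results")
SCRATCH = Path("scratch/simulated_screen")


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)

    # screen tables with planted funnel: 1200 -> 63 -> 15 -> 10 -> 6
    primary, primary_truth = generate_screen_table(
        1200, 63, seed=SEED, hit_margin=0.05, control_noise_sd=0.01
    )
    hit_ids = sorted(primary_truth.loc[primary_truth["is_hit"], "compound_id"])
    secondary, secondary_truth = generate_screen_table(
        63, 15, seed=SEED + 1, hit_margin=0.05, control_noise_sd=0.01,
        compound_ids=hit_ids,
    )
    sec_ids = sorted(secondary_truth.loc[secondary_truth["is_hit"], "compound_id"])
    flagged = sorted(rng.choice(sec_ids, size=5, replace=False))
    confirmed = sorted(
        rng.choice([c for c in sec_ids if c not in flagged], size=6, replace=False)
    )
    write_table(primary, SCRATCH / "primary_screen.csv")
    write_table(secondary, SCRATCH / "secondary_screen.csv")
    write_table(primary_truth, SCRATCH / "primary_truth.csv")
    write_table(secondary_truth, SCRATCH / "secondary_truth.csv")
    write_table(
        [{"compound_id": c} for c in flagged], SCRATCH / "autofluorescent.csv"
    )
    write_table(
        [{"compound_id": c} for c in confirmed], SCRATCH / "confirmed.csv"
    )
    print(f"primary screen: {len(primary)} compounds, "
          f"{primary_truth['is_hit'].sum()} planted hits")
    print(f"secondary screen: {len(secondary)} compounds, "
          f"{secondary_truth['is_hit'].sum()} planted passers; "
          f"{len(flagged)} flagged auto-fluorescent, {len(confirmed)} confirmed")

    # imaging well pair: clustered (treated) vs dispersed (control)
    layout = pd.DataFrame(
        {
            "well_id": ["B01", "B02"],
            "compound_id": ["DMSO", "clustering-compound"],
            "is_control": [True, False],
        }
    )
    write_table(layout, SCRATCH / "plate_layout.csv")
    spec = SyntheticCellSpec(seed=SEED)
    channel_map = None
    for well, kappa, seed in (("B01", 0.2, SEED + 10), ("B02", 0.8, SEED + 11)):
        field, truth = generate_field(
            dataclasses.replace(spec, clustered_fraction=kappa, seed=seed)
        )
        field.well_id = well
        channel_map = write_field(field, SCRATCH / f"{well}_f000.tif")
        print(f"well {well}: kappa={kappa}, {len(truth.cells)} cells, "
              f"mean true in-circle fraction "
              f"{np.mean([c.true_in_circle_fraction for c in truth.cells]):.3f}")
    (SCRATCH / "channel_map.json").write_text(json.dumps(channel_map))

    # flow cytometry: 10,000 events per sample, control vs enhanced flux
    for name, median_ratio, seed in (("control", 1.0, SEED + 20),
                                     ("treated", 2.0, SEED + 21)):
        events, truth = generate_flow_events(
            10_000, dead_fraction=0.08, rfp_negative_fraction=0.05,
            seed=seed, median_ratio=median_ratio,
        )
        write_table(events, SCRATCH / f"flow_events_{name}.csv")
        print(f"flow sample {name}: {truth['n_events']} events, "
              f"planted median RFP/GFP {truth['median_ratio']}")


if __name__ == "__main__":
    main()
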