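#!/usr/bin/env python
"""Run the multi-stage hit-calling cascade on the simulated screen.

Reads the fold-change tables and annotations written by
01_simulate_screen.py, calls hits at the strict 1.1-fold threshold at
both stages, removes annotated auto-fluorescent compounds, records the
confirmation annotations, and writes the stage ledger as JSON under
results/.  Recovery against the planted truth is reported.

Run from the repository root after 01_simulate_screen.py.
"""

from pathlib import Path

from lysoscreen import run_cascade
from lysoscreen.io import read_table

RESULTS = Path("results")
SCRATCH = Path("scratch/simulated_screen")


def main() -> None:
    primary = read_table(SCRATCH / "primary_screen.csv")
    secondary = read_table(SCRATCH / "secondary_screen.csv")
    flagged = read_table(SCRATCH / "autofluorescent.csv")["compound_id"].tolist()
    confirmed = read_table(SCRATCH / "confirmed.csv")["compound_id"].tolist()

    ledger = run_cascade(
        primary, secondary, flagged, threshold=1.1, confirmed=confirmed
    )
    ledger.to_json(RESULTS / "cascade_ledger.json")

    counts = " -> ".join(
        [str(ledger.stages[0].input_count)]
        + [str(c) for c in ledger.counts()]
    )
    print(f"screening funnel: {counts}")

    truth = read_table(SCRATCH / "primary_truth.csv")
    planted = set(truth.loc[truth["is_hit"], "compound_id"])
    called = set(ledger.stages[0].passed)
    print(f"primary hits: {len(called)} called, "
          f"{len(called & planted)} of {len(planted)} planted recovered, "
          f"{len(called - planted)} false positives")
    print(f"final candidates: {sorted(ledger.final_candidates)}")


if __name__ == "__main__":
    main()
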