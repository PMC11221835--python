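"""Screening funnel: fold-change hit calling and the multi-stage ledger.

Primary screen: compounds whose clustering-value fold change is strictly
over the threshold (default 1.1) are hits.  Secondary screen: the same
rule on the autophagic-flux (RFP/GFP) fold change of the primary hits.
Auto-fluorescent compounds, an input annotation, are then excluded; an
optional final confirmation stage (manual in practice) is recorded from
supplied annotations, never computed.  The ledger chains counts across
stages: every stage's input count equals the previous stage's output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import DataError, ValidationError


@dataclass
class StageRecord:
    stage: str
    input_count: int
    rule: str
    output_count: int
    passed: list[str]
    excluded: dict[str, str]  # compound_id -> reason


@dataclass
class CascadeLedger:
    """Ordered record of the screening funnel."""

    stages: list[StageRecord] = field(default_factory=list)

    def add(self, record: StageRecord) -> None:
        if self.stages and record.input_count != self.stages[-1].output_count:
            raise DataError(
                f"stage {record.stage!r} input count {record.input_count} "
                f"!= previous output {self.stages[-1].output_count}"
            )
        self.stages.append(record)

    @property
    def final_candidates(self) -> list[str]:
        return list(self.stages[-1].passed) if self.stages else []

    def counts(self) -> list[int]:
        return [s.output_count for s in self.stages]

    def to_dict(self) -> dict:
        return {
            "stages": [
                {
                    "stage": s.stage,
                    "input_count": s.input_count,
                    "rule": s.rule,
                    "output_count": s.output_count,
                    "passed": s.passed,
                    "excluded": s.excluded,
                }
                for s in self.stages
            ]
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def call_hits(rows: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Hits: fold_change strictly over ``threshold``.

    Returns the hit rows sorted by descending fold change, ties broken by
    compound_id.  Rows with NaN fold change are excluded (never silently
    dropped: they carry an ``excluded_reason``) and reported via the
    ``attrs['excluded']`` mapping of the result.
    """
    if threshold <= 0:
        raise ValidationError("threshold must be > 0")
    required = {"compound_id", "fold_change"}
    if not required <= set(rows.columns):
        raise ValidationError(f"hit table needs columns {sorted(required)}")
    fold = pd.to_numeric(rows["fold_change"], errors="coerce")
    invalid = rows.loc[fold.isna(), "compound_id"]
    valid = rows.loc[~fold.isna()].copy()
    valid["fold_change"] = fold[~fold.isna()].astype(float)
    if np.isinf(valid["fold_change"]).any():
        raise ValidationError("fold changes must be finite")
    hits = valid.loc[valid["fold_change"] > threshold]
    hits = hits.sort_values(
        ["fold_change", "compound_id"], ascending=[False, True]
    ).reset_index(drop=True)
    hits.attrs["excluded"] = {
        str(c): "non-numeric fold change" for c in invalid
    }
    return hits


def exclude_autofluorescent(
    hits: pd.DataFrame,
    flagged: Iterable[str],
    known_compounds: Optional[Iterable[str]] = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Remove auto-fluorescent compounds from a hit table.

    ``flagged`` is the set of compound ids annotated as auto-fluorescent;
    if ``known_compounds`` is given, any flagged id outside it raises a
    validation error.  Returns the filtered hits and the exclusion record.
    """
    flagged = set(map(str, flagged))
    if known_compounds is not None:
        unknown = flagged - set(map(str, known_compounds))
        if unknown:
            raise ValidationError(
                f"unknown compounds in autofluorescence flags: {sorted(unknown)}"
            )
    removed = hits.loc[hits["compound_id"].astype(str).isin(flagged)]
    kept = hits.loc[~hits["compound_id"].astype(str).isin(flagged)].reset_index(
        drop=True
    )
    record = {str(c): "auto-fluorescent" for c in removed["compound_id"]}
    return kept, record


def run_cascade(
    primary: pd.DataFrame,
    secondary: pd.DataFrame,
    flagged: Iterable[str],
    threshold: float = 1.1,
    secondary_threshold: Optional[float] = None,
    confirmed: Optional[Iterable[str]] = None,
) -> CascadeLedger:
    """Run the full screening funnel and return its ledger.

    ``primary`` and ``secondary`` are fold-change tables (compound_id,
    fold_change); secondary rows must be a subset of the primary hits.
    Primary hits missing from the secondary table are recorded as
    excluded ("no secondary measurement") so stage counts chain exactly.
    ``confirmed`` ids, when given, record the manual confirmation stage.
    """
    if secondary_threshold is None:
        secondary_threshold = threshold
    ledger = CascadeLedger()

    primary_hits = call_hits(primary, threshold)
    primary_ids = [str(c) for c in primary_hits["compound_id"]]
    ledger.add(
        StageRecord(
            "primary_screen",
            input_count=len(primary),
            rule=f"clustering value fold change > {threshold}",
            output_count=len(primary_ids),
            passed=primary_ids,
            excluded={
                **{
                    str(c): "below threshold"
                    for c in primary["compound_id"]
                    if str(c) not in primary_ids
                },
                **primary_hits.attrs.get("excluded", {}),
            },
        )
    )

    secondary_ids = set(str(c) for c in secondary["compound_id"])
    extra = secondary_ids - set(primary_ids)
    if extra:
        raise DataError(
            f"secondary table contains compounds absent from primary hits: "
            f"{sorted(extra)}"
        )
    secondary_hits = call_hits(secondary, secondary_threshold)
    sec_pass = [str(c) for c in secondary_hits["compound_id"]]
    sec_excluded = {
        str(c): "below threshold"
        for c in secondary["compound_id"]
        if str(c) not in sec_pass
    }
    sec_excluded.update(
        {
            c: "no secondary measurement"
            for c in primary_ids
            if c not in secondary_ids
        }
    )
    sec_excluded.update(secondary_hits.attrs.get("excluded", {}))
    ledger.add(
        StageRecord(
            "secondary_screen",
            input_count=len(primary_ids),
            rule=f"RFP/GFP fold change > {secondary_threshold}",
            output_count=len(sec_pass),
            passed=sec_pass,
            excluded=sec_excluded,
        )
    )

    kept, removed = exclude_autofluorescent(
        secondary_hits, flagged, known_compounds=primary["compound_id"]
    )
    kept_ids = [str(c) for c in kept["compound_id"]]
    ledger.add(
        StageRecord(
            "autofluorescence_exclusion",
            input_count=len(sec_pass),
            rule="remove annotated auto-fluorescent compounds",
            output_count=len(kept_ids),
            passed=kept_ids,
            excluded=removed,
        )
    )

    if confirmed is not None:
        confirmed = set(map(str, confirmed))
        unknown = confirmed - set(kept_ids)
        if unknown:
            raise DataError(
                f"confirmed compounds not in cascade: {sorted(unknown)}"
            )
        final = [c for c in kept_ids if c in confirmed]
        ledger.add(
            StageRecord(
                "manual_confirmation",
                input_count=len(kept_ids),
                rule="endogenous lysosomal clustering confirmed by "
                "immunofluorescence (recorded annotation)",
                output_count=len(final),
                passed=final,
                excluded={
                    c: "not confirmed" for c in kept_ids if c not in confirmed
                },
            )
        )
    return ledger
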