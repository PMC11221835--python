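"""Autophagic-flux readouts.

Flow cytometry of the tandem RFP–GFP–LC3 reporter: GFP quenches in acidic
autolysosomes while RFP persists, so a higher per-cell RFP/GFP ratio
means more flux.  Events are gated on DAPI (dead-cell exclusion) and a
minimum RFP (reporter-positive), ratios are summarised per sample and
expressed as fold change versus control.  Densitometry ratios cover the
HaloTag-LC3 processing assay (free Halo band over the sum of both bands,
x100) and generic band ratios (LC3-II over loading, Triton-insoluble over
soluble fractions).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .metrics import normalize_to_control

EVENT_COLUMNS = ("gfp", "rfp", "dapi")


def gate_events(
    events: pd.DataFrame,
    dapi_max: float,
    rfp_min: float,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Live, reporter-positive gate.

    Keeps events with ``dapi <= dapi_max`` (live) and ``rfp >= rfp_min``
    (RFP-positive).  Counts are conserved per exclusion reason; an event
    failing both gates is counted as dead.
    """
    if not np.isfinite(dapi_max) or not np.isfinite(rfp_min):
        raise ValidationError("gate thresholds must be finite")
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValidationError(f"event table missing columns: {missing}")
    dead = events["dapi"] > dapi_max
    rfp_neg = ~dead & (events["rfp"] < rfp_min)
    kept = events.loc[~dead & ~rfp_neg].reset_index(drop=True)
    counts = {
        "total": len(events),
        "kept": len(kept),
        "dead": int(dead.sum()),
        "rfp_negative": int(rfp_neg.sum()),
    }
    if counts["kept"] == 0:
        warnings.warn("no events pass the gates", stacklevel=2)
    return kept, counts


def rfp_gfp_ratio(
    gated: pd.DataFrame,
    statistic: str = "median",
) -> tuple[float, int]:
    """Per-event RFP/GFP ratio summarised by ``statistic``.

    Events with zero GFP cannot form a ratio and are excluded; their
    count is returned alongside the summary.  No valid events yields NaN.
    """
    stat = {"mean": np.mean, "median": np.median}.get(statistic)
    if stat is None:
        raise ValidationError(f"unknown statistic {statistic!r}")
    valid = gated.loc[gated["gfp"] > 0]
    n_zero_gfp = len(gated) - len(valid)
    if len(valid) == 0:
        warnings.warn("no events with positive GFP", stacklevel=2)
        return float("nan"), n_zero_gfp
    ratios = valid["rfp"].to_numpy(dtype=float) / valid["gfp"].to_numpy(dtype=float)
    return float(stat(ratios)), n_zero_gfp


def flux_fold_change(
    treated_ratios: Sequence[float],
    control_ratios: Sequence[float],
    statistic: str = "median",
) -> float:
    """Fold change of per-event ratios vs control (same stat-and-divide
    contract as the clustering value)."""
    return normalize_to_control(treated_ratios, control_ratios, statistic)


def halo_processing_ratio(halo_tmr: float, halo_tmr_lc3b: float) -> float:
    """HaloTag-LC3 processing: 100 * free / (free + fused) band intensity.

    ``halo_tmr`` is the liberated HaloTag band, ``halo_tmr_lc3b`` the
    intact fusion band.  A zero denominator yields NaN with a warning.
    """
    if halo_tmr < 0 or halo_tmr_lc3b < 0:
        raise ValidationError("band intensities must be nonnegative")
    total = halo_tmr + halo_tmr_lc3b
    if total <= 0:
        warnings.warn("zero total Halo band intensity", stacklevel=2)
        return float("nan")
    # divide before scaling: the correctly-rounded quotient is <= 1, so the
    # result can never exceed 100 by a rounding ulp
    return 100.0 * (halo_tmr / total)


def band_ratio(numerator: float, denominator: float) -> float:
    """Generic densitometry ratio (LC3-II/loading, insoluble/soluble...)."""
    if numerator < 0 or denominator < 0:
        raise ValidationError("band intensities must be nonnegative")
    if denominator == 0:
        warnings.warn("zero denominator band", stacklevel=2)
        return float("nan")
    return numerator / denominator


def band_ratio_table(
    bands: pd.DataFrame,
    numerator: str,
    denominator: str,
    sample_col: str = "sample_id",
) -> pd.DataFrame:
    """Per-sample band ratios from a long-format densitometry table.

    ``bands`` has columns (sample_id, band_name, intensity); the result
    has one row per sample with the requested ratio.
    """
    required = {sample_col, "band_name", "intensity"}
    if not required <= set(bands.columns):
        raise ValidationError(f"band table needs columns {sorted(required)}")
    wide = bands.pivot_table(
        index=sample_col, columns="band_name", values="intensity", aggfunc="sum"
    )
    for name in (numerator, denominator):
        if name not in wide.columns:
            raise ValidationError(f"band {name!r} absent from table")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ratios = [
            band_ratio(float(n), float(d))
            for n, d in zip(wide[numerator], wide[denominator])
        ]
    return pd.DataFrame(
        {sample_col: wide.index.to_list(), "ratio": ratios}
    )
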