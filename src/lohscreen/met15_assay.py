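"""Secondary LOH screen at MET15: sector counting and threshold calling.

Colonies heterozygous *met15Δ/MET15* stay white on lead-containing plates;
cells that lose the functional copy precipitate PbS and appear as dark
sectors within the patch.  A control plate of non-hit strains sets the
baseline sector count; the positivity threshold is the rounded control
mean plus a margin (+2 by default — baseline ~11 sectors giving a
threshold of 13).  A strain is called positive when its mean sector count
over countable replicates reaches the threshold; strains whose patches are
entirely brown cannot be counted and are reported as not assessable.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "UNCOUNTABLE_BROWN",
    "compute_threshold",
    "call_sector_positive",
]

UNCOUNTABLE_BROWN = "UNCOUNTABLE_BROWN"


def _countable(values: Sequence) -> list[int]:
    out = []
    for v in values:
        if isinstance(v, str):
            if v.strip().upper() == UNCOUNTABLE_BROWN:
                continue
            v = int(v)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            continue
        iv = int(v)
        if iv < 0:
            raise ValueError(f"negative sector count {v!r}")
        out.append(iv)
    return out


def compute_threshold(
    control_counts: pd.DataFrame | Sequence,
    margin: int = 2,
    per_strain: bool = False,
) -> int:
    """Positivity threshold = round(control baseline mean) + margin.

    ``control_counts`` is either a table with ``strain_id`` and
    ``sector_count`` columns or a flat sequence of counts.  The baseline is
    the pooled mean over all countable control observations; with
    ``per_strain=True`` each strain's mean is taken first and those means
    averaged.  Halves round up (half-up, not banker's) so the threshold is
    deterministic on integer-valued means.
    """
    if isinstance(control_counts, pd.DataFrame):
        if per_strain:
            means = [
                np.mean(c)
                for _, grp in control_counts.groupby("strain_id")
                if (c := _countable(grp["sector_count"]))
            ]
            if not means:
                raise ValueError("no countable control observations")
            baseline = float(np.mean(means))
        else:
            counts = _countable(control_counts["sector_count"])
            if not counts:
                raise ValueError("no countable control observations")
            baseline = float(np.mean(counts))
    else:
        counts = _countable(control_counts)
        if not counts:
            raise ValueError("no countable control observations")
        baseline = float(np.mean(counts))
    return int(math.floor(baseline + 0.5)) + int(margin)


def call_sector_positive(
    counts: pd.DataFrame,
    threshold: int,
    strict: bool = False,
) -> pd.DataFrame:
    """Call strains positive for elevated LOH at MET15.

    One row per strain: ``mean_sectors`` over countable replicates and a
    ``call`` of ``"positive"`` (mean >= threshold), ``"negative"``, or
    ``"NOT_ASSESSABLE"`` when every replicate is uncountably brown.
    ``strict=True`` additionally requires every countable replicate to
    reach the threshold.  Raising the threshold can only turn positives
    negative, never the reverse.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if "strain_id" not in counts.columns or "sector_count" not in counts.columns:
        raise ValueError("counts table needs strain_id and sector_count columns")
    if counts.empty:
        raise ValueError("empty counts table")
    rows = []
    for strain_id, grp in counts.groupby("strain_id", sort=True):
        vals = _countable(grp["sector_count"])
        if not vals:
            rows.append(
                {"strain_id": strain_id, "n_countable": 0, "mean_sectors": np.nan,
                 "call": "NOT_ASSESSABLE"}
            )
            continue
        mean = float(np.mean(vals))
        positive = mean >= threshold
        if strict:
            positive = positive and all(v >= threshold for v in vals)
        rows.append(
            {"strain_id": strain_id, "n_countable": len(vals), "mean_sectors": mean,
             "call": "positive" if positive else "negative"}
        )
    return pd.DataFrame(rows)
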