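"""MAT-locus LOH screen scoring and top-hit calling.

Diploid deletion-collection strains are mated against *MATa* and *MATα*
haploid testers; colonies on double-selection plates indicate an LOH event
at the MAT locus restored mating.  Colony counts per pinned spot are
binned into an ordinal score — 0 colonies → "0", 1–9 → "+", 10–19 → "++",
20–29 → "+++", 30 or more → "++++" — and a strain is a *top-hit* when,
for at least one tester, every one of its four replicates scores "+++" or
better (which forces the summed score to 12 or more; the sum is reported
alongside).  Strains showing lawn growth with both testers, or annotated
with an inherent mating phenotype, are excluded: their growth does not
reflect LOH.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Collection

import pandas as pd

__all__ = [
    "LAWN",
    "SCORE_SYMBOLS",
    "TESTERS",
    "GrowthScore",
    "score_colony_count",
    "call_top_hits",
    "summarize_screen",
]

LAWN = "LAWN"
SCORE_SYMBOLS = ("0", "+", "++", "+++", "++++")
TESTERS = ("MATa", "MATalpha")

#: every replicate must reach this level ("+++") for a pairing to qualify
QUALIFYING_LEVEL = 3


@dataclass(frozen=True)
class GrowthScore:
    """Ordinal growth category of one pinned spot (or a lawn flag)."""

    level: int | None
    lawn: bool = False

    def __post_init__(self) -> None:
        if self.lawn:
            if self.level is not None:
                raise ValueError("lawn score carries no level")
        elif self.level is None or not 0 <= self.level <= 4:
            raise ValueError(f"level must be in 0..4, got {self.level}")

    @property
    def symbol(self) -> str:
        return LAWN if self.lawn else SCORE_SYMBOLS[self.level]


def score_colony_count(count_or_lawn: int | str) -> GrowthScore:
    """Bin a colony count into its ordinal growth score.

    0 → "0"; 1–9 → "+"; 10–19 → "++"; 20–29 → "+++"; ≥30 → "++++";
    the string ``"LAWN"`` flags confluent growth.
    """
    if isinstance(count_or_lawn, str):
        if count_or_lawn.strip().upper() == LAWN:
            return GrowthScore(level=None, lawn=True)
        raise ValueError(f"unrecognised token {count_or_lawn!r} (expected a count or 'LAWN')")
    if isinstance(count_or_lawn, bool) or not isinstance(count_or_lawn, (int,)):
        raise ValueError(f"colony count must be a non-negative integer, got {count_or_lawn!r}")
    count = count_or_lawn
    if count < 0:
        raise ValueError(f"colony count must be non-negative, got {count}")
    if count == 0:
        level = 0
    elif count <= 9:
        level = 1
    elif count <= 19:
        level = 2
    elif count <= 29:
        level = 3
    else:
        level = 4
    return GrowthScore(level=level)


def _score_cell(value) -> GrowthScore:
    if isinstance(value, str) and value.strip().upper() != LAWN:
        value = int(value)
    return score_colony_count(value)


def call_top_hits(
    observations: pd.DataFrame,
    mating_annotations: Collection[str] = (),
    replicates_per_tester: int = 4,
) -> pd.DataFrame:
    """Call top-hit strains from per-well colony counts.

    ``observations`` needs columns ``strain_id``, ``tester`` (``MATa`` /
    ``MATalpha``), ``replicate_id`` and ``colony_count`` (integer or
    ``"LAWN"``).  A strain × tester pairing *qualifies* when all its
    replicates score "+++" or better; a pairing containing any lawn
    replicate is voided (it cannot qualify), and a strain lawn with both
    testers — or named in ``mating_annotations`` — is excluded outright.
    Calling does not depend on replicate or tester ordering, and raising
    any replicate's count never removes top-hit status.

    Returns one row per strain: per-tester score strings and sums, lawn and
    exclusion flags, the set of qualifying testers, and ``top_hit``.
    """
    required = {"strain_id", "tester", "replicate_id", "colony_count"}
    missing = required - set(observations.columns)
    if missing:
        raise ValueError(f"observations missing columns: {sorted(missing)}")
    bad_testers = set(observations["tester"]) - set(TESTERS)
    if bad_testers:
        raise ValueError(f"unknown testers {sorted(bad_testers)}; expected {TESTERS}")

    annotated = set(mating_annotations)
    rows = []
    for strain_id, strain_obs in observations.groupby("strain_id", sort=True):
        info: dict = {"strain_id": strain_id}
        lawn_by_tester: dict[str, bool] = {}
        qualifying: list[str] = []
        for tester in TESTERS:
            sub = strain_obs[strain_obs["tester"] == tester].sort_values("replicate_id")
            if len(sub) != replicates_per_tester:
                raise ValueError(
                    f"strain {strain_id}, tester {tester}: expected "
                    f"{replicates_per_tester} replicates, found {len(sub)}"
                )
            scores = [_score_cell(v) for v in sub["colony_count"]]
            n_lawn = sum(s.lawn for s in scores)
            lawn_by_tester[tester] = n_lawn > 0
            mixed = 0 < n_lawn < len(scores)
            levels = [s.level for s in scores if not s.lawn]
            col = tester.replace("MATalpha", "alpha").replace("MATa", "a")
            info[f"scores_{col}"] = ",".join(s.symbol for s in scores)
            info[f"sum_{col}"] = sum(levels) if n_lawn == 0 else pd.NA
            info[f"mixed_lawn_{col}"] = mixed
            if n_lawn == 0 and all(lv >= QUALIFYING_LEVEL for lv in levels):
                qualifying.append(tester)
        lawn_both = all(lawn_by_tester[t] for t in TESTERS)
        is_annotated = strain_id in annotated
        excluded = lawn_both or is_annotated
        info.update(
            lawn_both_testers=lawn_both,
            mating_annotated=is_annotated,
            qualifying_testers=",".join(qualifying),
            top_hit=bool(qualifying) and not excluded,
        )
        rows.append(info)
    return pd.DataFrame(rows)


def summarize_screen(calls: pd.DataFrame, n_screened: int) -> dict:
    """Hit count and genome fraction (percentage, 1 decimal) of a screen."""
    if n_screened <= 0:
        raise ValueError("n_screened must be positive")
    n_hits = int(calls["top_hit"].sum())
    if n_hits > n_screened:
        raise ValueError("more hits than strains screened")
    return {
        "n_hits": n_hits,
        "n_screened": int(n_screened),
        "percent_of_genome": round(100.0 * n_hits / n_screened, 1),
    }
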