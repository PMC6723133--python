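"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the *statistical* structure of a heterozygous
deletion-collection LOH screen, not its biology: 96-well mating-screen
plates with a ~2% false-positive growth rate and rare constitutive
lawn-growing strains; Poisson sector counts around a baseline of ~11;
gene maps with planted positional hit clusters; and per-culture
Luria-Delbruck mutant counts under the Lea-Coulson model.  Every
generator takes an explicit integer seed and is deterministic given it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .mat_screen import LAWN
from .pge import GeneLocus

__all__ = [
    "ScreenSimConfig",
    "GenomeSimConfig",
    "FluctuationSimConfig",
    "simulate_screen",
    "simulate_sectors",
    "simulate_genome",
    "simulate_fluctuation",
]

#: colony-count range sampled for each ordinal score level (lo, hi) inclusive
_LEVEL_COUNTS = {0: (0, 0), 1: (1, 9), 2: (10, 19), 3: (20, 29), 4: (30, 60)}


def _check_distribution(name: str, dist: Sequence[float]) -> np.ndarray:
    arr = np.asarray(dist, dtype=float)
    if arr.shape != (5,):
        raise ValueError(f"{name} must have 5 entries (levels 0..4)")
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError(f"{name} entries must lie in [0, 1]")
    if not np.isclose(arr.sum(), 1.0, atol=1e-9):
        raise ValueError(f"{name} must sum to 1 (got {arr.sum()})")
    return arr


@dataclass(frozen=True)
class ScreenSimConfig:
    """Mating-screen simulation parameters.

    Defaults mirror the screen being emulated: 4 replicates per tester, a
    ~2% chance a non-hit well shows any growth (never above "++"), and a
    lawn-strain fraction matching 14 such wells among 6477 strains.  True
    hits score "+++"/"++++" in nearly every replicate.
    """

    n_strains: int = 500
    n_hit_strains: int = 25
    hit_score_distribution: tuple[float, ...] = (0.0, 0.0, 0.005, 0.295, 0.7)
    background_score_distribution: tuple[float, ...] = (0.98, 0.016, 0.004, 0.0, 0.0)
    false_positive_rate: float = 0.02
    lawn_strain_fraction: float = 14 / 6477
    replicates_per_tester: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_hit_strains <= self.n_strains:
            raise ValueError("n_hit_strains must be in [0, n_strains]")
        _check_distribution("hit_score_distribution", self.hit_score_distribution)
        _check_distribution("background_score_distribution", self.background_score_distribution)
        for name in ("false_positive_rate", "lawn_strain_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.replicates_per_tester < 1:
            raise ValueError("replicates_per_tester must be >= 1")


@dataclass(frozen=True)
class GenomeSimConfig:
    """Toy genome layout with planted positional hit clusters.

    ``planted_clusters`` entries are (chromosome index, start gene ordinal,
    cluster size in genes, hits inside the cluster).
    """

    n_chromosomes: int = 4
    genes_per_chromosome: int = 100
    gene_length_bp: int = 1500
    intergenic_bp: int = 500
    planted_clusters: tuple[tuple[int, int, int, int], ...] = ()
    background_hits: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.genes_per_chromosome < 1:
            raise ValueError("need at least one chromosome and one gene")
        if self.gene_length_bp < 1 or self.intergenic_bp < 0:
            raise ValueError("invalid gene/intergenic lengths")
        if self.background_hits < 0:
            raise ValueError("background_hits must be non-negative")
        for chrom, start, size, hits in self.planted_clusters:
            if not 0 <= chrom < self.n_chromosomes:
                raise ValueError(f"cluster chromosome {chrom} out of range")
            if start < 0 or size < 1 or start + size > self.genes_per_chromosome:
                raise ValueError(
                    f"cluster [{start}, {start + size}) exceeds chromosome of "
                    f"{self.genes_per_chromosome} genes"
                )
            if not 0 <= hits <= size:
                raise ValueError("cluster hits must fit inside the cluster")


@dataclass(frozen=True)
class FluctuationSimConfig:
    """Lea-Coulson culture simulation: Poisson(m_true) mutation events per
    culture, clone sizes floor(1/U) truncated at the final population."""

    m_true: float = 2.0
    n_final: float = 1e8
    n_cultures: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m_true < 0:
            raise ValueError("m_true must be non-negative")
        if self.n_final < 1:
            raise ValueError("n_final must be at least 1")
        if self.n_cultures < 1:
            raise ValueError("n_cultures must be at least 1")


def _draw_count(level: int, rng: np.random.Generator) -> int:
    lo, hi = _LEVEL_COUNTS[level]
    return int(rng.integers(lo, hi + 1))


def simulate_screen(config: ScreenSimConfig) -> tuple[pd.DataFrame, list[str]]:
    """Simulate a plate-observation table plus its ground-truth hit list.

    Returns (observations, hit strain ids).  Lawn strains lawn with both
    testers in every replicate; hit strains draw per-replicate scores from
    the hit distribution with both testers; other strains are blank except
    for false-positive wells, which draw a nonzero background score.
    """
    rng = np.random.default_rng(config.seed)
    width = len(str(config.n_strains))
    strains = [f"strain{idx:0{width}d}" for idx in range(1, config.n_strains + 1)]
    lawn_mask = rng.random(config.n_strains) < config.lawn_strain_fraction
    non_lawn = [i for i in range(config.n_strains) if not lawn_mask[i]]
    n_hits = min(config.n_hit_strains, len(non_lawn))
    hit_idx = set(rng.choice(non_lawn, size=n_hits, replace=False).tolist())

    hit_dist = np.asarray(config.hit_score_distribution)
    bg = np.asarray(config.background_score_distribution)
    grow_mass = bg[1:].sum()
    bg_grow = bg[1:] / grow_mass if grow_mass > 0 else np.array([1.0, 0.0, 0.0, 0.0])

    records = []
    for i, strain in enumerate(strains):
        for tester in ("MATa", "MATalpha"):
            for rep in range(1, config.replicates_per_tester + 1):
                if lawn_mask[i]:
                    value: int | str = LAWN
                elif i in hit_idx:
                    level = int(rng.choice(5, p=hit_dist))
                    value = _draw_count(level, rng)
                elif rng.random() < config.false_positive_rate:
                    level = 1 + int(rng.choice(4, p=bg_grow))
                    value = _draw_count(level, rng)
                else:
                    value = 0
                records.append(
                    {"strain_id": strain, "tester": tester,
                     "replicate_id": f"r{rep}", "colony_count": value}
                )
    hits = sorted(strains[i] for i in hit_idx)
    return pd.DataFrame.from_records(records), hits


def simulate_sectors(
    lambda_per_strain: float | Sequence[float],
    n_strains: int | None = None,
    n_biological: int = 2,
    n_technical: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Poisson sector counts: n_biological x n_technical replicates per strain.

    ``lambda_per_strain`` is one mean for all strains (give ``n_strains``)
    or a per-strain sequence of means.
    """
    if np.isscalar(lambda_per_strain):
        if n_strains is None:
            raise ValueError("n_strains required when lambda_per_strain is scalar")
        lambdas = np.full(n_strains, float(lambda_per_strain))
    else:
        lambdas = np.asarray(lambda_per_strain, dtype=float)
    if np.any(lambdas < 0):
        raise ValueError("sector-count means must be non-negative")
    if n_biological < 1 or n_technical < 1:
        raise ValueError("replicate counts must be >= 1")
    rng = np.random.default_rng(seed)
    width = len(str(len(lambdas)))
    records = []
    for s, lam in enumerate(lambdas, start=1):
        for b in range(1, n_biological + 1):
            for t in range(1, n_technical + 1):
                records.append(
                    {"strain_id": f"strain{s:0{width}d}",
                     "replicate_id": f"b{b}t{t}",
                     "sector_count": int(rng.poisson(lam))}
                )
    return pd.DataFrame.from_records(records)


def simulate_genome(config: GenomeSimConfig) -> tuple[list[GeneLocus], list[str]]:
    """Lay out a toy genome and plant hit clusters.

    Genes are non-overlapping, evenly spaced, ordered by coordinate.
    Each planted cluster contributes exactly its configured number of hit
    genes (chosen within the cluster, always including its first and last
    gene when it has two or more hits, so the planted signal is contiguous
    in span); ``background_hits`` further hits are scattered uniformly over
    genes outside every cluster.  Total hits = background + sum of cluster
    hits; hit genes are unique by construction.
    """
    rng = np.random.default_rng(config.seed)
    loci: list[GeneLocus] = []
    ids: dict[tuple[int, int], str] = {}
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        for g in range(config.genes_per_chromosome):
            start = g * (config.gene_length_bp + config.intergenic_bp) + config.intergenic_bp + 1
            gene_id = f"g{c + 1:02d}_{g:04d}"
            ids[(c, g)] = gene_id
            loci.append(
                GeneLocus(gene_id, chrom, start, start + config.gene_length_bp - 1, index=g)
            )

    hits: list[str] = []
    clustered: set[tuple[int, int]] = set()
    for chrom, start, size, n_hits in config.planted_clusters:
        members = [(chrom, start + k) for k in range(size)]
        clustered.update(members)
        if n_hits == 0:
            continue
        if n_hits >= 2:
            chosen = {members[0], members[-1]}
            interior = [m for m in members[1:-1]]
            extra = rng.choice(len(interior), size=n_hits - 2, replace=False) if n_hits > 2 else []
            chosen.update(interior[k] for k in extra)
        else:
            chosen = {members[int(rng.integers(size))]}
        hits.extend(ids[m] for m in sorted(chosen))

    outside = [key for key in ids if key not in clustered]
    if config.background_hits > len(outside):
        raise ValueError("background_hits exceeds genes outside planted clusters")
    bg_pick = rng.choice(len(outside), size=config.background_hits, replace=False)
    hits.extend(ids[outside[k]] for k in bg_pick)
    return loci, sorted(set(hits))


def simulate_fluctuation(config: FluctuationSimConfig) -> np.ndarray:
    """Per-culture mutant counts under the Lea-Coulson model.

    Each culture draws M ~ Poisson(m_true) mutation events; each event's
    clone size is floor(1/U), U ~ Uniform(0,1), truncated at the final
    population size; the culture's count is the clone-size sum.
    """
    rng = np.random.default_rng(config.seed)
    counts = np.zeros(config.n_cultures, dtype=np.int64)
    for i in range(config.n_cultures):
        n_events = rng.poisson(config.m_true)
        if n_events == 0:
            continue
        u = rng.random(n_events)
        sizes = np.minimum(np.floor(1.0 / u), config.n_final).astype(np.int64)
        counts[i] = sizes.sum()
    return counts
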