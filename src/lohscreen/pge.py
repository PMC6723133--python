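"""Positional gene enrichment: chromosomal intervals over-represented in hits.

Genes that raise loss-of-heterozygosity rates when deleted sometimes cluster
along a chromosome — whether through shared local regulation, a single
driver gene with neighbourhood effects, or collection-construction
artifacts.  The scan asks, for every candidate interval of consecutive
genes, whether it holds more hit genes than a random scatter of the same
number of hits across the genome would.

Candidate intervals are *hit-delimited*: an interval is only worth scoring
if its first and last genes are both hits, since extending past a
terminal hit can only dilute the enrichment.  A chromosome with h hits
therefore contributes h*(h+1)/2 candidates.  Each candidate is scored with
the upper hypergeometric tail (region genes drawn from the genome, counting
hits), the family of candidates is corrected (Bonferroni by default, BH
optional), and significant regions with at least ``min_hits`` hits are
reported after collapsing any region that strictly contains a
no-less-significant sub-region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Collection, Literal, Sequence

from scipy.stats import hypergeom

from .go_enrichment import bh_adjust

__all__ = [
    "GeneLocus",
    "EnrichedRegion",
    "enumerate_candidate_regions",
    "score_region",
    "pge_scan",
]


@dataclass(frozen=True)
class GeneLocus:
    """One gene's position: 1-based inclusive coordinates.

    ``index`` is the ordinal rank of the gene along its chromosome, assigned
    by start coordinate.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    index: int = -1

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")


@dataclass(frozen=True)
class EnrichedRegion:
    """A reported interval: bp span, gene content, and raw/adjusted p."""

    chromosome: str
    bp_start: int
    bp_end: int
    orf_total: int
    hit_count: int
    hit_genes: tuple[str, ...]
    p_raw: float
    p_adj: float


def _order_loci(loci: Sequence[GeneLocus]) -> dict[str, list[GeneLocus]]:
    """Group by chromosome, sort by start, and (re)assign ordinal indices."""
    by_chrom: dict[str, list[GeneLocus]] = {}
    seen: set[str] = set()
    for locus in loci:
        if locus.gene_id in seen:
            raise ValueError(f"duplicate gene id {locus.gene_id}")
        seen.add(locus.gene_id)
        by_chrom.setdefault(locus.chromosome, []).append(locus)
    out = {}
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda g: (g.start, g.end, g.gene_id))
        out[chrom] = [
            GeneLocus(g.gene_id, g.chromosome, g.start, g.end, index=i)
            for i, g in enumerate(ordered)
        ]
    return out


def enumerate_candidate_regions(
    hits: Collection[str], loci: Sequence[GeneLocus]
) -> list[tuple[str, int, int]]:
    """All hit-delimited gene-ordinal intervals, as (chromosome, i, j).

    i and j are ordinal indices (inclusive) of the first and last gene;
    both must be hits.  Hits lacking coordinates are an error.
    """
    hit_set = set(hits)
    by_chrom = _order_loci(loci)
    known = {g.gene_id for genes in by_chrom.values() for g in genes}
    missing = sorted(hit_set - known)
    if missing:
        raise ValueError(f"hits without coordinates: {', '.join(missing)}")
    candidates: list[tuple[str, int, int]] = []
    for chrom, genes in by_chrom.items():
        hit_idx = [g.index for g in genes if g.gene_id in hit_set]
        for a in range(len(hit_idx)):
            for b in range(a, len(hit_idx)):
                candidates.append((chrom, hit_idx[a], hit_idx[b]))
    return candidates


def score_region(
    region: tuple[str, int, int],
    hits: Collection[str],
    loci: Sequence[GeneLocus],
) -> float:
    """Upper hypergeometric tail for one interval's hit content.

    p = P(X >= hits in region), X ~ Hypergeom(N=genes in genome,
    K=total hits, n=genes in region).
    """
    chrom, i, j = region
    hit_set = set(hits)
    by_chrom = _order_loci(loci)
    N = sum(len(g) for g in by_chrom.values())
    K = sum(1 for genes in by_chrom.values() for g in genes if g.gene_id in hit_set)
    genes = by_chrom[chrom][i : j + 1]
    if not genes:
        raise ValueError("empty region")
    n = len(genes)
    a = sum(1 for g in genes if g.gene_id in hit_set)
    return float(hypergeom.sf(a - 1, N, K, n))


def pge_scan(
    hits: Collection[str],
    loci: Sequence[GeneLocus],
    alpha_adj: float = 0.01,
    min_hits: int = 3,
    adjust: Literal["bonferroni", "bh"] = "bonferroni",
    collapse: bool = True,
) -> list[EnrichedRegion]:
    """Scan the genome for hit-enriched intervals.

    Scores every hit-delimited candidate, adjusts over the number of
    candidates tested, keeps regions with ``p_adj < alpha_adj`` and at
    least ``min_hits`` hit genes, and (unless ``collapse=False``) drops any
    kept region that strictly contains another kept region on the same
    chromosome whose adjusted p is no worse.  Reported spans run from the
    first gene's start to the last gene's end, 1-based inclusive.
    """
    hit_set = set(hits)
    by_chrom = _order_loci(loci)
    candidates = enumerate_candidate_regions(hit_set, loci)
    if not candidates:
        return []

    N = sum(len(g) for g in by_chrom.values())
    K = sum(1 for genes in by_chrom.values() for g in genes if g.gene_id in hit_set)
    m = len(candidates)

    raw: list[float] = []
    meta: list[tuple[int, int, tuple[str, ...]]] = []
    for chrom, i, j in candidates:
        genes = by_chrom[chrom][i : j + 1]
        region_hits = tuple(g.gene_id for g in genes if g.gene_id in hit_set)
        raw.append(float(hypergeom.sf(len(region_hits) - 1, N, K, len(genes))))
        meta.append((len(genes), len(region_hits), region_hits))

    if adjust == "bonferroni":
        adjusted = [min(1.0, p * m) for p in raw]
    elif adjust == "bh":
        # BH-adjusted p: smallest Q at which the step-up rule rejects.
        order = sorted(range(m), key=lambda i: raw[i])
        adjusted = [1.0] * m
        running = 1.0
        for rank in range(m, 0, -1):
            idx = order[rank - 1]
            running = min(running, raw[idx] * m / rank)
            adjusted[idx] = running
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")

    kept: list[EnrichedRegion] = []
    for (chrom, i, j), p_raw, p_adj, (n_genes, n_hits, region_hits) in zip(
        candidates, raw, adjusted, meta
    ):
        if p_adj < alpha_adj and n_hits >= min_hits:
            genes = by_chrom[chrom][i : j + 1]
            kept.append(
                EnrichedRegion(
                    chromosome=chrom,
                    bp_start=genes[0].start,
                    bp_end=genes[-1].end,
                    orf_total=n_genes,
                    hit_count=n_hits,
                    hit_genes=region_hits,
                    p_raw=p_raw,
                    p_adj=p_adj,
                )
            )

    if collapse:
        # Among nested significant regions keep only the best: a region is
        # dropped when another one nested with it (contained or containing)
        # has a better adjusted p (ties broken toward the smaller, then
        # leftmost, region).  Overlapping-but-not-nested regions both stay.
        def _key(r: EnrichedRegion) -> tuple:
            return (r.p_adj, r.orf_total, r.bp_start)

        def _nested(a: EnrichedRegion, b: EnrichedRegion) -> bool:
            return a.chromosome == b.chromosome and (
                (a.bp_start <= b.bp_start and b.bp_end <= a.bp_end)
                or (b.bp_start <= a.bp_start and a.bp_end <= b.bp_end)
            )

        kept = [
            r
            for r in kept
            if not any(s is not r and _nested(r, s) and _key(s) < _key(r) for s in kept)
        ]
    kept.sort(key=lambda r: (r.chromosome, r.bp_start, r.bp_end))
    return kept
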