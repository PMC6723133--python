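"""Positional gene enrichment scan vs brute-force all-interval oracles."""

import numpy as np
import pytest
from scipy.stats import hypergeom

from conftest import hypergeom_tail_exact
from lohscreen.pge import (
    GeneLocus,
    enumerate_candidate_regions,
    pge_scan,
    score_region,
)
from lohscreen.synthetic_data import GenomeSimConfig, simulate_genome


def toy_loci(n_genes: int, chromosome: str = "chr1", offset: int = 0) -> list[GeneLocus]:
    return [
        GeneLocus(f"{chromosome}_g{i}", chromosome, offset + i * 100 + 1, offset + i * 100 + 80)
        for i in range(n_genes)
    ]


def brute_force_scan(hits, loci, alpha_adj=0.01, min_hits=3):
    """Independent oracle: enumerate ALL O(G^2) intervals per chromosome,
    keep the hit-delimited ones, Bonferroni-adjust over that count, filter,
    and keep only the best region of every nested chain."""
    hit_set = set(hits)
    by_chrom = {}
    for g in loci:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for genes in by_chrom.values():
        genes.sort(key=lambda g: g.start)
    N = sum(len(g) for g in by_chrom.values())
    K = sum(g.gene_id in hit_set for genes in by_chrom.values() for g in genes)

    raw = []
    for chrom, genes in by_chrom.items():
        for i in range(len(genes)):
            for j in range(i, len(genes)):
                if genes[i].gene_id in hit_set and genes[j].gene_id in hit_set:
                    span = genes[i : j + 1]
                    a = sum(g.gene_id in hit_set for g in span)
                    p = float(hypergeom.sf(a - 1, N, K, len(span)))
                    raw.append((chrom, span[0].start, span[-1].end, len(span), a, p))
    m = len(raw)
    kept = [
        (chrom, s, e, n, a, p, min(1.0, p * m))
        for chrom, s, e, n, a, p in raw
        if min(1.0, p * m) < alpha_adj and a >= min_hits
    ]

    def nested(r1, r2):
        return r1[0] == r2[0] and (
            (r1[1] <= r2[1] and r2[2] <= r1[2]) or (r2[1] <= r1[1] and r1[2] <= r2[2])
        )

    def key(r):
        return (r[6], r[3], r[1])

    final = [r for r in kept if not any(s != r and nested(r, s) and key(s) < key(r) for s in kept)]
    return sorted((r[0], r[1], r[2], r[3], r[4], r[6]) for r in final)


class TestEnumerateCandidates:
    def test_no_hits_no_candidates(self):
        assert enumerate_candidate_regions([], toy_loci(10)) == []

    def test_three_hits_six_intervals(self):
        loci = toy_loci(10)
        hits = [loci[1].gene_id, loci[4].gene_id, loci[8].gene_id]
        assert len(enumerate_candidate_regions(hits, loci)) == 6

    def test_matches_bruteforce_filter_of_all_intervals(self):
        rng = np.random.default_rng(21)
        loci = toy_loci(50)
        hits = [loci[i].gene_id for i in rng.choice(50, size=7, replace=False)]
        candidates = set(enumerate_candidate_regions(hits, loci))
        hit_set = set(hits)
        brute = {
            ("chr1", i, j)
            for i in range(50)
            for j in range(i, 50)
            if loci[i].gene_id in hit_set and loci[j].gene_id in hit_set
        }
        assert candidates == brute

    def test_hit_without_coordinates_is_error(self):
        with pytest.raises(ValueError, match="phantom"):
            enumerate_candidate_regions(["phantom"], toy_loci(5))


class TestScoreRegion:
    def test_whole_genome_is_certain(self):
        loci = toy_loci(30)
        hits = [loci[0].gene_id, loci[29].gene_id]
        assert score_region(("chr1", 0, 29), hits, loci) == pytest.approx(1.0)

    def test_against_enumeration_oracle(self):
        loci = toy_loci(100)
        rng = np.random.default_rng(3)
        hit_ids = [loci[i].gene_id for i in sorted(rng.choice(100, size=10, replace=False))]
        # a 10-gene window containing 3 of the 10 hits
        idx = [int(h.split("_g")[1]) for h in hit_ids]
        i = idx[0]
        j = i + 9
        a = sum(1 for x in idx if i <= x <= j)
        p = score_region(("chr1", i, j), hit_ids, loci)
        oracle = hypergeom_tail_exact(a, 100, 10, 10, upper=True)
        assert p == pytest.approx(float(oracle), rel=1e-10)

    def test_zero_hit_region_is_one(self):
        loci = toy_loci(20)
        hits = [loci[0].gene_id, loci[19].gene_id]
        assert score_region(("chr1", 5, 10), hits, loci) == pytest.approx(1.0)

    def test_widening_without_new_hits_never_decreases_p(self):
        loci = toy_loci(40)
        hits = [loci[i].gene_id for i in (10, 12, 14)]
        p_prev = score_region(("chr1", 10, 14), hits, loci)
        for j in range(15, 40):
            p = score_region(("chr1", 10, j), hits, loci)
            assert p >= p_prev - 1e-12
            p_prev = p


class TestPgeScan:
    def test_no_hits_empty(self):
        assert pge_scan([], toy_loci(20)) == []

    def test_planted_cluster_reported_once(self):
        config = GenomeSimConfig(
            n_chromosomes=1, genes_per_chromosome=200, background_hits=3,
            planted_clusters=((0, 90, 5, 5),), seed=17,
        )
        loci, hits = simulate_genome(config)
        regions = pge_scan(hits, loci, alpha_adj=0.01, min_hits=3)
        assert len(regions) == 1
        region = regions[0]
        cluster_ids = {g.gene_id for g in sorted(loci, key=lambda g: g.start)[90:95]}
        planted = cluster_ids & set(hits)
        assert planted <= set(region.hit_genes)
        assert region.p_adj < 0.01

    def test_reported_p_raw_matches_direct_recomputation(self):
        config = GenomeSimConfig(
            n_chromosomes=2, genes_per_chromosome=100, background_hits=5,
            planted_clusters=((1, 30, 6, 5),), seed=23,
        )
        loci, hits = simulate_genome(config)
        by_chrom = {}
        for g in sorted(loci, key=lambda g: (g.chromosome, g.start)):
            by_chrom.setdefault(g.chromosome, []).append(g)
        for region in pge_scan(hits, loci, alpha_adj=0.05, min_hits=2):
            genes = by_chrom[region.chromosome]
            i = next(k for k, g in enumerate(genes) if g.start == region.bp_start)
            j = next(k for k, g in enumerate(genes) if g.end == region.bp_end)
            assert region.p_raw == pytest.approx(
                score_region((region.chromosome, i, j), hits, loci), rel=1e-12
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_oracle_on_random_genomes(self, seed):
        rng = np.random.default_rng(1000 + seed)
        loci = toy_loci(100)
        hits = [loci[i].gene_id for i in rng.choice(100, size=10, replace=False)]
        regions = pge_scan(hits, loci, alpha_adj=0.05, min_hits=2)
        got = sorted(
            (r.chromosome, r.bp_start, r.bp_end, r.orf_total, r.hit_count, r.p_adj)
            for r in regions
        )
        expected = brute_force_scan(hits, loci, alpha_adj=0.05, min_hits=2)
        assert [g[:5] for g in got] == [e[:5] for e in expected]
        assert np.allclose([g[5] for g in got], [e[5] for e in expected])

    def test_invariant_under_relabeling_and_chromosome_permutation(self):
        config = GenomeSimConfig(
            n_chromosomes=2, genes_per_chromosome=60, background_hits=4,
            planted_clusters=((0, 20, 5, 4),), seed=31,
        )
        loci, hits = simulate_genome(config)
        regions = pge_scan(hits, loci, alpha_adj=0.05, min_hits=2)

        relabel = {g.gene_id: f"renamed_{g.gene_id}" for g in loci}
        swap = {"chr1": "chrB", "chr2": "chrA"}
        loci2 = [
            GeneLocus(relabel[g.gene_id], swap[g.chromosome], g.start, g.end)
            for g in reversed(loci)
        ]
        hits2 = [relabel[h] for h in hits]
        regions2 = pge_scan(hits2, loci2, alpha_adj=0.05, min_hits=2)
        key1 = sorted((swap[r.chromosome], r.bp_start, r.bp_end, r.hit_count) for r in regions)
        key2 = sorted((r.chromosome, r.bp_start, r.bp_end, r.hit_count) for r in regions2)
        assert key1 == key2

    def test_uncollapsed_scan_is_superset(self):
        config = GenomeSimConfig(
            n_chromosomes=1, genes_per_chromosome=150, background_hits=2,
            planted_clusters=((0, 50, 6, 5),), seed=8,
        )
        loci, hits = simulate_genome(config)
        collapsed = pge_scan(hits, loci, alpha_adj=0.01, min_hits=3)
        full = pge_scan(hits, loci, alpha_adj=0.01, min_hits=3, collapse=False)
        keys = {(r.chromosome, r.bp_start, r.bp_end) for r in full}
        assert {(r.chromosome, r.bp_start, r.bp_end) for r in collapsed} <= keys
        assert len(full) >= len(collapsed)
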