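"""End-to-end pipeline: run configured stages and bundle a JSON summary.

Stage order mirrors the screen it models: primary mating screen, secondary
sectoring screen, screen-overlap statistics, GO enrichment, positional gene
enrichment, fluctuation analysis.  Stages absent from the configuration are
skipped without error; a failing stage aborts with an error naming it,
leaving earlier stages' outputs in place.  Every threshold applied is
logged to stderr and echoed into the output file headers.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import (
    fluctuation as fl,
    go_enrichment,
    io,
    mat_screen,
    met15_assay,
    overlap_stats,
    pge,
)

__all__ = ["run_pipeline", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1

log = logging.getLogger("lohscreen")


def _stage_screen(cfg: dict, outdir: Path) -> dict:
    observations = io.read_tsv(cfg["plates"])
    annotations = io.read_gene_list(cfg["annotations"]) if cfg.get("annotations") else []
    calls = mat_screen.call_top_hits(observations, annotations)
    n_screened = int(cfg.get("n_screened", calls["strain_id"].nunique()))
    summary = mat_screen.summarize_screen(calls, n_screened)
    log.info("screen: %d/%d top-hits (%.1f%%)", summary["n_hits"], n_screened,
             summary["percent_of_genome"])
    io.write_tsv(calls, outdir / "screen_calls.tsv", {"n_screened": n_screened})
    io.write_gene_list(calls.loc[calls["top_hit"], "strain_id"], outdir / "screen_hits.txt")
    return summary


def _stage_sectors(cfg: dict, outdir: Path) -> dict:
    counts = io.read_tsv(cfg["counts"])
    margin = int(cfg.get("margin", 2))
    if "threshold" in cfg:
        threshold = int(cfg["threshold"])
    else:
        control = io.read_tsv(cfg["control"])
        threshold = met15_assay.compute_threshold(control, margin=margin)
    log.info("sectors: threshold=%d (margin %d)", threshold, margin)
    calls = met15_assay.call_sector_positive(counts, threshold,
                                            strict=bool(cfg.get("strict", False)))
    io.write_tsv(calls, outdir / "sector_calls.tsv",
                 {"threshold": threshold, "margin": margin})
    n_pos = int((calls["call"] == "positive").sum())
    return {"threshold": threshold, "n_positive": n_pos,
            "n_not_assessable": int((calls["call"] == "NOT_ASSESSABLE").sum()),
            "n_strains": len(calls)}


def _stage_overlap(cfg: dict, outdir: Path) -> dict:
    hits1 = io.read_gene_list(cfg["hits1"])
    hits2 = io.read_gene_list(cfg["hits2"])
    background = io.read_gene_list(cfg["background"])
    result = overlap_stats.compare_screens(hits1, hits2, background)
    log.info("overlap: k=%d rf=%.2f p=%.3g (%s)", result.k, result.rf, result.p, result.tail)
    row = pd.DataFrame([{**asdict(result), "rf_1dp": result.rf_rounded()}])
    io.write_tsv(row, outdir / "overlap.tsv")
    return asdict(result)


def _stage_enrich(cfg: dict, outdir: Path) -> dict:
    hits = io.read_gene_list(cfg["hits"])
    background = io.read_gene_list(cfg["background"])
    ann_path = Path(cfg["annotations"])
    gene_terms = (io.read_gaf(ann_path) if ann_path.suffix.lower() == ".gaf"
                  else io.read_annotations(ann_path))
    q = float(cfg.get("q", 0.05))
    if cfg.get("slim") and cfg.get("hierarchy"):
        slim = set(io.read_gene_list(cfg["slim"]))
        hierarchy = io.read_hierarchy(cfg["hierarchy"])
        gene_terms = go_enrichment.slim_rollup(gene_terms, slim, hierarchy)
    term_genes: dict[str, set[str]] = {}
    for gene, terms in gene_terms.items():
        for term in terms:
            term_genes.setdefault(term, set()).add(gene)
    annotations = [go_enrichment.TermAnnotation(term, frozenset(genes))
                   for term, genes in sorted(term_genes.items())]
    results = go_enrichment.enrich_terms(hits, background, annotations, Q=q)
    log.info("enrich: %d terms, %d significant (Q=%g)", len(results),
             sum(r.significant for r in results), q)
    df = pd.DataFrame([vars(r) for r in results]).sort_values("p")
    io.write_tsv(df, outdir / "enrichment.tsv", {"Q": q})
    return {"n_terms": len(results), "n_significant": int(sum(r.significant for r in results)),
            "Q": q}


def _stage_pge(cfg: dict, outdir: Path) -> dict:
    hits = io.read_gene_list(cfg["hits"])
    loci = io.read_bed(cfg["loci"])
    alpha = float(cfg.get("alpha_adj", 0.01))
    min_hits = int(cfg.get("min_hits", 3))
    adjust = cfg.get("adjust", "bonferroni")
    regions = pge.pge_scan(hits, loci, alpha_adj=alpha, min_hits=min_hits,
                           adjust=adjust, collapse=not cfg.get("no_collapse", False))
    log.info("pge: %d enriched regions (alpha_adj=%g, min_hits=%d, %s)",
             len(regions), alpha, min_hits, adjust)
    df = pd.DataFrame([{**asdict(r), "hit_genes": ",".join(r.hit_genes)} for r in regions])
    io.write_tsv(df, outdir / "pge_regions.tsv",
                 {"alpha_adj": alpha, "min_hits": min_hits, "adjust": adjust})
    return {"n_regions": len(regions),
            "regions": [{"chromosome": r.chromosome, "bp_start": r.bp_start,
                         "bp_end": r.bp_end, "hit_count": r.hit_count,
                         "p_adj": r.p_adj} for r in regions]}


def _stage_fluctuation(cfg: dict, outdir: Path) -> dict:
    df = io.read_fluctuation_counts(cfg["counts"])
    alpha = float(cfg.get("alpha", 0.05))
    reference = cfg.get("reference")
    estimates: dict[str, fl.RateEstimate] = {}
    for strain_id, grp in df.groupby("strain_id", sort=True):
        exp = fl.FluctuationExperiment(
            strain_id=str(strain_id),
            counts=tuple(int(c) for c in grp["count"]),
            n_final=float(grp["n_final"].mean()),
        )
        estimates[str(strain_id)] = fl.estimate_rate(exp, alpha=alpha)
    rows = []
    ref = estimates.get(reference) if reference else None
    for strain_id, est in estimates.items():
        row = asdict(est)
        if ref is not None and strain_id != reference:
            cmp_res = fl.compare_to_reference(est, ref)
            row["fold_vs_reference"] = cmp_res.fold_change
            row["significant"] = cmp_res.significant
        else:
            row["fold_vs_reference"] = float("nan")
            row["significant"] = pd.NA
        rows.append(row)
    log.info("fluctuation: %d strains (reference=%s)", len(rows), reference)
    io.write_tsv(pd.DataFrame(rows), outdir / "fluctuation_rates.tsv",
                 {"alpha": alpha, "reference": reference})
    return {"n_strains": len(rows), "reference": reference,
            "rates": {s: e.rate for s, e in estimates.items()}}


_STAGES = [
    ("screen", _stage_screen),
    ("sectors", _stage_sectors),
    ("overlap", _stage_overlap),
    ("enrich", _stage_enrich),
    ("pge", _stage_pge),
    ("fluctuation", _stage_fluctuation),
]


def run_pipeline(config: dict, outdir: str | Path | None = None) -> dict:
    """Run every stage present in ``config``; write TSVs and summary.json.

    Returns the summary dict (also written to ``<outdir>/summary.json``).
    """
    outdir = Path(outdir if outdir is not None else config.get("output_dir", "."))
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"schema_version": SCHEMA_VERSION, "tool_version": io.tool_version(),
                     "stages": {}}
    for name, runner in _STAGES:
        if name not in config:
            continue
        start = time.perf_counter()
        try:
            summary["stages"][name] = runner(config[name], outdir)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        log.info("stage %s finished in %.2fs", name, time.perf_counter() - start)
    with (outdir / "summary.json").open("w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    return summary
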