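"""Gene Ontology term enrichment over screen hit lists.

Each term defines a 2x2 table (hit/non-hit x in-term/not-in-term) over the
screened background; over-representation is assessed with a one-sided
Fisher's exact test (equivalently, the upper hypergeometric tail), and the
family of term tests is controlled with the Benjamini-Hochberg step-up
procedure at FDR level Q.  A slim-rollup maps each gene's granular
annotations up a parent-term DAG onto a curated set of broad "slim" terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Collection, Iterable, Mapping, Sequence

import networkx as nx
from scipy.stats import binom, hypergeom

from .overlap_stats import overlap_pvalue

__all__ = [
    "TermAnnotation",
    "EnrichmentResult",
    "fisher_term_test",
    "binomial_term_test",
    "bh_adjust",
    "enrich_terms",
    "slim_rollup",
]

ASPECTS = ("process", "function", "component", "complex")


@dataclass(frozen=True)
class TermAnnotation:
    """A GO term with its annotated gene set.

    ``parents`` (immediate parent term ids) are only needed for slim rollup.
    """

    term_id: str
    genes: frozenset[str]
    aspect: str = "process"
    parents: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"term {self.term_id}: empty gene set")
        if self.aspect not in ASPECTS:
            raise ValueError(f"term {self.term_id}: unknown aspect {self.aspect!r}")


@dataclass
class EnrichmentResult:
    """One term's 2x2 counts, Fisher p, and BH decision.

    a = hits in term, b = hits not in term, c = background non-hits in
    term, d = background non-hits not in term.  ``significant`` is the
    step-up decision; ``significant_literal`` the literal per-rank
    ``p < rank/m*Q`` comparison, kept for transparency.
    """

    term_id: str
    a: int
    b: int
    c: int
    d: int
    p: float
    rank: int | None = None
    bh_critical: float | None = None
    significant: bool | None = None
    significant_literal: bool | None = None


def fisher_term_test(
    hits: Collection[str], background: Collection[str], term: TermAnnotation
) -> EnrichmentResult:
    """One-sided (enrichment) Fisher's exact test for a single term.

    p = P(X >= a) with X ~ Hypergeometric(N=|background|, K=|term∩bg|,
    n=|hits|).  A term disjoint from the background yields p = 1 with a
    warning.
    """
    bg = set(background)
    hit_set = set(hits)
    if not hit_set <= bg:
        raise ValueError("hits must be a subset of the background")
    term_bg = term.genes & bg
    N, n = len(bg), len(hit_set)
    K = len(term_bg)
    a = len(hit_set & term_bg)
    b = n - a
    c = K - a
    d = (N - n) - c
    if K == 0:
        warnings.warn(f"term {term.term_id} disjoint from background; p = 1", stacklevel=2)
        p = 1.0
    else:
        p = float(hypergeom.sf(a - 1, N, K, n))
    return EnrichmentResult(term_id=term.term_id, a=a, b=b, c=c, d=d, p=p)


def binomial_term_test(
    hits: Collection[str], background: Collection[str], term: TermAnnotation
) -> EnrichmentResult:
    """Binomial-tail alternative test statistic.

    Approximates the hit draw as n independent Bernoulli(K/N) trials:
    p = P(Bin(n, K/N) >= a).  Offered as an alternative; the Fisher test is
    the default.
    """
    res = fisher_term_test(hits, background, term)
    N = res.a + res.b + res.c + res.d
    K = res.a + res.c
    n = res.a + res.b
    if K:
        res.p = float(binom.sf(res.a - 1, n, K / N))
    return res


def bh_adjust(
    pvalues: Sequence[float], Q: float = 0.05
) -> tuple[list[float], list[bool], list[bool]]:
    """Benjamini-Hochberg step-up critical values and decisions.

    For m p-values sorted ascending, the rank-i critical value is
    ``i/m * Q``; the step-up rule rejects every hypothesis with rank at or
    below the largest rank whose p-value passes its critical value.  Returns
    (critical values, step-up flags, literal per-rank flags), all in the
    input order.  Ties in p share the more favourable decision because ranks
    follow a stable sort.
    """
    m = len(pvalues)
    if m == 0:
        return [], [], []
    if any(not (0.0 <= p <= 1.0) for p in pvalues):
        raise ValueError("p-values must lie in [0, 1]")
    order = sorted(range(m), key=lambda i: pvalues[i])
    criticals = [0.0] * m
    literal = [False] * m
    cutoff_rank = 0
    for rank, idx in enumerate(order, start=1):
        crit = rank / m * Q
        criticals[idx] = crit
        if pvalues[idx] <= crit:
            literal[idx] = True
            cutoff_rank = rank
    stepup = [False] * m
    for rank, idx in enumerate(order, start=1):
        stepup[idx] = rank <= cutoff_rank
    return criticals, stepup, literal


def enrich_terms(
    hits: Collection[str],
    background: Collection[str],
    terms: Iterable[TermAnnotation],
    Q: float = 0.05,
    statistic: str = "fisher",
) -> list[EnrichmentResult]:
    """Test every term and apply BH control across the family.

    Results come back in input term order with rank, critical value and
    both decision variants filled in.
    """
    test = {"fisher": fisher_term_test, "binomial": binomial_term_test}[statistic]
    results = [test(hits, background, t) for t in terms]
    criticals, stepup, literal = bh_adjust([r.p for r in results], Q=Q)
    order = sorted(range(len(results)), key=lambda i: results[i].p)
    ranks = {idx: rank for rank, idx in enumerate(order, start=1)}
    for i, r in enumerate(results):
        r.rank = ranks[i]
        r.bh_critical = criticals[i]
        r.significant = stepup[i]
        r.significant_literal = literal[i]
    return results


def slim_rollup(
    gene_terms: Mapping[str, Collection[str]],
    slim_terms: Collection[str],
    hierarchy: Mapping[str, Collection[str]],
    unknown_term: str | None = None,
) -> dict[str, set[str]]:
    """Map each gene's granular annotations onto a slim term set.

    A gene maps to every slim term that is an ancestor of (or equal to) any
    of its annotated terms under the child->parents ``hierarchy``.  A gene
    with an empty annotation set maps to ``unknown_term`` when one is
    given; an annotated gene with no slim ancestor is left unmapped.  Cycles
    in the hierarchy are an error naming the offending cycle.
    """
    dag = nx.DiGraph()
    for child, parents in hierarchy.items():
        for parent in parents:
            dag.add_edge(child, parent)
    try:
        cycle = nx.find_cycle(dag)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        path = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[-1][1]}"
        raise ValueError(f"hierarchy contains a cycle: {path}")

    slim = set(slim_terms)
    mapping: dict[str, set[str]] = {}
    for gene, terms in gene_terms.items():
        terms = set(terms)
        if not terms:
            mapping[gene] = {unknown_term} if unknown_term is not None else set()
            continue
        ancestors: set[str] = set(terms)
        for t in terms:
            if t in dag:
                ancestors |= nx.descendants(dag, t)  # edges point child -> parent
        mapping[gene] = ancestors & slim
    return mapping
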