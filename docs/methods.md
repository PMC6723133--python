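# Methods

## Growth scoring and top-hit calling (mat_screen)

Colony counts per pinned spot are binned into ordinal scores: 0 → "0",
1–9 → "+", 10–19 → "++", 20–29 → "+++", ≥30 → "++++". A count of exactly 30
is assigned "++++" so the bins are contiguous. A strain × tester pairing
qualifies when every one of its four replicates (2 biological × 2
technical) scores at least "+++"; this implies the summed score is ≥ 12,
and the sum is retained in the output for transparency. A strain is a
top-hit when at least one pairing qualifies and no exclusion applies.
Exclusions: lawn growth with *both* testers (growth without mating,
i.e. an inherent resistance genotype) or a user-supplied inherent-mating
annotation. A lawn with only one tester voids that pairing only — the
other tester's replicates can still qualify the strain. A pairing mixing
lawn and countable replicates is flagged (`mixed_lawn_*`) and voided.

The all-replicates rule is deliberately conservative: background
(false-positive) growth in control experiments tops out at "++", so a
strain can only qualify if every replicate clears the background ceiling.
On simulated screens with that background structure the caller has
specificity 1 by construction and sensitivity > 0.95 whenever true hits
place ≥ 0.99 probability on scores ≥ "+++".

## Sectoring assay (met15_assay)

The positivity threshold is `round_half_up(baseline) + margin`, where the
baseline is the pooled mean of all countable sector counts on a control
plate of non-hit strains (a per-strain-then-average variant is available;
both agree on balanced designs). The margin defaults to +2 sectors,
mirroring the +2-over-baseline convention of earlier unmagnified assays.
With a control plate averaging ~11 sectors the threshold is 13. Half-up
rounding (not banker's) keeps the threshold deterministic when the mean
lands exactly on .5.

A strain is positive when its mean over countable replicates is ≥ the
threshold; a strict mode instead requires every countable replicate to
reach it. Uncountable, fully-brown replicates are dropped from the mean
rather than imputed; a strain with no countable replicate at all is
reported NOT_ASSESSABLE rather than forced into either class.

## Overlap statistics (overlap_stats)

For hit lists of sizes n₁ and n₂ on a background of N screened genes, the
null overlap is hypergeometric: X ~ Hypergeom(N, n₁, n₂), E[X] = n₁n₂/N.
Reported are the representation factor rf = k/E[X] (rounded only at report
time) and a directional tail probability: P(X ≥ k) when k ≥ E[X], else
P(X ≤ k). Switching tails at the expectation makes the reported p the
probability of an outcome at least as extreme in the observed direction;
both tails include the observed atom, so p(upper) + p(lower) ≥ 1. The
exact tail (scipy's hypergeometric survival function; double precision
suffices — it agrees with exact rational enumeration to 10⁻¹⁰ across every
instance with N ≤ 25) is the default; a normal approximation with optional
continuity correction is provided for comparison but degrades far in the
tail. The background N is always an explicit argument, never inferred from
the lists: comparisons against screens of a different collection use the
intersection background (e.g. 5134 non-essential genes rather than all
6477), and both lists are restricted to it before counting.

## Term enrichment (go_enrichment)

Each term defines a 2×2 table over the background (hits × term
membership); over-representation is tested with the one-sided Fisher exact
test, i.e. the upper hypergeometric tail P(X ≥ a) — identical machinery to
the overlap tail, and cross-checked against it in tests. Only
over-representation is tested because depletion is not a meaningful screen
outcome here. The family of term tests is controlled by Benjamini–Hochberg
at Q = 0.05: rank-i critical value i/m·Q, step-up closure (every rank up
to the largest passing rank is rejected). The literal per-rank comparison
is also emitted, since the two differ exactly when a passing rank follows
a failing one. A binomial-tail test (n draws at rate K/N) is available as
an alternative statistic. Slim rollup maps each gene to every slim term
that is an ancestor-or-equal of any of its annotations, by transitive
closure over a child→parent DAG (cycles are rejected with the offending
path named); genes with empty annotation sets can be directed to an
aspect's "unknown" term.

## Positional gene enrichment (pge)

Candidate regions are intervals of consecutive genes whose first and last
genes are hits ("hit-delimited") — extending an interval past a terminal
hit only dilutes enrichment, so non-delimited intervals are never optimal.
A chromosome with h hits yields h(h+1)/2 candidates. Each candidate is
scored P(X ≥ a), X ~ Hypergeom(N genes, K hits, n region genes); adjusted
p-values are Bonferroni over the candidate count by default (BH
optional — Bonferroni is conservative and keeps the family-wise error of
the whole scan below the α threshold, which the false-positive control
test verifies empirically). Regions with p_adj < 0.01 and ≥ 3 hit genes
are reported after a nested-redundancy collapse: within any chain of
nested significant regions only the one with the best
(p_adj, size, position) key survives, so a planted cluster is reported
once rather than once per sub-interval. The full unfiltered list is
available (`collapse=False`), since both wide regions and their sharper
subsections can be of interest. Coordinates are read from BED (0-based
half-open) and reported 1-based inclusive, spanning the first gene's start
to the last gene's end. Strand is ignored — position is all that matters
here.

## Fluctuation analysis (fluctuation)

Model: Lea–Coulson, i.e. mutation events per culture M ~ Poisson(m), each
event founding a clone whose final size has P(S = s) = 1/(s(s+1)) (no
mutant fitness difference, complete plating). Partial plating and fitness
corrections are out of scope. The count pmf follows the Ma–Sandri–Sarkar
recursion p₀ = e⁻ᵐ, pₙ = (m/n) Σⱼ pⱼ/(n−j+1), computed with a vectorised
inner product (O(k²) total). The distribution's ~m/k² tail means partial
sums approach 1 only at rate m/k_max; the implementation truncates at the
largest observed count. Counts above 10⁴ are flagged as jackpots and
treated as right-censored — their likelihood contribution is P(X ≥ 10⁴)
rather than a point mass — which bounds the recursion cost without
discarding the observation.

m̂ maximises the log-likelihood by bounded Brent search (absolute
tolerance 10⁻⁶), started from the p₀-method value −ln(zero fraction)
(0.1 when no culture is empty), with automatic bracket widening. The 95%
CI is profile-likelihood: bounds solve 2[ℓ(m̂) − ℓ(m)] = χ²₁,₀.₉₅ = 3.841
by root bracketing, lower bound clipped at 0; with all-zero counts the
likelihood is e⁻ᶜᵐ and the interval is [0, 3.841/2C] in closed form. The
LOH rate is m̂/N_t with N_t the (mean) final population size — the
standard final-population normalisation. Two strains differ significantly
when their 95% rate CIs do not overlap; this CI-overlap rule (rather than
a two-sample likelihood-ratio test) is the decision rule of the assay
design this package supports, approximating a two-tailed test at p < 0.05.
Replicate experiments are pooled into one culture set by default;
per-replicate estimation is available by calling `estimate_rate` per
replicate.

Culture selection mimics the bench protocol: readings ≤ 0.5 OD are
discarded, and the 15 cultures closest to the median of the rest (ties by
input order) are kept.

Simulation checks (seeded, sizes chosen to balance statistical resolution
against runtime): MLE median bias within ±15% at m ∈ {0.5, 2, 8} with 15
cultures × 200 replicates; profile-CI coverage within 95% ± 3% over 500
replicates at m = 2; a 20× mutant called significant in ≥ 95 of 100 runs
of two pooled 15-culture replicates.

## Synthetic data (synthetic_data)

The generators reproduce the statistical structure the downstream analysis
assumes — not mating biology, growth kinetics, or recombination mechanism.
All take explicit integer seeds (numpy `default_rng`; no global state) and
are bit-reproducible.

- **Screen**: per strain × tester × 4 replicates. Hit strains draw
  per-replicate score levels from a distribution concentrated on
  "+++"/"++++" (default (0, 0, .005, .295, .7)); non-hit wells grow with
  probability 0.02 (the false-positive rate measured in the emulated
  screen's controls) and, when they grow, draw from a background
  distribution renormalised over nonzero levels whose mass stops at "++"
  (default (.98, .016, .004, 0, 0)). Score levels are converted to colony
  counts uniform within the level's bin (30–60 for "++++"). A fraction
  14/6477 of strains are constitutive lawn growers, lawning with both
  testers in every replicate. Not modelled: plate edge effects, spatial
  correlation, pinning failures — so passing tests say nothing about
  image-derived counts or plate normalisation.
- **Sectors**: i.i.d. Poisson(λ) counts per replicate, default λ
  around the observed baseline of ~11. Real sector counts are likely
  overdispersed; the Poisson choice makes the threshold derivation's
  sampling behaviour analytically checkable.
- **Genome**: evenly spaced non-overlapping genes (1.5 kb genes, 0.5 kb
  intergenic) on identical chromosomes, with planted clusters contributing
  an exact number of hit genes (cluster ends always hit when ≥ 2, so the
  planted span is hit-delimited) plus uniformly scattered background hits.
  Real gene-length and density variation is not emulated; the scan is
  position-rank based, so this mainly affects reported bp spans.
- **Fluctuation**: M ~ Poisson(m_true) events per culture; clone sizes
  floor(1/U) truncated at N_t — exactly the 1/(s(s+1)) law, so simulated
  counts follow the Ma–Sandri–Sarkar pmf by construction (verified by
  chi-square in tests).

## Numerical and interface choices

- TSV with header rows everywhere, "NA" for missing, UTF-8; every output
  file carries `#` header lines with the tool version and thresholds used.
- BED input is 0-based half-open; all internal and reported coordinates
  are 1-based inclusive.
- Rounding happens only at report time (representation factors to 1
  decimal, genome fractions to 1 decimal percentage).
- All stage randomness flows from explicit seeds; the pipeline re-run on
  the same config and inputs is bit-identical.

## Known limitations

- The GO machinery tests whatever annotation snapshot it is given; term
  p-values from any particular curated web tool are snapshot-dependent and
  not reproduced.
- The positional scan's enumeration + Bonferroni scheme is deliberately
  conservative and oracle-checkable; it is not a bit-for-bit reimplementation
  of any published region-scan web tool.
- Fluctuation estimation assumes complete plating and neutral mutants;
  rates for strains violating these assumptions will be biased.
- The screen caller takes counts as given: no plate normalisation,
  edge-effect correction, or image quantification.
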