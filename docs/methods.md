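# Methods

This note documents the models implemented in `varlinks`, the parameters
that matter, what the synthetic-data generator does and does not emulate,
and the numerical choices made where the design was genuinely open.

## Variant model and coordinates

A variant is a biallelic (ref, alt) pair at a 1-based position with a
minor allele frequency in [0, 0.5]; multi-allelic records are split at
load, and INDELs follow the VCF anchored-base convention. Intervals
(peaks, markers) are 0-based half-open, and a variant at position `p`
overlaps `[s, e)` iff `s ≤ p−1 < e`; the conversion happens only inside
overlap queries. For peak and marker overlap the variant is represented
by its anchored position alone, not its allele span — the annotation asks
where the locus sits, not what the allele does.

## Peak support

ChIP-seq experiments are grouped by experiment id with one interval track
per replicate. An experiment supports a variant only when every replicate
has a covering peak, which suppresses single-replicate noise at the cost
of sensitivity for experiments with weak replicates. Narrow- and
broad-peak experiments are counted separately and both reported; the same
all-replicates rule is applied to both kinds. Summary quantiles use
linear interpolation (numpy's default, type 7).

## Motif impact

Scoring uses log₂ odds against a uniform background (q = 0.25 per base,
configurable), with a pseudocount of 0.01 added per cell before column
normalization. `La` is the maximum placement score over all offsets and
both strands (ties: smallest offset, then + strand); `Lm` is the column
maximum sum. `N` bases contribute 0 (background); other ambiguity codes
are rejected at input.

The flanking window is 30 bp **per side** of the allele span, so every
placement of a motif up to 30 columns that overlaps the variant is
scoreable. Both alleles are scored on their own windows, and only the
best placement overlapping the variant site enters the retention
criteria: score floor 6 (TFBS) or 2 (RBP) on `La`, empirical p < 0.001,
normalized `La/Lm > 0.5` — each satisfiable by either allele. The floor
applies to the raw `La`, not the normalized ratio. RBP motifs are
evaluated only at UTR variants.

Empirical nulls are exact enumerations of all `4^L` sequences for motifs
up to 10 columns (computed by iterated outer sums, p-values are exact
tail ranks) and seeded background samples (default 100,000 draws) beyond
that, where the add-one estimator keeps p-values positive.

**Ratio normalization.** The raw `La/Lm` ratio of each result is divided
by the mean of (a) the grand mean of raw ratios across all
positive-scoring placements of the run and (b) the mean among motifs of
the same length. Both divisors are computed once per run (a two-pass
scan). This is one defensible reading of "normalized by the average and
the length-specific average of ratios"; it is isolated in
`RatioNormalization` so alternatives can be swapped.

**Classification.** With both alleles scoring positive, the relative
difference `|La_ref − La_alt| / max(La_ref, La_alt)` splits match
(< 10%) from change (≥ 10%); a positive score against a negative (or
absent) one is an addition or deletion; a motif match starting inside the
bases added by a small insertion is an addition unconditionally, with
"start" taken as the leftmost window coordinate of the placement on
either strand. Direction is the sign of the score difference.

## Genotype–transcript association

Ordinary least squares on the 7-column design (intercept, encoded
genotype, age, sex, PC1–3), vectorized across genes for each
(variant, model) since the design is fixed and only the response changes.
The per-class minimum (3) applies to the model-specific classes: three
classes for additive, two for dominant/recessive. Missing genotypes or
covariates drop the sample from that test only; constant design columns
(e.g. single-sex cohorts) are dropped with a warning and the residual
degrees of freedom adjust. P-values are two-tailed t-tests on β₁;
Benjamini–Hochberg correction (statsmodels) is applied per
(variant, model) across all tested genes — the most literal reading of
per-variant, per-model correction — and the retention threshold is
adjusted p < 0.005. Cis/trans labels use a 1 Mb window around the gene
span when gene loci are supplied.

## Similarity networks

Signed gene sets pool the three association models by default (a flag
restricts them); motif-derived sets aggregate motifs to their factor
symbol, keep only addition/deletion effects by default, and resolve
conflicting signs at one variant by the largest absolute score change.
Jaccard similarity treats (gene, +) and (gene, −) as distinct elements
and is undefined (excluded, logged) for empty sets. Edges exist iff
similarity > 0 and are weighted by it; an inverted element index keeps
construction proportional to the number of intersecting pairs, though the
profile statistics remain O(n²) in the worst case. Louvain (networkx)
runs on the non-isolated nodes with the similarity as edge weight and a
fixed seed; communities therefore partition the non-isolated node set.

LD pruning is greedy first-kept-wins in coordinate order within a 250 kb
window — an approximation of PLINK-style windowed pruning, not a clone.
r² is the squared Pearson correlation of dosages with pairwise deletion,
undefined for constant vectors.

## Variant–gene networks

Gene→variant "binding" edges are instantiated from retained motif-impact
results (change/addition/deletion by default); an association edge's sign
is the sign of β₁, a binding edge's sign the direction of the score
change. Closeness uses outgoing distances with Wasserman–Faust component
normalization — nodes with no outgoing reachability score 0 — which
reproduces the characteristic two-peak closeness profile (a zero peak for
nodes outside the strongly connected core). Betweenness is raw
(unnormalized) directed shortest-path betweenness.

**Degree-distribution model selection.** Discrete power law
(`k^−α / ζ(α, x_min)`, ML over α) versus discretized log-normal
(continuous CDF differences on integer bins, renormalized to the tail, ML
over μ, σ). Two numerical choices matter here. First, the comparison
defaults to the full positive-degree range (`x_min = 1`): a KS-estimated
tail start (available via `x_min=None`) discards the body of the
distribution, and on the tail alone the truncated log-normal family
collapses onto the power law (σ→∞ with μ/σ² fixed), making the
likelihood-ratio sign noise. Second, for the same reason μ and σ are
bounded to the identifiable region (μ ∈ [−10, 15], σ ∈ [0.05, 3] — far
wider than any realistic degree distribution), and the preferred model is
the sign of the Vuong log-likelihood ratio with Schwarz's correction for
the log-normal's extra parameter; the uncorrected ratio and its Vuong
p-value are reported alongside. Samples below 30 positive degrees, or
degenerate ones, return "inconclusive".

## Set enrichment

LD blocks are connected components of the pairwise r² graph above the
threshold (default 0.5) — the blocking algorithm was an open choice. The
observed statistic of an LD-pruned query is the mean over the 100
block-representative sets, compared against 100 MAF-matched random sets
(bin width 0.05, drawn without replacement per bin) with the add-one
empirical estimator `p = (r+1)/(n+1)`, which never returns zero and is
standard for permutation tests; with 100 random sets the smallest
achievable p is 1/101, just under the 0.01 decision threshold. Both
enrichment and depletion directions are computed; the reported direction
is the smaller-p side. The dual-factor analysis flags factors whose peak
and motif-alteration enrichment p-values are both below 0.01; pathway
enrichment of the flagged factors is out of scope — the factor list is
the output.

## Synthetic-data generator

The generator is the package's study-condition definition, a pure
function of its configuration (seed mandatory). Desk-scale defaults: 500
samples, 200 variants spaced 150 bp on one chromosome, 300 genes, 20
motifs, 30% motif disruptors, 3 planted 2-cycles, genotype effect size
1.0 on the normalized-expression scale with residual sd 0.5.

* **Genome and motifs.** Uniform background sequence; planted motifs are
  12–14 columns with near-invariant columns (consensus count 994 of
  1000). The length and concentration are an identifiability choice, not
  a claim about typical motifs: they make a planted single-base
  disruption unambiguous (the score drops ~9 bits, a ~35% relative
  change) while leaving chance background hits that satisfy all four
  retention criteria with expected count ≈ 0.01 per run, so the
  planted-truth contract (every disruptor recovered as a decreasing
  change/deletion, no retained impacts at neutral variants) is a property
  of the conditions rather than luck. Shorter or weaker motifs are
  exercised in the unit tests, not the planted fixture.
* **Genotypes.** Haplotype copying within consecutive blocks of 5
  variants sharing a block allele frequency from U(0.05, 0.5): each
  haplotype copies its left neighbour with probability 0.9, else redraws,
  giving adjacent dosage r² ≈ 0.8 decaying with distance; two independent
  haplotypes per individual give Hardy–Weinberg genotypes. This is
  copying, not coalescent simulation: it produces controllable LD but no
  recombination hotspots, allele-frequency spectrum or population
  structure.
* **Expression.** Gene baselines N(8, 1) on a log-like normalized scale,
  small random age/sex/PC coefficients per gene, Gaussian noise, and
  planted genotype effects on chosen (variant, gene, model) triples;
  ineligible draws (class counts below 3) are redrawn with a warning.
  Planted recessive effects with minimum-size homozygous classes are
  genuinely underpowered at the 0.005 adjusted threshold and may be
  missed — that is a property of the procedure, not a defect.
* **2-cycles.** Cycle variants are disruptors of a factor whose gene
  symbol is included among the expression genes and receives a planted
  additive association, so both network edges arise from the standard
  scans. Cycle variants are recorded as enhancer-marked on a 5% random
  marker background for the marker-enrichment analysis.

Passing tests on these fixtures demonstrate that the machinery recovers
known truth under clean conditions; they do not demonstrate robustness to
real-data features the generator omits (covariate–genotype confounding,
expression covariance beyond covariates, motif families with shared
binding cores, population stratification beyond three PCs).

## Problem sizes and determinism

The test suite and the acceptance script run the generator's default
sizes (200 variants × 20 motifs scanned per seed; 200 × 300 × 3
association triples; 500-replicate enrichment calibrations), chosen to
keep a full run in the order of a minute on one core while leaving every
statistical check comfortably powered. All randomness flows through
numpy Generators seeded from the configuration (child streams per stage),
and the pipeline is byte-identical across runs with the same seed —
checked by a dedicated test and by the acceptance script.

## Known limitations

* The motif-score normalization is one reading of an under-specified
  normalization scheme; results filtered at the 0.5 normalized-ratio
  threshold can shift if a different divisor is chosen.
* LD pruning is order-dependent (first-kept-wins); PLINK's
  variance-inflation pruning can keep a different representative set.
* The association model is OLS with fixed covariates — no kinship or
  mixed effects, no interaction terms between variants.
* Empirical enrichment p-values are bounded below by 1/(n_random+1);
  decisions at thresholds finer than that require more random sets.
* The bipartite network treats gene symbols as the join key between
  association and motif tables; symbol mismatches silently produce
  disconnected nodes rather than errors.
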