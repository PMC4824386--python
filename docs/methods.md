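# Methods

`clonerate` reconstructs the mutational history of a monoclonal cell
expansion from sequencing read counts. This note describes the models the
package implements, the defaults it ships with, what the synthetic data
generator does and does not emulate, and the numerical choices made where
the design was open.

## The expansion model

A single founder cell expands by strictly binary division for `G`
generations, producing `2^G` cells. Every daughter cell acquires a
Poisson-distributed number of new heterozygous single-nucleotide mutations
at birth, with mean `mu` (mutations per cell per division). No cell death
and no selection are modelled: a mutation born at division generation `n`
(`n = 1` is the founder's first division) is therefore carried by exactly
`2^-n` of the final cells, and — being heterozygous in a diploid genome —
by `2^-(n+1)` of template DNA molecules. Mutations present in the founder
itself (`n = 0`) are *clonal*: every cell carries them and their mutant
allele frequency (MAF) in the population sits near 0.5.

`simulate.simulate_expansion` materialises this genealogy cell by cell up
to 16 generations (a 2^17-node tree); larger expansions use
`simulate_expansion_counts`, which draws the number of generation-`n`
mutations as Poisson(`mu * 2^n`) — the superposition of the independent
daughter draws — and assigns carrier fractions analytically. The two paths
are equivalent in distribution for any site-level analysis; only the exact
path can answer questions about individual cells. `simulate_lineage_mutations`
generates the mutations carried by one sampled descendant (Poisson(`mu`)
per division along its ancestry), which is the relevant object when
candidate variants come from sequencing a clone line founded by one cell.

## Consensus error suppression

Amplicon read pairs are designed so both reads span the variant position.
`consensus.merge_pair` accepts a base call only when both reads report the
same base and the sum of their Phred qualities strictly exceeds 40, and
discards a pair outright when more than 10% of its doubly-called overlap
positions disagree. Both thresholds are strict inequalities and both are
configurable. Positions covered by a single read are excluded by default
(`include_flanks=True` re-admits them for coverage studies — they receive
no error suppression). Bases called `N` in either read are masked; a
masked position contributes nothing to downstream counts and is never a
guessed base.

The point of merging is quadratic error suppression: two independent reads
both report the same wrong base at a rate of about `3 (e/3)^2` when each
errs at rate `e` uniformly over the three wrong bases, so consensus error
is roughly `e^2/3` against `e` for a single read. The tests verify this
collision arithmetic by direct simulation.

## Sub-clonal calling

`subclonal.test_site` applies Pearson's chi-square to the 2x2 table of
(reference, mutant) read counts in the test population versus a matched
control, without Yates continuity correction by default (a flag enables
it; the choice is recorded in output metadata). Tables with a zero column
margin (no mutant reads anywhere) carry no evidence and are returned as
statistic 0, p 1, flagged degenerate. Family-wise error over a batch is
controlled by Bonferroni correction with the family equal to the sites
tested in the invocation — the batch composition is therefore explicit and
logged. A variant is *detected* only when the adjusted p falls below alpha
**and** the test population's MAF exceeds the control's; this direction
filter implements one-sided semantics over the two-sided test. Variants
are classified sub-clonal when MAF < 0.30 (strict), clonal otherwise.

## The Poisson molecule-sampling rate model

Deep amplicon sequencing assays `N` template molecules per locus (default
1,500: 5 ng of human genomic DNA is roughly 750 diploid genomes, i.e.
1,500 allele copies). The number of mutant molecules sampled for a
mutation of generation `n` is Poisson with mean

    lambda_n = N / 2^(n+1),

and the mutation is detectable iff at least one mutant molecule was
sampled, with probability `1 - exp(-lambda_n)`. Summing over the division
generations gives the detection factor

    F = sum_{n=1..G} (1 - exp(-lambda_n)),

the expected number of detectable sub-clonal mutations per unit mutation
rate when the rate is constant across generations. With `N = 1500` and
`G = 24`, `F = 9.88`. The clonal `n = 0` term (detection probability ~1)
is **excluded** by default: clonal mutations are identified separately as
the population-wide shared set, and only the `n >= 1` sum matches the
factor used in the worked example below; `include_clonal=True` exposes the
`n = 0..24` sum (10.88).

Given per-line detected sub-clonal counts `c_i` and the fraction `f_i` of
candidate sites each line actually assayed, the per-line rate is
`c_i / (f_i F)` and the summary is the mean and sample (n-1) standard
deviation across lines. The worked example — counts (60, 51, 58) with
assayed fractions (42.1%, 43.8%, 37.2%) — gives 14.0 ± 2.0 SNVs per cell
per generation. Per-line fractions (not a flat 40%) are the default
because they are what the assay actually achieved. The per-nucleotide
conversion divides by a diploid genome size of 6.6e9 bases by default;
the denominator is configurable and echoed in output. The number of
divisions implied by a final cell count is `round(log2(cells))`.

## Lineage reconstruction

Variant sharing across clone lines partitions variants into: *in-vivo
clonal* (present in every line and clonal in the bulk population, bulk MAF
within [0.4, 0.6] by default), *culture-shared* (present in two or more
but not all lines, or in all lines at sub-clonal bulk MAF), and *private*
(one line). A variant present in all lines with no bulk MAF measurement
cannot be confirmed clonal and is classed culture-shared.

MAF clustering uses a Dirichlet-process mixture of binomials: each variant
contributes its mutant read count and depth; the base measure is
Beta(1, 1) and the concentration 1.0 (both configurable). Inference is
collapsed Gibbs sampling (default 200 sweeps); the reported partition is
the most recent sampler state whose cluster count equals the posterior
mode over the second half of the chain. Because DP posteriors tend to
shave small transient clusters off a well-populated level, clusters whose
centres map to the same division-generation label (nearest `2^-(g+1)`)
are pooled by default — the generation structure, not the raw partition,
is the scientific output. A deterministic fallback (`model='em'`) fits a
finite binomial mixture by EM with centres fixed at the halving series.

Tree building maps each variant to its carrier set (the lines containing
it). If the carrier sets form a laminar family they define the genealogy
restricted to the sampled lines directly. Conflicting (overlapping,
non-nested) sets are resolved by maximum compatibility: distinct sets are
accepted greedily in decreasing order of supporting variants, and the
variants of rejected sets are reported as conflicts, never dropped. Edge
counts are minima — detection of sub-clonal variants is incomplete, so an
edge can only undercount. Trees serialise as newick with the edge count
in the branch-length slot.

## Mutational spectra and signatures

SNVs are classified into 96 channels by the substituted pyrimidine and its
flanking bases (purine-reference variants are reverse-complemented first);
channel order is substitution-class major, then 5'x3' context
lexicographic. Signature extraction is non-negative matrix factorisation
under the generalised Kullback-Leibler divergence — the natural objective
for count data — using Lee-Seung multiplicative updates, whose objective
is non-increasing at every iteration (asserted in tests). A Frobenius
mode is not provided; practitioners wanting other objectives can operate
on the exported catalog TSVs. Defaults: 50 random restarts, keep the
best objective, maximum 2,000 iterations, relative tolerance 1e-8.
Per-signature stability is the mean cosine similarity between each
best-run signature and its counterpart in every other restart, matched by
Hungarian assignment on the cosine matrix. The number of signatures `k`
is always chosen by the user; the stability-and-error report supports the
choice but no automatic selection is applied. Exposure attribution to
fixed signatures is non-negative least squares, reported as proportions.

## What the synthetic generator does and does not emulate

The generator reproduces the statistical structure the analysis assumes:
binary expansion with Poisson mutation accrual, Poisson sampling of
template molecules, binomial read sampling, uniform per-base substitution
error with constant Q30 qualities by default, and multinomial catalogs
from signature mixtures (a CpG-enriched C>T deamination-like process and
a context-uniform C>A process). It does not simulate cell death,
selection, passaging bottlenecks, PCR amplification bias or jackpots,
indels, copy-number change, strand-biased or position-dependent error,
quality miscalibration, or contamination. Passing tests therefore show
the inference is correct *under the model's own assumptions*; on real
data, PCR jackpots and systematic error would inflate low-frequency
counts in ways the chi-square control comparison only partially absorbs.

## Problem sizes and numerical choices

Simulation-based tests use deliberately moderate problem sizes — e.g. 20
replicates for end-to-end rate recovery, 60 replicate batches for the
family-wise error check at m = 1,000 sites, 3,000 read pairs for error
suppression — chosen so the full suite completes in well under a minute
on one core while keeping Monte-Carlo error small relative to the margins
tested (tolerances are set at 3-4 standard errors throughout). Degenerate
inputs follow one rule: impossible parameters raise `ValueError` eagerly;
uninformative but valid data (zero-depth sites, zero-margin tables,
empty spectra) return flagged results or explicit statuses rather than
raising mid-batch. All randomness flows from explicit integer seeds
through `numpy.random.default_rng`; no global state is touched.

## Known limitations

* The detection-factor model treats molecule sampling at different loci as
  independent Poisson draws and ignores PCR duplication of templates.
* The DP clustering reports a point partition, not posterior uncertainty
  over assignments.
* Tree edge counts are lower bounds and the greedy conflict resolution is
  not guaranteed optimal for adversarial sharing patterns (conflicts are
  always surfaced for inspection).
* NNMF restarts mitigate but cannot eliminate local optima; stability
  below ~0.9 for any signature should be treated as a warning that `k` or
  the data do not support the factorisation.
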