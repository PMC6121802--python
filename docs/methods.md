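# Methods

## The quantity being measured

`evoparallel` quantifies *parallel genetic evolution*: the tendency of
independently evolving populations to accumulate mutations in the same
genes.  Its input is the curated output of whole-population (pooled)
sequencing — one row per mutation per population with a population
frequency — as produced downstream of a polymorphism-mode variant caller
such as breseq.  Variant calling itself is out of scope; the pipeline
starts at the curated table.

The central object is the gene-level mutation-frequency profile
`n_ig`: the summed frequency of all qualifying mutations in gene `g` in
population `i`.  Mutations at different sites within one gene (including
its upstream promoter window) are added together, and `n_ig` may exceed 1
because competing lineages within one population can carry different
mutations in the same gene.

Genetic similarity between populations `i` and `j` is the Bray–Curtis
similarity applied to those profiles,

```
BC_ij = 1 − Σ_g |n_ig − n_jg| / Σ_g (n_ig + n_jg),
```

which is 0 when no mutated gene is shared and 1 when the same genes are
hit at identical frequencies.  Genes mutated in neither population do not
affect the value.  Jaccard similarity (presence/absence of mutated genes)
and Euclidean distance on the frequency vectors are provided as
sensitivity alternates; Euclidean results are reported as distances, with
the orientation recorded on the matrix object.

## Curation rules

Only mutations whose effect is attributable to a single gene enter the
profiles:

- runs of same-population, same-type single-base indels at consecutive
  positions with effectively equal frequency (tolerance 0.01 — pooled
  frequency estimates are noisy at the third decimal) are consolidated
  into one multi-base event at the run's first position, at the mean
  frequency of the run;
- synonymous mutations are excluded; nonsense and non-coding in-gene
  classes are retained;
- events spanning several genes are excluded;
- intergenic mutations are retained only when they fall in the
  strand-aware 150 bp window 5′ of exactly one gene's start (the likely
  promoter region); a position inside the upstream windows of two genes is
  ambiguous and excluded, and a position inside one gene takes priority
  over a neighbour's window;
- mutations below the detection/frequency floor (default 0.05; 0.10 for
  the sensitivity rerun) are excluded.

The `FilterReport` attributes each input row to exactly one bucket using
the fixed precedence order frequency → synonymous → multi-gene →
ambiguous → distal-intergenic, so the accounting always sums to the input
count regardless of how many filters a row fails.

## Randomization tests

All tests operate on the precomputed pairwise similarity matrix and
permute the population → treatment assignment, preserving group sizes.

- **Within vs. between.**  Statistic: `BC_within − BC_between`, where the
  two terms pool every within-treatment and every cross-treatment pair
  with equal weight (not a mean of treatment means — a single overall
  number per category).  One-sided p-value: when the number of distinct
  label arrangements is at most `n_permutations` the null is enumerated
  exhaustively and `p = #{null ≥ observed}/total` (the observed
  arrangement is a member of the null multiset, so p is never 0);
  otherwise arrangements are sampled and the add-one estimator
  `p = (1 + #{null ≥ observed})/(1 + n_permutations)` is used.  Permuted
  statistics within 1e-12 of the observed one count as ties toward
  rejection (conservative).
- **Treatment pairs.**  The same test restricted to two treatments'
  populations, run over all unordered treatment pairs and corrected with
  the sequential Bonferroni (Holm) step-down at family-wise α = 0.05.
  Holm is implemented directly — sort ascending, reject `p_(k)` iff
  `p_(j) ≤ α/(m − j + 1)` for all `j ≤ k` — because the exact step-down
  form is part of the pipeline's contract; tests cross-check it against
  statsmodels.
- **Shared selection pressure.**  Restricted to the four carbon × mode
  factorial treatments (the small-bead population-size control occupies
  the same factorial cell as the large-bead treatment and is excluded;
  when two treatments share a cell the one with `bead == "small"` is
  dropped).  Statistic: mean per-treatment-pair similarity over "edge"
  pairs (sharing exactly one factor) minus the mean over "diagonal" pairs
  (sharing neither).  The null permutes population → treatment labels, as
  above.  A coarser null — shuffling the four whole groups over the four
  cells — was considered and rejected: with four groups the edge/diagonal
  partition takes only three distinct values, so the smallest attainable
  p is 1/3 and the test could never resolve small p-values.

Sampled tests are reproducible given `(seed, n_permutations)`; exhaustive
results are seed-independent.

## Fitness and the similarity–fitness correlation

Competition assays against the ancestor yield a selection rate (per day):
the difference of the competitors' Malthusian parameters,
`[ln(evolved_d2/evolved_d0) − ln(ancestral_d2/ancestral_d0)] / duration`.
Zero means equal fitness; positive means the evolved competitor is
fitter.  Note an orientation subtlety: written with `d0/d2` ratios the
same expression flips sign while the verbal interpretation stays
"positive = evolved fitter"; the package defaults to the growth-oriented
form that matches the interpretation and exposes
`printed_orientation=True` for the sign-flipped variant.  Replicate
assays for one (population, environment) pair are averaged before any
correlation.

For each environment, a population's *similarity to that environment* is
its mean pairwise Bray–Curtis similarity to the populations evolved
there, excluding its own self-similarity when it is native.  The
association between this similarity and the selection rate measured in
that environment is Kendall's rank correlation (tau-b, tie-corrected —
similarity means tie at 0 frequently on sparse data), computed via scipy
with exact small-sample p-values where available; no linear relationship
is assumed.  A nonnative-only variant drops the environment's own
populations to show the correlation is not driven by native superiority.

## The synthetic-data generator

The generator emulates the statistical structure of a factorial
bead-transfer evolution experiment so every stage is testable without any
external download.  Defaults are the study conditions:

| parameter | default | meaning |
|---|---|---|
| treatments | 5 | carbon {high, low} × mode {biofilm, planktonic} + small-bead control |
| replicates | 6 per treatment, one large-bead replicate dropped → 29 usable |
| mutations/population | Poisson, mean 14.9 | curated calls incl. decoys |
| fixation probability | 51/352 | fraction of retained calls at frequency 1.0 |
| intermediate frequencies | uniform on [0.05, 0.95] | only the detection floor and the fixed/intermediate split are constrained by the data, so a maximally uninformative law is used |
| synonymous decoys | 55/432 of calls | exercise the synonymous filter |
| distal-intergenic decoys | 25/432 of calls | exercise the promoter-window filter |
| divergence d | 0.6 | pool-mixture weight, below |
| pool concentration | 1.5 | Zipf exponent for gene choice within a pool |
| fitness slope / intercept / noise | 2.5 / 0.5 / 0.15 per day | couples content to selection rate |
| colony target | 200 | Poisson plating depth for count noise |

Adaptive mutations hit genes drawn from nested pools: a global pool
(beneficial everywhere), one pool per factor level, and one private pool
per treatment.  The mixture weights interpolate smoothly in the
divergence parameter `d`: `w_private = d²`, `w_factor = 2d(1−d)` (split
equally between the carbon-level and mode pools), `w_global = (1−d)²`.
Thus `d = 0` is a single shared pool — an exchangeable null used for
type-I-error calibration — and `d = 1` is fully treatment-private
evolution with cross-treatment similarity exactly 0.  Within a pool,
genes are chosen with Zipf weights (exponent 1.5): real parallelism
concentrates in a few large-effect genes, and uniform choice produces
within-treatment similarities well below observed levels.  Two further
structural switches mirror the experiment: the low-carbon factor pool
splits into disjoint biofilm/planktonic halves (`low_carbon_tradeoff`),
reproducing the scenario where a shared selection pressure does not share
its genetic solutions, and the small-bead control draws from the same
private pool as the large-bead treatment (`bead_control_shares_pool`),
since the bead size changes the bottleneck, not the selective
environment.  One global-pool gene carries a promoter hotspot: its
upstream mutations always land 61 bp before the start codon, giving the
nucleotide-level parallelism summary a planted signal.

True selection rates are affine in a population's frequency-weighted
adaptive-content overlap with an environment's beneficial pools, plus
Gaussian noise; competition counts follow exactly (noise off) or with
Poisson colony-count noise at the plating depth (noise on, zero counts
redrawn).  With noise off the selection-rate computation inverts the
construction to 1e-9; at the default depth of ~200 colonies the mean
absolute recovery error is below 0.1/day.

What the generator does *not* emulate: linkage and clonal interference
through time, hitchhiking, sequence context (no reads or reference
sequence beyond coordinates), misalignment artifacts, or shared ancestry
between the marker-swapped founder clones.  Passing tests therefore
demonstrate correctness of the measurement and inference machinery under
the experiment's sampling structure, not robustness to variant-calling
error.

## Problem sizes and numerical choices

The calibration and power suites run at reduced but statistically
meaningful sizes chosen for a desk-scale run: type-I error uses 1000 null
datasets at 200 permutations per test with a 99% binomial acceptance band
around α = 0.05; power checks use 200 datasets at the default effect
sizes.  Default `n_permutations` is 10,000 for interactive use and
configurable upward (resolving p < 1e-5 needs ≥ 1e5).  Undefined
similarities (all-zero profiles) propagate as NaN and are excluded from
means rather than coerced to 0 or 1.  Ties in permutation statistics
count toward rejection.  All randomness flows from a single integer seed
through `numpy.random.default_rng`; identical configurations give
byte-identical outputs.

## Known limitations

- The headline similarity statistics of the original experiment can only
  be recomputed when its archived curated table is staged locally
  (`data/deposited/`); the repository itself ships no data.
- The shared-trait test requires a complete 2×2 factorial; incomplete
  designs raise rather than degrade.
- Operon-level collapsing requires an operon sidecar table; no operon
  inference is attempted.
- The competition-assay model ignores marker costs and frequency-
  dependent fitness within the assay.
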