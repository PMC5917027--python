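# Methods

## Scope and data model

The package analyses an aligned set of complete (or near-complete)
mitochondrial genomes partitioned into temporal groups — typically
*historical* (museum specimens with collection years spanning roughly a
century) and *modern* samples — for one or more taxa. Inputs are an aligned
FASTA, a TSV of per-sample metadata (taxon, era, collection year, optional
coordinates and range flag), a BED mask (used to remove the hypervariable
D-loop, which is assembly-error-prone in degraded material and excluded
from all analyses), and an optional gene annotation for variant
classification. Coordinates are 0-based half-open throughout (BED
convention). Both `N` and `-` count as missing, since consensus sequences
from museum material use either.

## Diversity statistics

All pairwise statistics use **pairwise deletion**: a site enters a pair's
comparison only when both sequences are resolved there. Per-site totals of
resolved-base counts make this O(nL) rather than O(n²L).

* Haplotype (gene) diversity: H<sub>d</sub> = n/(n−1)·(1 − Σp<sub>i</sub>²).
* Mean pairwise differences k̄, and π = (total pair differences)/(total
  pairwise-comparable sites), so missing data shrinks the denominator
  instead of deflating π.
* Tajima's D in the standard 1989 formulation from total S and k̄,
  explicitly *undefined* (an exception, not 0) for S = 0 or n < 4.
* Hudson-type F<sub>ST</sub> = 1 − H<sub>w</sub>/H<sub>b</sub> with
  H<sub>w</sub> the unweighted mean of the two within-group means and
  H<sub>b</sub> the between-group mean pairwise difference. Between-group
  pairs sharing a sample id are self-comparisons and are excluded, which
  makes F<sub>ST</sub> of a group against itself exactly 0 while keeping
  the estimator unbiased (mean ≈ 0) for two samples from one panmictic
  population. Raw (possibly negative) values are returned.

**Haplotype calling with missing data.** The default *compatible-merge*
rule assigns two sequences to one haplotype iff they show zero differences
over sites resolved in both, merged greedily with the most-complete
sequence of a cluster as its seed and deterministic (missing-count, id)
ordering. This avoids inflating the haplotype count through N-runs in
museum sequences. A *strict* mode (drop all columns containing any missing
base, then exact match) is provided, because published haplotype counts can
follow either convention; the two modes bracket the plausible range.
Private-haplotype counts between groups re-call haplotypes on the pooled
sequences so that the same merge rule decides sharing, guaranteeing
priv(A) + priv(B) + shared = pooled haplotype count.

**Variant classification** translates coding variants with the vertebrate
mitochondrial genetic code on a majority-consensus codon background
(either strand, arbitrary frame), flags stop-gains, and scores amino-acid
replacements with the PAM250 matrix (score ≥ 0 marking substitutions
commonly observed in nature). Triallelic sites are reported as
`multiallelic` and excluded from the Ts/Tv tally, so
Ts + Tv + multiallelic = S always.

**Minimum spanning networks** use ε = 0: Kruskal's algorithm processed in
(weight, label-pair) order, keeping every edge whose endpoints are in
different components at the start of its weight class — i.e. the union of
all minimum spanning trees, so tied alternative connections are retained.

## Permutation subsampling

Groups of very different size are compared by repeatedly (default 1000×)
subsampling each group *without replacement* to the smallest group's size
and recomputing the statistic. Subsets, not bootstrap resamples, because
the aim is "what would this group look like at the smaller n", and the
exhaustive-subset expectation is then the natural correctness oracle
(tested exactly for small n). Between-group differences are reported with a
Welch two-sample t-test for continuity with common practice, *and* with a
label-shuffling permutation p-value; the latter is the preferred
inferential quantity because resampling replicates of one group are not
independent observations, so the t-test's nominal degrees of freedom are
optimistic.

## Serial coalescent simulator

A haploid (maternally inherited, female-only) coalescent: N in all rate
computations is the number of breeding females. Lineages activate at their
sampling age — collection years converted to generations before the
reference year (default 2014) with a generation time of 20 years — and
while k lineages are active, coalescence occurs at rate k(k−1)/2 · 1/N(t)
per generation. N(t) is piecewise constant with one change at `t_change`
(prior: uniform 30–110 years before present), giving three model classes:
constant, decline (N_historical > N_present) and expansion. Waiting times
are exponential, re-drawn at epoch boundaries and activation times (valid
by memorylessness). Correctness is tested against closed forms: E[T₂] = N
for an isochronous pair, age + N for a heterochronous pair, the two-epoch
piecewise-exponential integral, and a cross-simulator check against
msprime's constant-size haploid coalescent (mean S, π, TMRCA).

**Mutation model.** Finite sites, K80-like: per-branch event counts are
Poisson(branch length · μ_gen · L), each event hits a uniform site, is a
transition with probability R/(R+1) (R = Ts/Tv bias, interpreted as the
expected transition:transversion *count* ratio) and otherwise a uniformly
chosen transversion; repeat hits are allowed and applied in time order
along each root-to-tip path; the root sequence is uniform random (no gamma
rate variation, symmetric base frequencies). The default rate 1.28×10⁻⁸ is
taken to be per site per **year** (mitogenome rates are usually calibrated
on time, not generations) and converted internally — 2.56×10⁻⁷ per site
per generation at 20 y/generation. Both the unit interpretation and the
Ts/Tv parameterization are configurable because conventions differ between
tools. Default Ts/Tv biases: 0.933 (Grauer's-like), 0.75 (mountain-like).

Two emission paths share identical RNG consumption per seed:
`simulate_dataset` writes full sequences; `simulate_site_matrix` returns
only the mutated columns (all variation lives there), which is what makes
10⁴–10⁵-row ABC reference tables affordable. Their agreement is tested.

## ABC

Eight summary statistics per dataset, in fixed order: haplotype count,
private-haplotype count and haplotype diversity for each temporal group,
plus mean between-group pairwise differences and F<sub>ST</sub>. Haplotype
diversity (not π) is the "genetic diversity" summary by default; π can be
swapped in via the resampling statistics if desired. F<sub>ST</sub> is
defined as 0 for totally monomorphic simulations so the vector stays
finite.

* **Priors:** log-uniform N on [10², 10⁵] per epoch (spans published
  great-ape female effective sizes without being informative), t_change
  uniform on [30, 110] years, equal model weights; decline/expansion order
  constraints enforced by redrawing.
* **Reference table:** equal rows per model, interleaved; each row consumes
  its own spawned seed stream, so tables are bit-identical for any worker
  count. Statistics are standardized by the whole-table SD (constant
  columns contribute zero distance).
* **Rejection:** Euclidean distance on standardized statistics; the
  ⌈proportion·rows⌉ closest rows are accepted, ties broken by row index.
  Model posteriors are accepted-row fractions, reported across 10
  acceptance proportions log-spaced on [5×10⁻⁵, 5×10⁻⁴] with a consistency
  range; model choice decisions use the median proportion.
* **Regression adjustment** (Beaumont-style local-linear): log-transformed
  parameters regressed on standardized statistics with Epanechnikov
  weights in distance; each draw moves to the fitted value at the observed
  statistics plus its residual, then back-transforms. Statistics that are
  constant across the accepted rows carry no local information and are
  dropped from the design (they would be collinear with the intercept); a
  genuinely singular fit falls back to the unadjusted rejection sample
  with a warning. Requires ≥ 30 accepted rows.
* **Estimation target:** the reduction factor N_historical/N_present,
  summarized by the posterior median and equal-tailed 95% interval.

Default problem sizes are deliberately modest — 30,000-row tables for model
choice and POD work, 1% acceptance for estimation — and configurable
upward; they are large enough that prior-predictive calibration (mean
model posterior ⅓ per model) and ≥ 85% empirical coverage of nominal-95%
intervals hold in the test suite.

## POD power analysis

Pseudo-observed datasets simulated at known truths are pushed through the
identical inference path. The default grid of true reduction factors
{1, 2.5, 4.5, 10} covers no-change through strong recent decline on the
study-like design; reported quantities are the fraction of PODs where the
true (or the decline) model wins at the median acceptance proportion, the
mean true-model posterior, 95%-CI coverage of the true ratio, and the
median absolute log-ratio error. Power to detect a ≤ 10× decline over
30–110 years from mtDNA alone is intrinsically low — a century is a small
number of generations and a single locus carries few coalescences in that
window — so the meaningful checks are calibration and monotonicity of
power in effect size, not high absolute power.

## Synthetic data

The built-in designs emulate the two study-like group structures on 15 kb
sequences (≈ mitogenome minus D-loop): Grauer's-like, 68 historical samples
with collection years 1910–1980 plus 29 modern samples from 2014; and
mountain-like, 18 historical (1913–1956) plus 8 modern. Historical
collection years are drawn uniformly within the range (explicit per-sample
years can be supplied); a full-length 16.2 kb variant with a 1.2 kb
D-loop interval exercises the masking path. The generator reproduces the
*sampling structure and neutral genealogical signal* of such data; it does
not simulate sequencing error, DNA damage, contamination or capture bias,
so passing tests demonstrate correctness of the statistics and inference
machinery, not robustness to laboratory artefacts. Missing data can be
planted as N-runs at chosen per-sample fractions to exercise the
missing-data paths.

Hand-checkable toy fixtures (a Tajima's-D n=4 alignment with D ≈ −0.710, a
fixed-difference F_ST = 1 pair of groups, a {2,1,1} haplotype-diversity
fixture, a missing-data trio, a monomorphic alignment) ship with frozen
truth values and are verified by the pipeline itself in the tests.

## Numerical and reproducibility choices

* All randomness flows through `numpy.random.Generator`; every stochastic
  entry point takes a seed, and nested experiments spawn child
  `SeedSequence` streams, so results are bit-reproducible including under
  multi-worker table builds.
* Undefined statistics raise (`UndefinedStatistic`) rather than returning
  sentinel numbers; table-level wrappers convert them to NaN for display.
* Degenerate inputs: full-length masks, empty alignments, all-missing
  sequences and over-large subsample sizes are rejected with specific
  errors; monomorphic ABC simulations produce finite statistics.

## Known limitations

* Single non-recombining locus; no selection, no population structure, no
  migration. Temporal comparisons inherit mtDNA's single-marker variance.
* The t-test on subsampled statistics is reported for convention but its
  replicates are dependent; use the permutation p-value.
* Finite-sites repeat hits make the simulator's S slightly sub-linear in
  branch length at high θ; at the default mitogenome-scale θ the effect is
  negligible (and the calibration tests pass against infinite-sites
  expectations).
* The compatible-merge haplotype rule is greedy; pathological missing-data
  patterns could make cluster membership order-dependent beyond the
  deterministic ordering chosen.
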