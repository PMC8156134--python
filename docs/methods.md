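# Methods

This note records the models, parameter choices and numerical conventions
behind `rpfam`, and what the synthetic benchmarks do and do not demonstrate
about real data.

## Normalization

RPKM for gene *g* in library *l* is `1e6 · c_gl / N_l · 1e3 / L_g` with
`c_gl` the raw count, `N_l` the library's total mapped reads and `L_g` the
cDNA (exonic) length in bp.  Two conventions matter:

* **Total mapped reads.**  `N_l` defaults to the count-matrix column sum,
  which is correct when the matrix covers the whole counted transcriptome.
  When the matrix is restricted to the RP panel, the whole-transcriptome
  totals must be supplied as a sidecar — the relative levels of the
  stoichiometry analysis are invariant to this choice (any per-sample factor
  cancels), but absolute RPKM values are not.
* **Order of operations.**  RPKM is computed per library first and replicate
  columns are then averaged arithmetically.  Averaging pooled counts first
  gives a different answer whenever replicate totals differ; the per-library
  order is asserted by a test.

Gene length is exonic length (sum of `end − start + 1` over the exons of the
longest annotated mRNA, GFF3 coordinates being 1-based inclusive), not
genomic span.  log₂ transformation uses a configurable pseudocount
(default 1) because tissue-specific genes have exact zeros.  Quartiles in
expression summaries use linear interpolation (numpy default, R type 7).

## Family stoichiometry

Family expression is the plain sum of member RPKM (pseudogenes excluded).
The relative level divides each family's sum by the per-sample median over
all families, so the median family sits at exactly 1 (odd family counts) and
any per-sample scaling cancels.  Flags use strict inequalities — `low`
below 0.5, `high` above 2, boundary values unflagged — and are a pure
function of the replicate-averaged relative level.  Significance is a
two-sided one-sample t-test of replicate-wise relative levels (each library
normalized against its own family median) against the threshold the mean
crosses; with n = 2 replicates this test is intentionally weak (mean 2.5,
SD 0.14 against threshold 2 gives t = 5 on one degree of freedom yet
p ≈ 0.126), which is why flags are threshold-based and p-values are reported
alongside rather than used for flagging.  Benjamini–Hochberg adjusted
p-values are emitted in a separate column for transparency and never drive
any decision.  Degenerate zero-variance replicates yield p = 1 on the
threshold and p → 0 otherwise.

## Clustering

Gene and sample trees use complete linkage on Euclidean distances of
log₂(RPKM); complete linkage guarantees monotone merge heights, asserted on
every run, and the implementation is checked against an exhaustive
brute-force agglomerator for all panels of n ≤ 7.  Tie-breaking among equal
inter-cluster distances follows the linkage implementation's deterministic
order; random expression matrices have no exact ties.  Newick exports carry
branch lengths equal to merge-height differences (leaves at height 0).
Zero-variance genes are retained for distance-based clustering but rejected
by the Pearson sample-correlation matrix, which requires positive variance.
Heatmap rendering (black→yellow) is an optional thin layer; every
quantitative assertion runs on the leaf-ordered TSV.

## Trend analysis

Profiles are standardized per gene to mean 0 and sample SD 1 (ddof = 1);
constant profiles become zero rows and are flagged rather than fatal.
Fuzzy c-means minimises `J = Σ_ij u_ij^m ‖x_i − c_j‖²` by alternating the
standard membership (`u_ij ∝ d_ij^(−2/(m−1))`) and weighted-mean center
updates.  Numerical choices:

* k = 6 clusters and fuzzifier m = 2.0 by default (the conventional choice
  in the soft-clustering literature); convergence when the objective changes
  by < 1e-9, cap 300 iterations.
* Initialization draws k distinct data points as centers.  Initializing
  from near-uniform random memberships places every center at the global
  mean — a degenerate fixed point of the update equations in which
  memberships stay uniform — so point-seeded starts are essential.
* 10 seeded starts; lowest final objective wins, ties by lowest start
  index.  A profile coinciding exactly with a center receives full
  membership there (standard singularity rule).  At m → 1⁺ the hard labels
  coincide with k-means on separated data, which is tested at m = 1.05.

Paralogue pattern calls use raw RPKM profiles, not z-scores: Pearson r is
already location- and scale-invariant, which encodes the biological notion
that concerted paralogues may differ in level while matching in trend.
Within each developmental series a member is *expressed* if its maximum
RPKM reaches the expression floor (default 1 RPKM); a family is `similar`
iff every pairwise r among expressed members reaches the r-threshold
(default 0.5) in every evaluated series, `different` otherwise and
`insufficient_data` if no series has two expressed members.  Series shorter
than 5 sample groups are not evaluated for correlation — r over 3 points is
dominated by noise — though their groups still contribute to clustering and
summaries.  The 0.5 threshold and 1-RPKM floor are judgment calls exposed
as parameters; there is no canonical numeric criterion for
concerted-versus-contrasting in the literature, so these calls should be
read as a reproducible formalization rather than a gold standard.

## Synthetic panels

The generator emulates the structure of a deep developmental RNA-seq atlas
of the Arabidopsis RP complement: 81 families of 2–7 paralogues, 79 sample
groups × 2 replicates, library size 5 × 10⁶ mapped reads.  Expression is
composed multiplicatively from

* a family scale factor, log-normal σ = 0.12 around a family-sum base of
  120 RPKM (keeping baseline families comfortably inside the (0.5, 2)
  stoichiometry band);
* a family trend drawn from six archetypes — rising, falling, early/late
  peak and their mirror-image valleys — normalized to mean 1 with extreme
  deviation ±0.45 and evaluated *within* each developmental series, so each
  series traverses the full dynamic.  The archetypes form mirrored pairs,
  which pins the per-group median family at the base level and makes
  "baseline" a genuinely stoichiometric truth label;
* a shared per-tissue factor (log-normal σ = 0.05) that cancels from all
  ratio statistics;
* fixed Dirichlet (α = 5) member proportions splitting each family sum.

Planted scenarios override the baseline: `concerted` members share the
family trend at different scales; `contrasting` assigns the second member
the mirrored trend (Pearson r ≈ −0.9 on expectations after tissue-factor
jitter); `tissue_specific` silences one member outside a small group
subset; `substoichiometric`/`superfluous` pin the family sum to a target
ratio times the per-group median of the other families.  Counts are
negative-binomial (variance = μ + φμ²) around expected counts obtained by
inverting the RPKM formula and renormalizing each library to the target
size; φ = 0.005 by default, i.e. ~7% replicate CV, matching the very high
replicate concordance of pooled-tissue developmental atlases (dispersion is
a free parameter of the generator, not a calibrated estimate for any
specific dataset).  φ → 0 recovers the Poisson limit, which is tested via
variance/mean ratios.  Optional background genes at 8% of the RP base level
reproduce the high relative expression of RP genes.

What the synthetic benchmarks show: the pipeline recovers planted
stoichiometry ratios, trend archetypes and concerted/contrasting labels
essentially perfectly under the generator's assumptions, and the whole run
is byte-deterministic under a fixed seed.  What they do not show: real
atlases have batch structure, GC/length biases, unbalanced replicate
depths, families whose trends do not fall into six smooth archetypes, and
tissue factors that dominate family-relative variation — none of which the
generator models.  Recovery rates on real data will be lower, and the
planted-truth tests should be read as correctness checks of the statistics,
not as power estimates.

## Problem sizes

Default simulations run the full study scale (81 families, ~380 genes,
158 libraries) in a few seconds; the test suite and the acceptance script
use this scale directly, with smaller panels (20–30 families, 24 groups)
for shared fixtures where the full scale adds nothing.

## Packaged fixtures

The packaged gene catalogue and sample panel are *synthetic stand-ins*
(marked `.synthetic.tsv`) that mirror the published structure of the
Arabidopsis RP complement — 256 catalogued genes of which 240 are
non-pseudogenes, 81 families, RPS15 with members A–F, 79 sample groups × 2
replicates with the four named developmental series — but carry invented
locus identifiers and lengths.  Analyses of real Arabidopsis data should
supply the published catalogue as the gene-map TSV.

## Limitations

* The t-test at n = 2 replicates has almost no power; it is included for
  fidelity to the replicate-resolved workflow, not as a recommended test.
* Pattern calls depend on the r-threshold/floor choices; sensitivity should
  be checked by re-running `rpfam patterns` with different values.
* Fuzzy c-means is a local optimizer; 10 starts suffice for the panel sizes
  here but very large panels may need more.
* RPKM is retained for fidelity to the family-ratio workflow; it is not a
  recommended unit for cross-dataset comparison (TPM-style alternatives are
  out of scope).
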