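# Methods

This note records the models, estimators, numerical choices and known
limitations behind `rhizovar`, and what the synthetic-data generator does
and does not emulate.

## The experimental design being modelled

The package targets crossed factorial field designs of the kind used in
long-term crop-rotation studies: 2 years × 3 months (June, August,
September) × 2 blocks × 4 plots (continuous maize `M`, continuous soybean
`S`, and the two rotation phases `MS`, `SM`) × 2 nitrogen regimes
(standard fertilization vs none) × 2 soil compartments (rhizosphere,
bulk) × 2 subsamples = 384 samples.  Host species is a derived factor:
`M`/`S` plots carry their crop every year, `MS` carries maize in year 1
and alternates, `SM` the reverse.  The phase convention is configurable
(`rhizovar.io.DEFAULT_ROTATION_PHASE`) and recorded in output
provenance, because a design table alone cannot distinguish the two
phases.  All analyses run separately per compartment.

## Variance partitioning

### Model and estimator

Per ASV, `log((c_ij + pseudo) / sum_j (c_ij + pseudo))` is the response
(`pseudo` defaults to 1, the same pseudocount the differential-abundance
stage uses) and every design factor enters as a random intercept.  The
variance components are estimated by EM-REML.  The estimator was chosen
over alternatives because (a) it keeps every component nonnegative by
construction, with no post-hoc truncation, and (b) it is generic over
crossed designs.  On balanced one-way layouts it reproduces the
closed-form ANOVA estimator to ~1e-12, and on a crossed 48-sample
fixture it matches `lme4::lmer(..., REML=TRUE)` components to ~1e-5
(the residual difference is the two optimizers' stopping rules).

Implementation: the mixed-model covariance is inverted through the
Woodbury identity in the column space of the stacked random-effect
design (15 columns for the seven default factors), so each EM iteration
costs a 15×15 solve regardless of sample count.

### Convergence and the zero boundary

Plain EM approaches a zero component only harmonically (the step size
shrinks like the square of the component), so no per-component relative
criterion can terminate.  Convergence is therefore declared when the
largest absolute component change per iteration falls below 1e-8 of the
total variance, and every 20 iterations any component below 3% of the
total is tested against the boundary: it is fixed at exactly zero only
if doing so does not lower the restricted likelihood (guard 1e-10).
This is acceleration, not approximation — the fixed point is unchanged —
and brings typical fits from >500 to ~30–120 iterations.  Fits that
still fail to converge within `max_iter` (default 500) are returned
flagged, never dropped.

### Scores, tallies, compartment comparison

The variance score of a factor is its component divided by the total
(components + residual), so scores sum to 1 with the residual share.
"Responsive" ASVs have score strictly above a threshold (default 5%;
2.5%, 10% and 20% are also standard).  Responsive counts in two
compartments are compared as a 2×2 table with Pearson's chi-square and
Yates continuity correction (df = 1).  On published count tables this
reproduces the printed p-values (3.6e-14 for 539/2,225 vs 300/2,014;
0.03267 for 71 vs 42).

## Subgenus functional-group discovery

The discovery rule operationalizes "inspect the tree next to the score
plot":

1. per genus with ≥ `min_asvs` (5) profiled ASVs, fit diagonal-covariance
   Gaussian mixtures with K = 1..3 to the selected score vectors
   (defaults: host species and nitrogen, the two factors that
   biologically motivate subgenus structure);
2. select K by BIC **among K whose clusters pass the size
   (`min_cluster_size` = 3) and separation (`min_separation` = 0.05 in
   some coordinate) checks**;
3. accept the split only if each cluster occupies at most
   `max_components` (2) connected components of the genus subtree under
   a Fitch minimal-change labelling (ties broken toward the parent
   label, smallest label at the root); otherwise the genus stays whole
   with decision `rejected_incoherent`.

Two numerical choices matter.  The mixture variance floor (`reg_covar`)
is 1e-3: scores live on [0,1], and with a near-zero floor a degenerate
near-singleton cluster wins the BIC at small n, which is why selection
also skips inadmissible K rather than forcing K = 1 the moment the raw
BIC winner fails a check.  Cluster labels `_S1, _S2, …` are ordered by
decreasing total read count.

Component counting per label: a "birth" edge (parent label differs,
node label matches) opens a component; the root opens one for its own
label.  This tolerates a single misplaced leaf (it adds one component)
while rejecting score patterns interleaved across the tree.

### Measured power

On full synthetic surveys (60 genera, ~2,250 ASVs, subgroups planted in
the 12 most abundant genera with ≥ 20 ASVs, species-score contrast
0.45 vs 0.03, low-abundance curation at 1,000 total reads), the
procedure recovers 10–12 of 12 planted genera across seeds with **zero
spurious splits** and mean membership ARI 0.83–0.97.  Power is limited
by the sampling noise of variance scores — a 2-level factor's component
rests on essentially one degree of freedom — and by count-level
attenuation of low-abundance ASVs; both are properties of the data, not
the rule.  On the direct score fixture (29 + 28 ASVs, scores drawn
N(0.45, 0.05²) vs N(0.03, 0.02²) on two sister clades) detection is
exact (ARI 1.0) while 97%-identity clustering returns a single OTU.

### OTU comparator

De novo greedy centroid clustering: ASVs in decreasing-abundance order
(ties by id), each joining the first centroid with global-alignment
identity ≥ 0.97 (Needleman–Wunsch, match 1, mismatch −1, gap −2;
identity = matches / alignment columns), else founding a centroid.  This
is the control showing when identity thresholds merge functionally
distinct clades or shatter coherent ones; `compare_groupings` quantifies
the disagreement with the adjusted Rand index and supports cross-dataset
replication checks on shared ASV ids.

## Community structure

* Shannon uses the natural log (base not standardized in the field).
* Bray–Curtis is a semimetric; no triangle inequality is asserted
  anywhere.
* Weighted UniFrac enumerates branches explicitly
  (`raw = Σ_b l_b |p_b − q_b|`); the normalized variant (default)
  divides by `Σ_b l_b (p_b + q_b)` and is bounded in [0,1].  The
  implementation is cross-checked in tests against both a brute-force
  oracle and scikit-bio.
* PCoA is classical scaling of the Gower-centered matrix −½ J D² J.
  Negative eigenvalues are retained in the result but excluded from
  percent-explained; no Cailliez/Lingoes correction is applied by
  default.
* PERMANOVA partitions the Gower-centered matrix sequentially (Type I)
  in the McArdle–Anderson formulation, terms in user order, interactions
  as column products of treatment-coded dummies.  Permutations are free
  row permutations (no strata), p = (1 + #{F ≥ F_obs}) / (1 + n_perm),
  with a 1e-10 relative tolerance so permutations tied with the observed
  statistic count despite floating-point jitter (at small n most
  permutations are exact ties).
* Distance-based RDA (`constrained_pcoa`) eigendecomposes H G H for the
  constraint hat matrix H; percent-explained is relative to total
  inertia, and constrained + unconstrained inertia equals the total.
  Rank-deficient constraint sets are rejected naming the aliased term.

One surfaced ambiguity: ordination figures of the motivating study use
weighted UniFrac while its methods text names Bray–Curtis for the
constrained analysis.  Both metrics are implemented; the pipeline
default is Bray–Curtis and the choice is config-exposed rather than
resolved.

## Differential abundance

A deliberately fully-specified simplification of DESeq2-style NB
testing, adequate for balanced two-group contrasts of agglomerated
(hence high-count) groups: no dispersion shrinkage toward a trend, no
fold-change shrinkage, no outlier filtering.  Steps per contrast:
median-of-ratios size factors on the contrast's samples (pseudocounted
counts are strictly positive, so geometric means are defined);
method-of-moments dispersion `α = max(0, (s² − μ̄)/μ̄²)` with s² pooled
within condition; per-side NB mean MLEs by solving the monotone score
equation `Σ (k_j − s_j μ)/(1 + α s_j μ) = 0`; Wald SE from the Fisher
information of log μ (`I = Σ m_j/(1+α m_j)`), which at α = 0 reduces to
the Poisson case; two-sided normal p; Benjamini–Hochberg across tested
groups.  Swapping contrast sides negates every log2FC exactly and leaves
p unchanged.  The test's figure convention is numerator/denominator
(e.g. soybean/maize, stdN/lowN).

Known property inherited from median-of-ratios normalization: if a large
fraction of groups shifts in one direction, part of that shift is
absorbed into the size factors (≈0.45 log2 units with 25% of groups
fourfold-changed at dispersion 0.2).  The recovery tests therefore plant
direction-balanced changes, which is also the regime the normalization
assumes.

The rank-sum test uses exact enumeration when min(n) ≤ 10, combined
n ≤ 25 and no ties, else the normal approximation with tie and
continuity corrections.  `mean_abs_lfc_compare` compares effect-size
magnitudes of two contrasts by Welch's t test on |log2FC|.

## The synthetic-data generator

What it emulates: the full 384-sample factorial design; genera as
monophyletic clades on an ultrametric-ish random tree with 300-bp
sequences mutated along branches (within-genus identity ≳ 0.95,
between-genus < 0.90 at defaults); per-ASV log-scale linear predictors
with one random intercept per factor; gamma-Poisson (NB) counts around
library sizes that are log-normal with compartment-specific medians
(13,100 rhizosphere / 5,900 bulk, emulating uneven sequencing depth).

Key structural choices:

* **Planted fractions are on the REML-component scale** (the sample
  variance of the level effects), because that is what the fitted
  variance scores estimate.  Effects are empirically standardized, so
  the planted decomposition holds exactly in the emitted ground truth.
* **Response classes are assigned per genus** and **response patterns
  are shared within a response unit** (a genus, or a planted subgenus
  clade), with per-ASV magnitudes: treatment response is phylogenetically
  conserved and groups respond as units — the premise that makes
  group-level agglomeration meaningful.  Planted subgroup clades override
  one factor's fraction (defaults 0.45 vs 0.03 for host species) and get
  their own response pattern, making the two clades genuinely divergent.
* **Total latent log-variance defaults to 2.5** per ASV.  This was
  calibrated once against the qualitative patterns the package is meant
  to reproduce: at the emulated sequencing depth the count layer
  (NB sampling plus log(c+1) clipping of zeros) absorbs roughly a unit
  of variance, and 2.5 puts observed subgroup scores near 0.33–0.45
  after curation, responsive-ASV tallies at ~50–60% for year, ~45% for
  month, ~25% for nitrogen and <1% for rotation at the 5% threshold, and
  host-effect magnitudes in line with the multi-unit log2 fold changes
  reported for host-specific soil taxa.
* No zero-inflation beyond what gamma-Poisson sampling produces, no
  chimera/PCR artefacts, no read-level simulation.

What passing tests therefore do **not** show about real data: taxonomy
is error-free and complete to genus here; real SILVA annotations are
noisy and partially unassigned, which would blur genus membership before
grouping even starts.  Real dispersions vary per taxon and depth varies
systematically with sample type beyond a compartment median.  The
attenuation of variance scores for rare taxa, however, is faithfully
reproduced and is the main reason low-abundance curation precedes
grouping.

## Pipeline and reproducibility

A single global seed fans out to per-stage seeds through
`numpy.random.SeedSequence`, so stages are independently reproducible
and identical config + seed give byte-identical report bodies.  Each
stage writes its products plus a marker with the config hash; resumed
runs reuse matching stages.  Problem sizes in the shipped tests and the
acceptance script (e.g. 60 genera / ~2,250 ASVs for the end-to-end
grouping run, 200 response vectors for recovery, 500 replicates for the
null-calibration suites) were chosen as the smallest sizes at which the
measured properties are stable.

## Known limitations

* Variance components for 2-level factors are intrinsically noisy
  (~1 df); single-ASV scores should be read as noisy estimates, which is
  exactly why grouping pools them across clades.
* The subgroup rule evaluates K ≤ 3; a genus with four genuinely
  divergent clades would be under-split.
* BIOM support covers the JSON (1.0) dialect only.
* The NB test's moments dispersion is per group with no shrinkage;
  for very small contrasts (n ≲ 10 per side) it under-estimates
  dispersion variance and a shrinkage estimator would be preferable.
* Filter thresholds for "low-abundance" curation are dataset-dependent;
  the defaults (total ≥ 25, prevalence ≥ 2) are mild, and the analyses
  here use 1 read/sample-equivalent (≥ 384) to 1,000 total reads for
  grouping, reported per run in the FilterReport.
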