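# Methods

This note records the models, parameter choices, numerical conventions and
known limitations behind `poolsel`. It documents what the code does and why;
every empirical statement here is one the test suite or
`scripts/acceptance.py` computes.

## Study system and data model

The package analyses a pooled larval cohort descended from a factorial
cross of 5 sires × 19 dams (95 full-sibling families combined in equal
proportions), reared in five replicate cultures and sampled at days
0 (fertilized-egg pool, unreplicated), 2, 6, 10, 14, 16 and 22
post-fertilization. Each sample is sequenced as a pool, producing, per
biallelic SNP, read counts of the two alleles. Cumulative survival is
recorded per replicate per day and follows type III survivorship, declining
to roughly 4% by day 22.

The "minor" allele is designated once per locus — the allele with the lower
mean frequency across all samples — and held fixed thereafter, so a locus's
minor-allele frequency (MAF) may exceed 0.5 at individual ages without
being re-flipped. Day 0 supplies the egg-pool MAF used both as a filter
(loci with egg MAF ≤ 1% are dropped) and as the anchor for genotype
estimation.

## Synthetic data generator

`synthetic_data` emulates the experiment with known ground truth.

* **Truth propagation.** Each locus starts at Hardy–Weinberg proportions of
  a drawn initial MAF and advances per sampling interval by the viability
  update `f_g' = f_g·w_g / w̄` with `w̄ = Σ f_g w_g`; cumulative survival is
  the running product of `w̄`. The update keeps states exactly on the
  simplex and reduces to the textbook `p²w_AA + 2pq·w_AB + q²w_BB` form
  whenever the state is at Hardy–Weinberg proportions.
* **Survival shape.** The neutral per-interval viabilities are the ratios
  of a target type III curve (1 → 0.55 → 0.40 → 0.30 → 0.22 → 0.15 → 0.04
  over the seven sampling days): heavy losses in the first days and again
  around metamorphosis. Selective scenarios perturb genotype viabilities
  around this baseline, which necessarily raises cohort mean fitness — a
  strongly directional run ends nearer 8% survival than 4%. That is a
  property of viability selection, not a calibration target.
* **Scenarios.** Per locus, a selection strength `s ~ U(0.1, 0.3)` scales
  the perturbation: *neutral* (all viabilities equal), *directional*
  (w_AA ≥ w_AB ≥ w_BB every interval; a deleterious minor allele, i.e.
  genetic load), *balanced* (the homozygote ordering reverses once at a
  random interior interval), *overdominant* (w_AB strictly maximal).
* **Observation model.** Read depth is uniform on [50, 1000] (so the
  depth filter's boundaries stay exercisable) and the minor-read count is
  binomial at the true MAF. Replicates share the true MAF — they descend
  from a single embryo pool — so all replicate variation is sampling noise;
  an optional lognormal perturbation (σ = 0.05) roughens the replicate
  survival series. Everything is a deterministic function of the scenario
  seed.

What the generator does **not** emulate: overdispersion from unequal
individual contributions to the pool, mapping or base-calling error,
linkage between loci (each locus evolves independently), and
replicate-level biological divergence. Passing tests therefore demonstrate
correctness of the machinery under the stated noise model, not robustness
to artefacts real pool-seq data may carry.

## Per-locus testing and categorization

The age test fits, per locus, a binomial GLM of (minor, major) counts on
sampling day as a factor (cell-means coding, statsmodels IRLS) and compares
it to the intercept-only fit by the deviance difference, referred to
χ² with (number of days − 1) degrees of freedom. Day is a factor because
allele-frequency change during development is typically abrupt and
non-monotone. p-values are Benjamini–Hochberg adjusted across loci;
significance is q < 0.05. The test suite checks the GLM deviance against
independent closed-form binomial log-likelihood arithmetic (the by-day MLE
is the pooled per-day fraction).

Categorization runs on replicate MAFs from day 2 onward (day 0 has a single
egg sample; it still enters the GLM). One-way ANOVA across days is followed
by Tukey studentized-range comparisons over all day pairs — the family-wise
control is deliberately over the full family — but only sequential-day
pairs feed the rules: no significant sequential change → G; significant
changes all one direction → UD; two or more opposing significant changes →
BD. Tukey runs on raw frequencies (depths bounded in [50, 1000] keep
variance heterogeneity modest); loci with zero within-day variance
everywhere are flagged degenerate, and unequal sequential means are then
treated as significant with a warning. Flat loci trip the sequential tests
at about the nominal family-wise 5% rate; constructions that must classify
deterministically therefore share replicate perturbations across their flat
segments.

## Clustering

Each significant locus is represented by first differences of its mean MAF
across consecutive replicated days (ΔAF). A single missing interior mean is
linearly interpolated on the day scale; longer gaps exclude the locus with
a warning. ΔAF components are not normalized per interval: the sampling
intervals have unequal day spans, and the trajectory shape as sampled is
the clustering target.

k is selected on a 2–20 range by majority vote of three internal indices —
silhouette width on Manhattan dissimilarities, Calinski–Harabasz, and
Davies–Bouldin — with ties toward smaller k; the final clustering is plain
Euclidean k-means with 25 restarts. The Manhattan-for-selection /
Euclidean-for-clustering pairing is kept deliberately, mirroring the common
NbClust-then-kmeans workflow. The scan starts at 2 because the validity
indices are undefined at k = 1; identical-row inputs return k = 1 through
an explicit degenerate path. Labels are renumbered 1..k by descending
membership.

## Egg-pool genotype estimation

For a locus with egg MAF q, each of 50 simulations places
`round(q · 48)` minor-allele copies uniformly among the 48 parental allele
slots (24 parents), forms all 95 sire × dam families, and averages
Mendelian offspring expectations with equal family weights. With equal
weights the factorial average factorizes as
`mean_families(b_s·b_d) = mean(b_sires) · mean(b_dams)`, which the
implementation uses; a brute-force family enumeration is kept as a test
oracle.

Fixing the copy count keeps the parental allele frequency exact but couples
the sexes: the hypergeometric split of copies over 10 sire and 38 dam slots
makes their allele frequencies covary negatively, producing an exact
heterozygote excess of `2·Var(c_s)/380` — about +0.011 in f_AB at q = 0.5 —
relative to Hardy–Weinberg. This finite-pool excess is a real property of a
small dioecious breeding design, shrinks as the parent pool grows, and is
asserted exactly in the unit tests. Estimates remain within ~0.012 of
Hardy–Weinberg, i.e. "largely consistent" for downstream use. A q too small
to yield one parental copy is flagged monomorphic-in-parents.

## Trajectory forecaster

Per locus, the forecaster starts from the estimated egg genotype state
(factorial-cross mean by default, Hardy–Weinberg of the egg MAF as
fallback) and, for each interval up to the constrained days 2, 6, 10, 14
and 22 (day 16 is sampled but not constrained; day 0 is the initial state,
giving six states per trajectory), proposes viabilities
`w ~ Uniform(0,1)³`, advances the state, and accepts only if both

* |simulated MAF − empirical MAF| ≤ tolerance (absolute scale), and
* |simulated − empirical| / empirical ≤ tolerance for cumulative survival
  (relative scale),

with tolerance 0.10. The asymmetry is deliberate: survival is ~0.04 at day
22, where an absolute 0.10 window would accept anything, while a relative
window on MAF would collapse near 0. Both modes are switchable.

A rejected proposal re-draws the interval (budget 10 000 draws); an
exhausted interval restarts the trajectory from day 0 (budget 1 000
restarts); exhausted budgets return a partial ensemble with an explicit
infeasibility report. Proposals are drawn in blocks for speed; the first
accepted draw in stream order is used, so results equal one-at-a-time
proposing. Ensembles (50 accepted trajectories per locus) are summarized by
per-day means and 2.5/97.5 percentile intervals for genotype frequencies
and viabilities, and an independent checker re-verifies every accepted
trajectory against the constraints.

**What the ensemble does and does not identify.** Genotype frequencies are
recovered well: on synthetic loci with known fitness schedules the truth
falls inside the 95% ensemble interval for ≥ 90% of locus × day × genotype
calls and ensemble means sit within 0.10 of truth for ≥ 80% (the acceptance
script measures ~100% and ~97%). Fitness components are only partially
identified: conditional on the MAF and survival windows the accepted set is
(at small tolerance) a one-parameter family, and under uniform proposals
its mean inflates weakly constrained components — the viability of a
genotype that is rare carries little information and reverts toward the
prior mean of 0.5. Consequences, measured on synthetic truth: under
neutrality the two homozygote means agree (symmetry holds to < 0.01 at
q = 0.5) but the heterozygote mean need not equal them; under strong
directional selection the w_AA > w_BB ordering is recovered for essentially
all loci while the minor allele remains common, and degrades at the final
interval once it has become rare. Interpret ensemble fitness trajectories
comparatively (orderings, temporal switches), not as calibrated viability
estimates for rare genotypes.

## Distortion analysis

Reconstructed spat-stage genotype frequencies are regressed, per genotype
class, on (a) egg-pool genotype frequencies and (b) Hardy–Weinberg
expectations from the spat MAF; the formulation with the better summed
AIC + BIC across classes is selected (the Hardy–Weinberg formulation wins
whenever the two genuinely differ). Records outside the selected model's
two-sided 95% prediction interval are flagged; under pure-Hardy–Weinberg
synthetic records the flag rate calibrates to ~5%. Loci with flagged
genotypes are classified by residual sign pattern — fixation skew
(AA up, AB/BB down), heterozygote excess (AB up, AA/BB down), other — and
stratified by initial MAF at the 20% reporting threshold. Outliers are
counted per (locus, genotype).

## Linkage bridging

SNPs are assigned the cM position of the nearest mapped marker (by bp) on
their scaffold; scaffolds absent from the map or spanning multiple linkage
groups are omitted with reason codes rather than errors. Inter-marker
distance is the mean of adjacent gaps within each linkage group, summarized
as mean ± s.d. across groups (all-pairs distances available behind a flag);
co-located markers contribute zero-length gaps. Per-cluster summaries
restrict to one trajectory cluster's markers first, probing whether a
shared temporal pattern reflects shared genomic neighbourhood.

## Problem sizes and determinism

Default analysis sizes follow the experimental design (≈750 loci, 5
replicates, 7 sampling days); the test suite and acceptance script run the
stochastic checks at 50–500 loci, sizes at which the measured properties
(coverage, FDR, calibration) are stable across seeds. Every stochastic
stage takes an explicit seed (`numpy.random.Generator`); pipeline runs are
byte-reproducible given the same config, and k-means uses seeded restarts.

## Known limitations

* Fitness identifiability as above: the uniform-proposal rejection scheme
  is a bounding procedure, not a posterior; no likelihood or ABC weighting
  is attempted.
* Loci are treated as independent throughout; linkage is summarized
  descriptively, never modelled.
* The binomial read-count model carries no overdispersion by default
  (a beta-binomial option exists in the generator for robustness checks
  but is not part of the standard conditions).
* The factorial-cross estimator assumes equal family contributions and no
  meiotic drive or fertilization skew, matching the experimental design
  assumptions.
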