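# poolsel

Genotype-dependent mortality analysis for pooled allele-frequency time
series from larval cohorts.

## The problem

Broadcast-spawning marine invertebrates such as the Pacific oyster suffer
massive, genotype-dependent mortality during larval development (type III
survivorship: only a few percent of fertilized eggs reach settlement).
Pooled sequencing of the surviving cohort at successive ages yields allele
read counts — but not genotypes — at thousands of SNPs. `poolsel` implements
a full analysis chain that turns such pooled count tables plus a survival
series into locus-level statements about viability selection:

1. **Filtering** — depth bounds (50–1000×), biallelic and one-SNP-per-tag
   rules, replicate-presence and egg-pool MAF (>1%) filters.
2. **Change detection** — per locus, a binomial GLM of minor:major read
   counts on age as a multi-level factor, tested by the deviance
   (likelihood-ratio) statistic and Benjamini–Hochberg adjusted (q < 0.05).
3. **Categorization** — Tukey studentized-range comparisons of replicate
   allele frequencies at sequential ages classify each changing locus as
   gradual (G), uni-directional (UD) or bi-directional (BD).
4. **Clustering** — k-means over per-interval allele-frequency changes
   (ΔAF), with k chosen by majority vote of internal validity indices.
5. **Egg-pool genotypes** — the cohort descends from a controlled 5 × 19
   factorial cross (95 families), so the fertilized-egg genotype
   composition is estimable by simulating broodstock populations carrying
   the observed allele frequency and applying Mendelian ratios.
6. **Trajectory reconstruction** — a rejection sampler draws per-interval
   relative viabilities (w_AA, w_AB, w_BB) ~ Uniform(0,1)³, advances the
   genotype state with the Hardy–Weinberg fitness equation

       w̄ = p²·w_AA + 2pq·w_AB + q²·w_BB,   f_g′ = f_g·w_g / w̄,

   and accepts an interval only if simulated MAF and cumulative survival
   both land within 10% of the empirical means. Ensembles of accepted
   trajectories (50 per locus) bound the plausible genotype-frequency and
   fitness histories of each locus.
7. **Distortion analysis** — reconstructed settled-stage (spat) genotype
   frequencies are regressed on Hardy–Weinberg expectations from the spat
   MAF; genotypes outside the 95% prediction interval are flagged and loci
   classified as fixation skew (AA up — genetic load), heterozygote excess
   (AB up), or other, stratified by initial MAF around 20%.
8. **Linkage bridging** — SNPs are placed on linkage groups via shared
   genomic scaffolds and nearest-marker assignment; adjacent-gap distances
   summarize marker independence overall and per cluster.

A first-class synthetic-data module generates pooled count tables, survival
series and linkage maps under known fitness scenarios (neutral,
directional/load, temporally balanced, overdominant), so every stage is
testable against ground truth without any sequencing data.

## Worked example

```python
from poolsel import synthetic_data as sd, filtering, af_testing, forecaster, hw

sc = sd.make_scenario("balanced", n_loci=120, seed=7)     # temporally balanced selection
counts, survival, truth = sd.simulate_experiment(sc)

filtered, report = filtering.apply_filters(counts)
res = af_testing.test_age_effect(filtered)
print(int(res["significant"].sum()), "/", len(res))        # -> 118 / 120

per_sample, per_day, _ = filtering.compute_maf(filtered)
cats = af_testing.categorize_all(per_sample, res)
print(cats.loc[res.index[res["significant"]], "category"].value_counts().to_dict())
# -> {'UD': 51, 'G': 45, 'BD': 22}

locus = res.index[res["significant"]][0]
surv = survival.groupby("day")["cum_survival"].mean()
cons = forecaster.constraints_from_tables(per_day.loc[locus], surv, tolerance=0.10)
ens = forecaster.forecast_locus(hw.hwe_expected(float(per_day.loc[locus, 0])),
                                cons, n_accept=50, seed=1)
print(forecaster.summarize_ensemble(ens)[["day", "f_AA", "f_AB", "f_BB", "maf", "survival"]]
      .round(3).to_string(index=False))
```

```
 day  f_AA  f_AB  f_BB   maf  survival
   0 0.391 0.469 0.140 0.375     1.000
   2 0.481 0.419 0.100 0.310     0.602
   6 0.507 0.417 0.076 0.284     0.470
  10 0.524 0.413 0.064 0.270     0.371
  14 0.567 0.380 0.053 0.243     0.273
  22 0.613 0.300 0.087 0.237     0.041
```

118 of 120 loci show significant allele-frequency change across the 22-day
larval period (under balanced selection every locus truly changes; two are
missed at this depth). The reconstruction for the displayed locus shows the
minor allele declining from 0.375 to 0.237 while only ~4% of the cohort
survives, with the minor homozygote's frequency roughly halving — the
ensemble means quantify how much of the allele-frequency change was carried
by each genotype class.

The same stages run from the shell:

```sh
poolsel simulate --scenario balanced --n-loci 120 --seed 7 --out-dir run_in
poolsel run-all --counts run_in/counts.tsv --survival run_in/survival.tsv \
        --out-dir run_out --seed 7
```

`run_out/manifest.json` records per-stage locus counts, category tallies,
the chosen k and the distortion class counts, from which the run's summary
fractions are recomputable.

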