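# Methods

This note records the statistical model behind `triogrs`, the defaults and
why they were chosen, and what the simulation studies do and do not show.

## The design

In a CTD case-parent trio, the mother and father are (to excellent
approximation) genetically unrelated adults drawn from the same source
population. If the child's affection status is independent of the
mother's genotype given the transmitted alleles, then conditioning on an
affected child perturbs the parental *mating-type* distribution
symmetrically, and the mothers' and fathers' genetic risk score (GRS)
distributions remain exchangeable. A maternal genetic effect — the
mother's genotype influencing risk through the in-utero environment —
breaks this symmetry in one direction only: ascertainment enriches
high-risk genotypes among mothers but not fathers. The package's core
inference therefore treats mothers as "cases" and fathers as "controls".

Caveat inherited from the design: an effect of the *child's* genotype is
partially confounded with a maternal effect, because mothers transmit half
their alleles to the child and ascertainment on an affected child then
tilts both parents' distributions. With a child effect only, the tilt is
symmetric between parents, so the mother-father contrast is still null;
the simulator exposes an optional `beta_child` term (off by default) to
make this explorable.

## Scores

`S = Σᵢ wᵢ gᵢ` over a condition's SNP panel; `score_combined` is defined
as the exact floating-point sum of the three condition scores, so
additivity is an identity, not an approximation. No rescaling by SNP count
or weight total is applied — published per-condition means are on the raw
scale. Dosages may be fractional (imputed data); hard calls are the
integral special case and use the same formula.

**Allele alignment.** Dosages are oriented onto the weight table's risk
allele before scoring: if the file counts the other allele, `g ← 2 − g`.
Allele pairs that match the weight entry in neither order are hard errors
(no strand complementing; a silent strand flip would corrupt risk-allele
orientation). For strand-ambiguous pairs (A/T, C/G) a swapped-order match
is indistinguishable from a strand flip; it is treated as an orientation
flip, which is a documented limitation of allele-label-only inputs. The
simulated panels avoid ambiguous pairs entirely.

**Missing genotypes.** The default policy, `impute_role_mean`, replaces a
missing dosage with the mean oriented dosage of that SNP among samples of
the *same parental role*. Imputing within role cannot manufacture a
mother-father difference, whereas pooled-mean imputation would shrink a
real one. `drop_sample` and `score_available` are provided for
sensitivity analyses; with complete data all three are identical (tested).
A SNP missing in every sample of one role falls back to the overall mean;
a sample missing every genotype is an error.

## Contrasts

* **Means.** Unpaired, equal-variance Student's t. Mothers and fathers
  are genetically unrelated, so independence is defensible; a paired
  variant (pairing within trios) would only gain power if scores were
  correlated within couples, which random mating excludes. Normality is
  checked per group with Shapiro-Wilk at α = 0.05; if either group rejects
  and all values in both groups are positive, both groups are
  log-transformed first. Degenerate zero-variance groups return t = 0,
  p = 1 when identical.
* **Percentiles.** Nearest-rank: the cutoff is the `⌈n·q⌉`-th order
  statistic of the fathers' scores. It is always an observed score,
  deterministic under ties, and leaves between `⌊(1−q)n⌋ − 1` and
  `⌈(1−q)n⌉` fathers strictly above it for continuous scores (tested at
  n = 100, 466, 721). "High" means strictly greater than the cutoff.
* **2×2 test.** Two-sided Fisher's exact p (total probability of tables
  no more probable than the observed one), computed by `scipy`; the test
  suite checks it against an independent hypergeometric enumeration over
  every table with group sizes up to 30. The odds ratio is `ad/bc` with a
  Woolf logit 95% CI; when any cell is zero, the Haldane-Anscombe +0.5
  correction is applied to all cells for both the estimate and the CI.
  Note the exact test is discrete and therefore conservative: its
  realized size at α = 0.05 sits below 0.05 (measured ≈ 0.03–0.05 at
  n = 700 per group; see the type-I error study).
* **Subgroups.** Cohort, CTD-subtype and overt-phenotype filters compose
  conjunctively; percentile cutoffs are always recomputed from the
  filtered fathers so each subgroup is judged against its own paternal
  distribution. Subgroups below 10 trios are refused.

## SNP screen

Thresholds are the exact quotient `0.05 / n_snps` per condition
(displayed rounded to one significant digit: 0.002 for the 31-SNP HTN and
30-SNP obesity panels, 0.001 for the 46-SNP T2D panel). A p-value exactly
equal to the threshold counts as significant; the suggestive band is the
open interval up to 0.05. The screen consumes p-values; the trio GWAS
that produces them is out of scope.

## Descriptives

Percentages are reported to one decimal (half away from zero) over each
cohort's non-`unknown` denominator for the variable, uniformly. The
levels × cohorts table is tested with Fisher's exact test; for r×c tables
scipy has no exact routine, so the package enumerates all tables with the
observed margins (up to 200,000 tables) and otherwise estimates the same
tail probability by seeded Monte Carlo with Patefield-sampled tables
(`scipy.stats.random_table`, 100,000 draws by default). Table
probabilities are compared with a 1e-7 relative slack to keep floating-
point ties stable.

## Simulator

* **Panel.** 31/30/46 SNPs per condition by default, mirroring the
  published score composition. Effect-allele frequencies are uniform on
  (0.1, 0.9) — inside the common-variant constraint MAF > 0.05 with a
  margin so simulated panels are not dominated by near-boundary SNPs —
  and weights uniform on (0.05, 0.6), a band that covers the spread of
  published per-allele log-odds-scale weights for these conditions.
* **Genotypes.** Parents i.i.d. binomial(2, f) per SNP (Hardy-Weinberg,
  random mating; no LD, no stratification, no assortative mating).
  Children receive one Bernoulli(g/2) allele from each parent.
* **Affection.** `P(affected) = expit(α + β_m z_m)` with `z_m` the
  mother's combined GRS standardized by the exact population moments
  `μ = Σ 2wᵢfᵢ`, `σ² = Σ wᵢ²·2fᵢ(1−fᵢ)`; threshold mode replaces `z_m`
  with `1[z_m > z_q]`, where `z_q` is the population `threshold_quantile`
  of `z` (a property of the generative model, not of the sampled cohort).
  `α` is solved by bisection to an interval of 1e-10 so the marginal
  prevalence equals `baseline_prevalence` (default 0.01, the live-birth
  rate of congenital heart defects). With `β_m = 0` the closed form
  `α = logit(prevalence)` is used; otherwise the marginal prevalence is
  estimated over 400,000 maternal draws from the exact genotype
  distribution, seeded from the config, which keeps the realized
  unascertained affection rate within Monte Carlo error of the target
  (tested).
* **Ascertainment.** Rejection sampling: batches of mothers are drawn,
  affection is Bernoulli in the mother's risk, and affected trios are
  kept until the target size is reached. When no child effect is
  configured, fathers and children are conditionally independent of
  affection given the mother, so they are drawn after ascertainment —
  an exact, not approximate, shortcut.
* **Phenotype fields** (cohort label, CTD subtype, pregnancy conditions,
  age/BMI bands) are drawn with rates resembling the study cohorts so
  subgroup filters are exercisable; they are decoration, not part of the
  genetic model.

Everything is deterministic given `(seed, config)`; independent streams
are spawned per purpose (panel, calibration, cohort) via `SeedSequence`.

**What the simulator does not emulate:** linkage disequilibrium between
panel SNPs, population stratification, assortative mating, genotyping or
imputation error structure, and gene-environment interaction. Passing
operating-characteristics tests therefore show that the *statistical
machinery* has the advertised size and power under the design's own
assumptions — not that real cohorts satisfy those assumptions.

## Operating characteristics (problem sizes used)

The simulation studies run cohorts of 700 trios — the scale of the pooled
study — with 1000 replicates for the null (type-I error of the
95th-percentile OR test inside the 99% binomial band around 0.05) and 200
replicates per effect size for power (β_m ∈ {0, 0.3, 0.6, 1.0}). At
β_m = 1 the ascertained maternal shift is ≈ 1 population SD of the
combined score, power is essentially 1, and the mean OR at the 95th
percentile is ≈ 6; monotonicity of power in β_m is checked across the
grid.

## Known limitations

* Only parents are scored; offspring genotype adjustment is out of scope
  (no trio-based method exists for multi-SNP weighted scores).
* The r×c Monte Carlo p has simulation error ~1/√draws; the seed is part
  of the configuration so results are reproducible.
* The tabular dosage dialect encodes alleles in column names
  (`snp:counted:other`); files from other tools need a header rename or
  the VCF route.
* Real-data percentile cutoffs depend on the empirical quantile
  convention; nearest-rank was chosen for determinism and because printed
  cutoffs in this literature are observed scores, but other conventions
  can shift a cutoff by one order statistic.
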