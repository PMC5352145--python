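# Methods

## Survival phenotypes

Raw observations are per-fly event records (line, sex, replicate tube, time
in hours, dead/censored, pathogen/control). Deaths discovered at 12-hour
checks are interval-censored on the right edge of the interval, so the
synthetic generator rounds latent death times *up* to the scoring grid and
the readers validate that observed times sit on a declared grid.

Survival curves use the Kaplan-Meier product-limit estimator with the
Greenwood variance. **LT50** is the smallest event time t with S(t) ≤ 0.5,
without interpolation: on a 12-h grid an interpolated median suggests
precision the assay does not have. A curve that never reaches 0.5 (heavy
right-censoring, e.g. a 14-day horizon with resistant survivors) yields a
flagged undefined median, not a number. The per-line LT50 defaults to the
arithmetic mean of the replicate-tube LT50s; a pooled-curve median is
selectable.

**Micro-environmental plasticity** is the within-line spread among
genetically identical flies: σ_E is the root mean squared error of an
intercept-only fit to uncensored death times, which equals the ordinary
standard deviation with an n−1 denominator (the equality is asserted in the
tests). ln(σ_E) and CV_E = σ_E/mean (a dimensionless fraction, not a
percent) are derived from it. Censored flies contribute to curves only,
never to moments, and every exclusion is counted in a flags column. Two
within-line spread notions coexist in this area — a Greenwood-based standard
error of the curve and the root-MSE of the death times; both are available,
and root-MSE is the plasticity default because the variance-level analysis
is defined on it.

The two-group log-rank test (via `lifelines`) serves mutant-vs-control
functional comparisons; a hand-computed hypergeometric oracle checks it in
the tests.

## Variance partitioning and heritability

Pooled over sexes the model is `Y = μ + S + L + S×L + ε` with sex fixed and
line and sex×line random. Sums of squares use cell (line × sex) means —
the unweighted-means analysis — and components come from the method of
moments by equating observed to expected mean squares:

    σ²_E  = MS_E
    σ²_SL = (MS_SL − MS_E) / n_h
    σ²_L  = (MS_L − MS_SL) / (2 n_h)

with `n_h` the harmonic mean of cell counts (exact when balanced; the
standard approximation otherwise). Line and sex are tested over the
sex×line mean square, the interaction over error — never line over error in
the random-line pooled model. Negative moment estimates are truncated to
zero and flagged so that H² stays in [0, 1]. REML would be the modern
choice; the moment estimators are used because the published analysis is an
MS-based ANOVA reproducible in closed form, and a `statsmodels` ANOVA
cross-check runs in the tests. Single-sex data reduce to the one-way random
model with σ²_L = (MS_L − MS_E)/n_h.

Broad-sense heritability: H² = (σ²_L + σ²_SL)/(σ²_L + σ²_SL + σ²_E) pooled,
σ²_L/(σ²_L + σ²_E) within a sex. H² is scale-invariant, so day- and
hour-scale analyses agree.

**Variance-level heritability.** σ_E is estimated separately for each line,
sex and replicate tube; each tube contributes one ln(σ_E) observation to a
one-way random-effects ANOVA across lines, and H² = σ²_L/(σ²_L + σ²_E) on
that scale. Levene's test (classic, mean-centered; median variant
selectable) screens for heterogeneity of within-line variance.

**Covariate ANOVA.** Line-level infection status (e.g. *Wolbachia*) is
tested with `Y = μ + S + I + S×I + L(I) + S×L(I) + ε`, line nested in
status; the infection main effect is tested over the nested-line mean
square, sex and sex×infection over sex×line(infection). Null calibration of
the infection P value is property-tested by simulation.

## Association mapping

Observations are line means (or CV_E), not per-fly records: each inbred
line is a replicable genotype and its mean is the natural association unit.
Adjustment is two-step — OLS residualization on *Wolbachia* plus the five
major inversion indicators (In(2L)t, In(2R)NS, In(3R)P, In(3R)K, In(3R)Mo),
collinear columns dropped with a warning — followed by per-marker OLS of
adjusted values on homozygous dosage (0/2; heterozygous calls in inputs are
masked to missing because the panel is modeled as fully inbred, with a
logged count exposing residual heterozygosity). This is a deliberate
approximation to a joint mixed-model pipeline: the two-step form matches
the "adjust, then scan" design and keeps per-marker cost trivial, at the
price of ignoring line relatedness — the panel is treated as exchangeable,
a stated limitation.

The reported effect is the model-implied difference between major- and
minor-homozygote classes (twice the dosage slope, with sign fixed so that
negative effect ⇔ minor-allele homozygotes survive longer). Whether a
pipeline's effect is the class difference or half of it is convention; the
class difference is adopted and documented here. Markers with fewer than 4
minor-allele lines (complete cases) are skipped by default and the
minor-line count is always reported, since hits carried by ≤5 lines are
fragile. Nominal P values are reported against fixed discovery thresholds
(10⁻⁵, 10⁻⁶) rather than an FDR. Zero residual variance yields a
"boundary" flag, not P = 0. CV_E is the default plasticity phenotype for
scans, with ln(σ_E) selectable.

Downstream characterizations: the MAF/effect-size spectrum (fraction of
significant hits with MAF < 0.2, sign counts, binned |effect|), per-line
minor-allele load over the significant set with overall and
split-at-a-phenotype-value correlations (a U-shaped placement of minor
alleles produces near-zero overall r with opposite-signed split
correlations), and marker/gene-level overlap between two scans.

## Annotation

A polymorphism is genic if inside a gene span or within 1 kb (inclusive of
the 1000th base) of one, strand-aware for the up/downstream call. When
several features or overlapping genes apply, one class is reported under
the fixed precedence non-synonymous > synonymous > exon_other > UTR5 >
UTR3 > intron > downstream_1kb > upstream_1kb > intergenic — the source
analyses never state a precedence, so a deterministic rule is fixed here.
All genes hit are listed. Synonymy requires codon context (reference
codon, position in codon, strand) carried on the CDS interval; without it
the class is `exon_other`, never a guess. Enrichment uses the two-cell
goodness-of-fit χ² (1 df, no continuity correction) against genome
composition constants (genic 0.482, exonic 0.183, intronic 0.30,
intergenic 0.518) shipped as overridable configuration, since they are
inputs, not code. The inventory reports the "functional" fraction
(introns + UTRs + non-synonymous over total) and the genic fraction; both
pairings of the enrichment test are exposed in the CLI report.

Coordinates are 0-based half-open internally; 1-based inclusive conventions
exist only at the GFF/VCF boundary, giving a single conversion point.

## Trait correlations

Pairwise Pearson r (Spearman selectable) with two-sided P on a lines ×
traits table, pairwise-complete per pair with n recorded — public panel
traits cover different line subsets. The Holm-Bonferroni step-down is
applied across the declared family of pairs of a run (the family is a run
property recorded in the manifest). Holm rejections are provably between
Bonferroni and unadjusted rejections; both bounds are property-tested.

## Kinetics

Per-line CFU trajectories are the mean over sampled flies at each 12-h time
point. The threshold-crossing time is the first grid time with mean CFU
strictly greater than the threshold (">10 CFU" read literally);
never-crossing lines are flagged and excluded, with counts, from the
crossing-vs-LT50 Pearson correlation. Summary-statistic comparisons
(e.g. spores per cadaver between resistant and susceptible line sets) use
Welch's t with Welch-Satterthwaite df, recovering SD as SE·√n.

## Synthetic data generator

The generator emulates the study design: 100–200 inbred lines, two sexes,
3 replicate tubes × ~20 flies, 12-h scoring, optional right-censoring at a
horizon. Genotypes are homozygous dosages sampled per marker from a
rare-skewed MAF spectrum (0.5·Beta(0.8, 3) by default; alt is simulated as
the minor allele); markers within an optional LD block share a latent
per-line uniform, so block size 1 gives independence. Wolbachia and
inversion states are Bernoulli per line.

Per-fly latent death times are `location + scale·z`: location is
μ + sex + line + sex×line + Σ(causal effects · dosage/2) (a stored negative
effect lengthens minor-carrier survival, matching the reporting
convention); scale is line-specific,
σ_line = σ₀ · Π(multiplier^(dosage/2)) · exp(δ_l), δ_l ~ N(0, τ²), so
ln(σ_E) is linear in the variance effects — matching the analysis scale of
the plasticity model. Two families map latent values to hours: log-normal
(default — positive support, clean location/scale separation; latent is in
log-hours, and defaults μ = 4.844, σ²_L = 0.012, σ²_E = 0.033, sex effect
0.038 put the panel near a 5.3-day mean LT50 with ~0.58-day line SD and
~0.96-day within-line SD) and normal (latent is hours directly), which the
parameter-recovery tests use so that the nominal variance components live
on the analyzed scale. No distributional form for fly death times is
established in this literature; the log-normal default is a modeling
choice. Times are rounded up to the grid (minimum one grid step), adding
grid²/12 ≈ 12 h² to the residual variance — negligible against the
~530 h² within-line variance used in recovery runs.

For a chosen true variance-level heritability, the helper
`dispersion_for_variance_h2` solves τ²/(τ² + V_e) = H² analytically, with
V_e = ψ′((n−1)/2)/4 the exact sampling variance of ln(σ̂) for n normal
observations — the construction is a priori, not tuned to estimates.

CFU curves are phenomenological logistic growth with lag proportional to
the line's expected LT50 and multiplicative log-normal count noise; there
is no mechanistic within-host model, no recombination/linkage-map
simulation and no tolerance-vs-resistance mechanism. What passing
recovery tests show is that the estimators are consistent under the
generator's assumptions (normal/log-normal within-line variation,
independent markers unless blocked, exchangeable lines); they do not show
robustness to real-data features the generator omits — shared ancestry and
long-range LD, batch/day effects between replicates, non-monotone hazard
shapes, or measurement artifacts beyond grid discretization.

## Problem sizes and numerical choices

Recovery tests run at the study's design scale (188 lines × 3 tubes × 20
flies for the mean level; 150 lines for the variance level; 2000 markers
for scan calibration), averaged over 20 seeds — sizes chosen so the full
suite runs in a couple of minutes while leaving Monte-Carlo noise well
inside the asserted tolerances. Ties in the minor-allele definition break
toward the alt allele. Missing genotype cells drop lines per marker
(complete-case testing), not panel-wide. Float output uses 6 significant
digits with fixed column order so reruns diff cleanly.

## Known limitations

- No REML/Bayesian variance estimation; unbalanced designs rely on the
  harmonic-mean EMS approximation.
- No kinship correction, epistasis, imputation or gene-based burden tests
  in the scan.
- No parametric survival regression (Weibull/Cox) or frailty models.
- Annotation does no variant-effect prediction beyond synonymy.
- The in-repo pipeline is a single-machine, in-memory implementation; a
  2-million-marker panel is out of scope (synthetic panels stand in).
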