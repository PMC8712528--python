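# Methods

`isoswitch` analyses 3′UTR isoform switches driven by alternative
polyadenylation (APA) and their downstream consequences. A gene with tandem
poly(A) sites produces mRNA isoforms that share a 5′ body but differ in their
3′ ends; which isoform dominates can change between tissue states even when
total gene expression does not. The package implements five analysis stages
plus a synthetic-data layer that generates statistically matched inputs for
each of them.

## Probe-level SLR statistic (`apa_slr`)

On 3′-biased expression arrays, probes located 5′ of a tandem poly(A) site
(proximal) hybridize to all isoforms of a gene, while probes 3′ of it
(distal) hybridize only to isoforms that read through to a distal site. With
short-isoform abundance S and long-isoform abundance L, expected intensities
are proportional to S+L on the proximal side and L on the distal side, so the
short-to-long ratio

    SLR = mean(proximal intensities) / mean(distal intensities) = (S + L) / L

is 1 + S/L and rises under proximal-site (3′UTR-shortening) shifts. Details:

- **Partitioning.** A probe is proximal iff its entire span (start +
  probe length, half-open) ends at or before the site coordinate, distal iff
  it starts at or after it. Probes straddling the site measure an isoform
  mixture and are dropped. Each side must retain `min_probes` (default 2)
  probes or the partition is rejected with a reason — a one-probe side would
  reduce the ratio to a single-probe statistic.
- **Summary.** Arithmetic mean of linear-scale intensities per side (median
  selectable). The ratio is taken per sample; samples with a nonpositive
  distal mean are flagged and excluded rather than imputed.
- **Testing.** Group comparison is a two-sided unpaired t-test on ln(SLR)
  (Welch by default, pooled selectable): ratios are multiplicative, so the
  log scale is where a location shift is meaningful. Screens report raw
  p-values sorted ascending; Benjamini–Hochberg adjustment is available but
  off by default.

Useful exact invariants (all tested): SLR is invariant to rescaling any
sample's whole intensity column; swapping the side labels negates ln(SLR);
multiplying distal intensities by c divides SLR by exactly 1/c.

## Isoform fractions (`isoform_fraction`)

For transcript-level quantifications (TPM), the fraction of isoform *i* in a
sample is TPM_i / Σ_j TPM_j over the gene's isoforms. Fractions sum to 1 per
sample and are invariant to per-sample rescaling, which removes library-size
effects before any testing. Samples whose gene total is zero have undefined
fractions and are masked, never imputed as 0/0.

Per isoform, fractions are compared across sample groups with one-way ANOVA
followed by Tukey's HSD over all group pairs (studentized-range
distribution); significance stars use the conventional 0.05/0.01/0.001/0.0001
thresholds. Tests run on raw fractions; logit or arcsine transforms are
deliberately not applied by default. Isoforms with zero within-group variance
everywhere are flagged degenerate instead of producing an undefined F.

An isoform **switch** against a designated reference group is called when the
reference-dominant isoform loses ≥ δ of mean fraction in a contrast group
while some other isoform gains ≥ δ, and both isoforms' reference-vs-contrast
Tukey contrasts are significant (δ default 0.1, α default 0.05). This is a
deliberately conservative operationalization of "the dominant isoform
changed": it requires reciprocal movement, not just one significant contrast.

## Decay kinetics (`decay_kinetics`)

RT-qPCR abundance uses the classical 2^−ΔΔCt quantification with a fixed
amplification efficiency of 2: ΔCt subtracts the stable reference gene within
each (condition, timepoint, replicate), ΔΔCt subtracts the mean ΔCt at the
t = 0 calibrator, so mean RQ at t = 0 is 1 by construction. ΔΔCt is exactly
invariant to any constant added to all Ct values of one measurement cell.

Under transcription blockade, first-order decay gives log2 RQ(t) = −t/t½, so
half-life is estimated by OLS of log2(RQ) on time: t½ = −1/slope (hours per
halving), k = ln2/t½ per hour, R² reported. Log-linear OLS is preferred over
a nonlinear exponential fit because it is closed-form and matches
percent-remaining plots. Nonpositive RQ points are excluded with a warning;
fewer than 3 distinct timepoints → *indeterminate*. A transcript is
classified **stable** when its fitted half-life exceeds the observation
window or the slope is not significantly negative (one-sided p ≥ 0.05), and
**unstable** otherwise — the operational version of "no decay observed
within the experiment".

Cycloheximide (CHX) recovery — the signature of co-translational decay — is
the ratio of mean RQ under actinomycin D + CHX to mean RQ under actinomycin D
alone at a shared timepoint, with a seeded percentile bootstrap CI over
replicates (2,000 resamples by default).

## miRNA panel (`mirna_panel`)

Counts are normalized by total-count scaling to the mean library size
(geometric-mean-of-top-100 selectable; the method used is recorded). Fold
change is the ratio of normalized means (silenced / control); significance
follows the panel rule exactly: two-sided unpaired t-test p < 0.05 AND fold
change < 0.6 or > 1.5. The fc dead zone means small-but-precise shifts are
never called. The t-test runs on normalized counts by default (a log2 option
exists); with technical triplicates this tests measurement repeatability,
not biological variability — a caveat documented here rather than silently
"fixed", since the panel design has no biological replicates.

Changed miRNAs are classified by genomic context against host-gene models
using same-strand overlap: 3′UTR > exonic > intronic precedence (a 3′UTR is
exonic sequence, but 3′UTR-hosted miRNAs are a distinct regulatory class),
intergenic iff no same-strand gene-span overlap. The 3′UTR region is
intersected with exons before testing, so a miRNA inside an intron that
happens to fall between 3′UTR exons is still intronic. Host ties break by
largest overlap, then lexicographic gene id.

## Survival (`survival`)

Cohorts are stratified on an expression covariate into top and bottom
fractions (default quartiles): stable sort by (expression, sample id), exactly
floor(n/4) per group, middle half excluded. Group comparison uses the
Kaplan–Meier product-limit estimator, the two-group log-rank test, and a
hazard ratio from a proportional-hazards fit on a single binary group
covariate with Efron tie handling and a Wald 95% CI (a Mantel–Haenszel O/E
estimate with a Peto-style log-scale SE is the cross-check method). Zero
events in a group make the HR non-estimable; this is reported rather than
extrapolated. Estimation is delegated to lifelines; the test suite verifies
it against hand-coded product-limit and O−E oracles.

## Synthetic data (`synthetic_data`)

Each generator uses the simplest standard distribution for its data type, has
an explicit mandatory seed (no hidden global RNG), and is byte-identical
under a fixed seed.

| Generator | Model | Key defaults |
|---|---|---|
| `gen_probe_matrix` | latent L = 1000, S = ratio×L; probe reading × mean-one lognormal noise | 20+20 samples, S/L 1→3 (ln SLR effect = ln 2), noise CV 0.2 |
| `gen_apa_panel` | 50 probesets of 2+2 probes, a subset carrying the switch | 5/50 switch genes |
| `gen_isoform_tpm` | fraction ~ Dirichlet(group α), total ~ Gamma, TPM = fraction×total | α (12,4,2,2) → (4,12,2,2) dominance swap, 50/group, mean total 100 TPM |
| `gen_decay_cts` | Ct(t) = Ct₀ + t/t½ + N(0, σ); one PCR cycle per halving (efficiency 2, consistent with 2^−ΔΔCt) | σ = 0.2 cycles, 3 replicates, 0–12 h |
| `gen_mirna_counts` | NB counts, var = μ + φμ²; baseline μ ~ lognormal(6, 1); DE fold drawn from fc_range; matched toy host genes per context | 200 miRNAs, 10 DE, φ = 0.05, 3 technical replicates |
| `gen_survival` | exponential event times; top expression quartile has hazard × HR; per-stratum exponential censoring calibrated to the censor rate | n = 360, HR 2.7, 30% censoring |

Noise levels are realistic placeholders, not estimates from any dataset: the
assays emulated here do not publish per-sample variance structure. The
generators also deliberately omit several features of real data — probe
sequence affinity and cross-hybridization, array normalization artifacts,
isoform-mapping uncertainty in TPM estimates, qPCR efficiency differences,
NanoString background counts, and covariate-dependent (informative)
censoring. Passing tests therefore demonstrate that each statistic does what
it claims under its own model assumptions, not that those assumptions hold in
any particular cohort.

## Calibration results the suite verifies

- ln(SLR) equals an independent brute-force recomputation to 1e−12 relative
  tolerance; the 5 programmed switch genes occupy the top-5 p-value ranks in
  ≥ 95% of 200 seeded 50-gene panels; label permutation yields ~5% of genes
  at p < 0.05.
- ANOVA/Tukey agree with a textbook sums-of-squares / studentized-range
  oracle to 1e−10; the null rejection rate over 1,000 identical-Dirichlet
  repeats is ~5%.
- Noiseless decay recovers t½ to machine precision; at Ct noise 0.2 the
  median relative error at t½ = 3 h is well under 15% (100 simulations).
- The miRNA significance flag is bit-reproducible from the printed rule;
  false-positive rate ≈ 1% under the panel scenario. Sensitivity at a true
  fold change of 0.4 with three technical replicates measures ≈ 0.86: the
  raw-scale pooled t-test at NB dispersion 0.05 has intrinsic power ≈ 0.90
  even at saturating counts, and less at realistic count levels, so detection
  of 60% knockdowns from triplicates is not reliable above 90% — a property
  of the design, and the reason the log-scale test option exists.
- Log-rank type-I error under a true-HR-1 scenario lies in [0.035, 0.065]
  over 1,000 simulations; with true HR 2.7, n = 360, 60% censoring, the Cox
  estimate's median over 200 simulations is ≈ 2.7 with ≥ 90% CI coverage.

Problem sizes used by `scripts/acceptance.py` (100 screen seeds, 500 null
log-rank and ANOVA simulations, 200 HR recovery simulations) are the
package's standing choices for a single-CPU reproduction run; the test suite
uses the full design sizes above.

## Known limitations

- The SLR screen tests each probeset split independently; no multiple-testing
  correction is applied by default (BH is a flag).
- Per-sample-then-test is the only SLR comparison mode; pooled group-ratio
  testing is not implemented.
- Survival analysis is univariable; no multivariable Cox models or formal
  proportionality diagnostics.
- qPCR amplification efficiency is fixed at 2; no per-primer calibration.
- Real accession-scale inputs (CEL-derived intensity matrices, RSEM TPM
  compendia, relapse annotations) must be normalized upstream and supplied as
  the documented TSV formats; the package contains no download clients or
  CEL/RCC parsers.
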