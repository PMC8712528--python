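# isoswitch

Detection of 3′UTR isoform switches driven by alternative polyadenylation
(APA), and analysis of their downstream consequences — transcript stability,
miRNA co-regulation, and patient survival.

Many genes carry tandem poly(A) sites and produce mRNA isoforms that encode
the same protein but differ in their 3′ ends. In cancers, expression can
shift between these isoforms without any change in total gene expression,
swapping an unstable transcript for a stable one and thereby raising protein
output. This package provides a tested pipeline for finding such switches
and quantifying what follows from them, aimed at computational biologists
working with probe-level microarray intensities, transcript-level TPM
matrices, RT-qPCR decay time courses, miRNA panel counts, and clinical
survival tables.

## What it computes

**SLR statistic (probe-level APA detection).** On 3′-biased arrays, probes
5′ of a poly(A) site see all isoforms (short + long), probes 3′ of it see
only long isoforms. Per sample,

    SLR = mean(proximal intensities) / mean(distal intensities) = (S + L)/L,

reported as ln(SLR) and compared between groups with an unpaired t-test on
the log scale. A screen runs every probeset × poly(A)-site split, with QC
(straddling probes dropped, minimum probes per side, nonpositive distal
means excluded).

**Isoform fractions.** fraction = TPM_isoform / Σ TPM over the gene's
isoforms; one-way ANOVA + Tukey's HSD across sample groups per isoform, and
a formal switch call (reference-dominant isoform loses ≥ δ of mean fraction
while another isoform gains ≥ δ, both contrasts significant).

**Decay kinetics.** 2^−ΔΔCt quantification against a reference gene and the
t = 0 calibrator; half-life from OLS of log2(RQ) on time (t½ = −1/slope);
stable/unstable classification; cycloheximide recovery folds with bootstrap
CIs to detect co-translational decay.

**miRNA panel.** Library-size normalization, fold-change + t-test filtering
(significant iff p < 0.05 and fc < 0.6 or fc > 1.5), and genomic-context
classification of changed miRNAs (intronic / exonic / 3′UTR-hosted /
intergenic) against BED12/GTF gene models.

**Survival.** Quartile stratification on expression (top vs bottom 25%,
middle half excluded), Kaplan–Meier curves, log-rank test, and hazard ratio
with 95% CI (Cox fit with Efron ties; Mantel–Haenszel O/E as cross-check).

A `synthetic_data` module generates statistically matched inputs for every
stage (Dirichlet isoform usage, lognormal probe noise, negative-binomial
panel counts, exponential survival), so the whole pipeline is testable
without any downloads. See `docs/methods.md` for models, assumptions and
parameter choices.

## Worked example

Screen a 50-gene synthetic panel (20 tumor vs 20 normal samples) in which 5
genes carry a programmed 3′UTR switch of effect ln 2:

```python
from isoswitch.synthetic_data import gen_apa_panel
from isoswitch.apa_slr import run_apa_screen

matrix, probes, sites, switch_genes = gen_apa_panel(
    n_genes=50, n_switch=5, n_tumor=20, n_normal=20, seed=11)
results, rejected = run_apa_screen(matrix, probes, sites)
print(results.head(5).to_string(index=False))
```

```
gene_id  mean_ln_slr_normal  mean_ln_slr_tumor  mean_difference  t_statistic      p_value
GENE039            0.675248           1.362708         0.687460    13.969173 1.564870e-16
GENE030            0.672313           1.425816         0.753504    14.086374 2.214559e-16
GENE025            0.653803           1.376336         0.722533    13.000204 1.485168e-15
GENE007            0.638858           1.323160         0.684302    12.070833 2.273551e-14
GENE047            0.748740           1.362924         0.614183    11.496378 7.596439e-14
```

The five top-ranked genes are exactly the five programmed switches
(`switch_genes`); their mean ln(SLR) difference scatters around the true
effect ln 2 ≈ 0.693, and the t-tests separate them from the 45 null genes by
ten orders of magnitude in p.

Downstream, a survival contrast on a simulated 360-patient cohort with a
true hazard ratio of 2.7 between expression strata:

```python
from isoswitch.synthetic_data import SurvivalScenario, gen_survival
from isoswitch.survival import analyze_cohort

table = gen_survival(SurvivalScenario(n=360, true_hr=2.7,
                                      censor_rate=0.3, seed=11))
cohort, fit, km_high, km_low = analyze_cohort(table)
print(f"n={len(cohort.high_ids)}/{len(cohort.low_ids)}  "
      f"HR={fit.hazard_ratio:.3f} ({fit.ci_low:.3f}-{fit.ci_high:.3f})  "
      f"log-rank p={fit.logrank_p:.3g}")
```

```
n=90/90  HR=2.923 (1.994-4.284)  log-rank p=1.2e-08
```

Quartile stratification keeps 90 high and 90 low expressers; the estimated
hazard ratio of 2.92 covers the programmed 2.7 within its CI, and the
log-rank test rejects decisively.

Each stage is also exposed on the command line (`isoswitch simulate`,
`isoswitch apa`, `isoswitch fractions`, `isoswitch decay`, `isoswitch mirna`,
`isoswitch survival`); run `isoswitch --help` for options. Real datasets
enter through the same plain TSV / BED12 / GTF formats the simulators write.

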