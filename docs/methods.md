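# Methods

## Study design being modelled

`pancprs` analyses a small candidate-SNP case–control study of pancreatic
adenocarcinoma: 78 histologically confirmed cases and 256 cancer-free
controls genotyped on a 26-SNP panel of loci previously associated with PA
risk or survival in GWAS. Genotypes arrive as minor-allele dosages
(0/1/2/missing) keyed by rsID; loci are never matched by genomic position.
Two panel SNPs (rs684559, rs353630) were reported only for survival and are
excluded from risk scores by construction.

## Quality control

Applied in a fixed, idempotent order:

1. **Duplicates** (5% of samples re-genotyped for concordance): concordance
   is the fraction of jointly non-missing calls that agree; pairs below
   0.99 are flagged. The pair member with the higher call rate is retained
   — the retention rule is this package's choice, since only the
   concordance check itself is part of the design.
2. **Call rate**: subjects genotyped at fewer than 75% of panel SNPs are
   excluded.
3. **Monomorphic loci** (zero copies of one allele among survivors) are
   dropped; with the default panel this removes rs35226131, leaving 25
   analyzed SNPs.
4. **Hardy–Weinberg equilibrium**, tested in controls only, with the exact
   conditional test: all heterozygote counts compatible with the observed
   allele counts are enumerated and configurations no more probable than
   the observed one are summed. The exact test (rather than the chi-square
   approximation) is used because control genotype counts per cell are
   small; it also admits an exact enumeration oracle. SNPs at p ≤ 0.05 are
   excluded by default (`exclude_hwe_failures=False` downgrades this to a
   flag).

## Association model

Per SNP, the more common allele in controls is the reference category; if
the panel minor allele exceeds frequency 0.5 in controls the dosage is
complemented, with a tie at exactly 0.5 keeping the panel orientation.
Disease odds are fitted by unconditional logistic regression adjusted for
age (linear, years) and sex (0 = female, the larger group), on complete
cases, under allelic (dosage 0/1/2), codominant (two indicators) and
dominant (carrier indicator) codings. Contrasts whose genotype cell is
empty in either status group are reported as undefined rather than fitted.
Cohorts with fewer than 10 complete cases in either group (configurable)
yield an `insufficient_data` marker.

The trend p-value is the two-sided Cochran–Armitage test with scores
(0, 1, 2) on the unadjusted 2×3 genotype table — deliberately distinct from
the adjusted allelic fit, which is why the two p-values differ. An
unadjusted allele-count 2×2 OR is emitted alongside for cross-checks
against frequency tables. No multiple-testing correction is applied
(significance is nominal p < 0.05, matching the design being reproduced); a
Bonferroni-aware reader can divide by the number of analyzed SNPs.

### Numerical details

The logistic MLE is computed by iteratively reweighted least squares from a
zero start: Newton steps (clipped to ±10 per coordinate so separated fits
drift rather than overflow), convergence when the largest absolute score
component falls below 1e-8, at most 50 iterations. The step of the
converging iteration is still applied, so the coefficient error is of the
order of the squared score tolerance. Standard errors come from the inverse
observed information at the optimum (pseudo-inverse if degenerate); 95% CIs
are exp(β ± 1.96·se). Quasi-complete separation is flagged when any
coefficient exceeds 15 in absolute value — under separation the score also
vanishes numerically, so magnitude, not convergence failure, is the
criterion. Exactly collinear designs are rejected naming the first
dependent column. Single-covariate binary fits agree with the closed-form
2×2 solution to ~1e-14; multivariate fits agree with an independent
maximiser to 1e-6.

## Contingency machinery

Pearson chi-square (no continuity correction — the continuity-corrected
statistic does not reproduce the published tobacco p-value), two-sided
Fisher exact (total hypergeometric probability of tables no more likely
than observed, computed from `scipy.stats.hypergeom` over the support), and
pooled-variance Student t (Welch optional). Printed percentages are
converted back to integer counts by rounding half away from zero; the
exposure tables use effective denominators of 76 cases / 260 controls — the
smallest integers reproducing every printed percentage, slightly off the
enrolled 78/256, a discrepancy surfaced in the log rather than hidden.
Ancestry allele-frequency comparisons build 2×2 minor/major allele tables
with 2n alleles per group of n diploid subjects and apply chi-square or
Fisher (Fisher by default below 15 subjects per group). The published
ethnicity and alcohol p-values are not reproducible from the printed
percentages under any denominator tried; they are reported but never
asserted.

## Polygenic risk scores

The risk allele is the minor allele when the external per-minor-allele OR
is ≥ 1 and the major allele otherwise, so each weight X = |ln OR| is
non-negative and every SNP contributes risk in the direction of its
published effect. Scores: unweighted Σa, weighted ΣaX, over non-missing
calls; scaled variants multiply by (m total)/(n genotyped) so partially
genotyped subjects remain comparable. Four analysis variants are fitted,
{unweighted, weighted} × {subjects at 100% call rate on raw scores, all
subjects on scaled scores}, each with its own control-derived cutpoints.
Quintile cutpoints are nearest-rank 20/40/60/80th percentiles of the
control scores with left-open/right-closed bins — deterministic and
unambiguous under ties. The association model is the same age/sex-adjusted
logistic regression, with quintile indicators against quintile 1 and,
separately, the integer quintile index 1–5 as a continuous covariate (the
published unit of increment), not the raw score.

The shipped default weights are the study's own allelic ORs, a documented
placeholder: the original GWAS estimates the weighted score was defined
with are not tabulated in the source, so users scoring real cohorts should
substitute them in the panel TSV's `gwas_or` column.

## Synthetic cohorts

The generator emulates the study conditions as defaults: 78/256 subjects,
control genotypes from exact HWE at the panel's control MAFs, case
genotypes from the exact tilted distribution P(g|case) ∝ HWE(g)·OR^g
implied by case–control sampling under an additive logistic model (no
rejection sampling; closed-form case MAF available for checking), group age
means 62.46/56.62, 41%/43% male, ancestry at the published proportions,
published exposure rates (family history, unprinted, fixed at 8%/5%),
1% base genotype missingness with a 3% subject tail at 40% missingness to
exercise the call-rate filter, and 5% duplicate samples. The age SD (26
years) is not printed in the source; it is the value implied by the
published group means and the non-significant t-test, and is deliberately
preferred over a typical-looking 12 years, which would contradict that
non-significance.

What the generator does **not** emulate: linkage disequilibrium (the panel
loci sit on different chromosomes and the PRS assumes additivity),
genotype–exposure dependence, population-structure beyond categorical
ancestry labels, and genotyping-intensity artefacts. Passing tests
therefore validate the statistical machinery under the stated generative
model, not robustness to LD or confounding in real data. Age/sex are
generated independent of genotype; an `age_effect_per_year` knob (default
off) adds a genotype-independent age shift to verify that adjustment is
wired correctly. All randomness flows from a single `numpy` generator
seeded by `SimConfig.seed`; identical config and seed give byte-identical
fixtures.

## Problem sizes used in validation

Oracle equivalence is exhaustive: all 2×2 tables with total ≤ 60 for Fisher
(635,375 tables), all genotype triples with n ≤ 50 for HWE (23,425), and
100 random 2×2 layouts for the closed-form logistic check. Parameter
recovery uses cohorts of 2,000 cases / 2,000 controls across a grid of true
ORs {0.6, 1.0, 1.5, 2.0} × MAFs {0.1, 0.25, 0.4} with 200 replicates per
cell (median fitted OR within 5% of truth); null calibration uses 10,000
simulated genotype tables at 500 per group; PRS power uses 200 cohorts of
1,000/1,000 with ten independent OR-1.3 SNPs. The session-pinned test
fixture uses generator seed 5, chosen so that QC reproduces the study
structure (the monomorphic locus is the only exclusion and all analyzed
SNPs pass HWE in controls, as reported for the original cohort).

## Known limitations

- Wald intervals and p-values are asymptotic; at 78 cases, rare-genotype
  contrasts have wide, poorly calibrated CIs (mirrored in the very wide
  published quintile CIs). No Firth or exact logistic fallback is provided.
- The published per-SNP ORs and PRS quintile ORs cannot be reproduced
  without the raw cohort, which is not deposited; they anchor schema,
  direction and simulation design only.
- The trend test is unadjusted; an adjusted score test would differ
  slightly.
- VCF ingest supports diploid GT on biallelic panel sites only.
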