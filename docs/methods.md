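# Methods

## Model

The package computes an odds-ratio-weighted, population-standardized
polygenic score. For SNP *i* with per-allele odds ratio `OR_i` (from
external GWAS) and risk-allele frequency `f_i` (from a reference
population), an individual carrying `g_i ∈ {0,1,2}` risk alleles scores

    GRS = ∏_i OR_i^{g_i} / W_i,
    W_i = f_i² OR_i² + 2 f_i (1−f_i) OR_i + (1−f_i)².

`W_i` is the expectation of `OR_i^g` when `g` follows Hardy–Weinberg
genotype frequencies `((1−f)², 2f(1−f), f²)`, so each factor — and hence the
product over independent SNPs — has population mean exactly 1. The score is
therefore interpretable as a relative risk against the general population,
and "mean GRS ≈ 1 in controls" is a built-in calibration check: deviation
signals allele-orientation errors, wrong reference frequencies, or a
non-representative control set.

Assumptions: SNPs are independent (enforced operationally by pruning to
pairwise dosage r² < 0.2), allelic effects multiply within and across loci,
and the external OR and f refer to the same allele on the same strand as the
genotypes after alignment.

### Case model

The per-SNP genotype distribution among cases consistent with a
multiplicative per-allele odds ratio is the tilted law
`P(g|case) = OR^g P(g) / W`; its normalizer is exactly `W`. Under it, the
expected per-SNP score factor is `E[OR^{2g}]/W² =
(f²OR⁴ + 2f(1−f)OR² + (1−f)²)/W²`, and the expected case GRS is the product
over SNPs (`analytic_case_mean_grs`). It is ≥ 1 with equality only when
every OR is 1. The synthetic-cohort generator samples cases from this law
and controls from plain HWE, which makes the generator and the analysis
share a single coherent model: simulated studies must recover the input ORs
from 2×2 allele counts and the closed-form case mean, and the test suite
checks both.

## Parameters and conventions

- **Risk strata**: low is GRS < 0.5, high is GRS > 1.5, average is the
  closed interval between — scores exactly at a cutpoint are average,
  because the defining inequalities of the extreme groups are strict.
  The average stratum is the odds-ratio reference.
- **Stratum OR and CI**: cross-product OR against the reference with a Wald
  interval, `exp(log OR ± z_{1−α/2}·√(Σ 1/cell))`, α = 0.05 by default.
  This choice reproduces published stratified ORs and their intervals at
  printed precision (checked in the acceptance tests). A stratum with zero
  cases reports OR 0 with an undefined (NaN) upper bound; no
  Haldane–Anscombe correction is applied unless requested.
- **Stratum p-value**: 1-df Pearson chi-square on the 2×2 without
  continuity correction; Fisher's exact test by flag for sparse cells.
- **Trend**: Cochran–Armitage with equally spaced scores (0,1,2), identical
  to R's `prop.trend.test`. Two-sided p from the signed z.
- **Rank-sum**: exact enumeration when the pooled sample is ≤ 12 with no
  ties, otherwise the normal approximation with tie and continuity
  corrections (scipy's Mann–Whitney implementation).
- **Mean-GRS summaries**: arithmetic mean with a normal-approximation CI.
- **Missing genotypes**: the default `skip` policy omits the SNP's factor
  (equivalently contributes its population-mean factor of 1); `mean_dose`
  imputes `g = 2f` before exponentiation. The policy is recorded in run
  logs. No genotype imputation is attempted.
- **Allele orientation**: VCF dosages count ALT alleles; alignment leaves
  dosages unchanged when the risk allele is ALT, reflects `g → 2−g` when it
  is REF, and otherwise strand-complements the catalog alleles and applies
  the same rules. A strand-ambiguous SNP (A/T or C/G) whose alleles match
  the VCF directly is aligned as-is; frequency-based strand disambiguation
  is deliberately not attempted. Note that for a biallelic site whose
  catalog allele *pair* equals the VCF pair, one direct orientation always
  matches — so a silent strand flip at an ambiguous SNP is undetectable
  from allele labels alone, which is precisely why such SNPs deserve
  suspicion in real data.
- **LD pruning**: greedy in catalog order (the earlier-listed SNP of a
  correlated pair wins); r² is the squared Pearson correlation of dosage
  vectors over pairwise-complete subjects. Deterministic and reproducible;
  other tie-breaks (e.g. keep the larger |log OR|) would be defensible.
- **Multiple testing**: none across cancer types; reported p-values are raw.
- **Numerics**: GRS products accumulate in log space (panels approaching
  ~80 SNPs would otherwise risk float extremes); closed forms are compared
  at relative tolerance 1e−9 in tests.

## Synthetic cohorts

`simulate_study` draws case and control genotypes i.i.d. per SNP from the
tilted and HWE laws above, assigns sex by a Bernoulli ratio (default 0.5),
and optionally masks genotypes uniformly at random (`missing_rate`). One
master seed spawns separate child streams for cases, controls, sex and
missingness, so growing one arm leaves the others' draws untouched. Default
study sizes used in the test suite reflect the scale at which the method's
properties are measurable on one CPU in seconds: 50 000 subjects for
calibration checks (Monte-Carlo SE ≈ 0.003 on the mean), 1000 cases /
10 000 controls with a 19-SNP panel (ORs 1.1–1.4) for the dose-response
study.

What the generator emulates: HWE genotype frequencies, multiplicative
case enrichment, independent SNPs, sex labels, uniform missingness. What it
does not: population structure and admixture, genotyping error, LD between
panel SNPs, imputation uncertainty, covariates (age, sex effects on risk),
and ascertainment quirks of real cohorts. Passing tests therefore
demonstrate that the implementation is faithful to the model, not that the
model captures every feature of real case/control data.

## Design choices where the design was open

- The case simulator uses the exact tilted-HWE law rather than a
  liability-threshold model: it is the unique genotype law consistent with
  the per-allele OR weights, makes `W` its normalizer, and admits the
  closed-form case mean used as an oracle.
- Risk-allele frequencies always come from the catalog (external reference
  population), never re-estimated from the cohort: standardization is
  against the general population, not the study sample.
- Monomorphic catalog SNPs (f exactly 0 or 1) are rejected by default —
  `W` degenerates and the SNP carries no information — but can be allowed
  explicitly (`allow_monomorphic`), in which case a fixed allele simply
  contributes a constant factor.
- Catalog files are headered TSV rather than any array-vendor format;
  VCF is the single genotype interchange format.

## Known limitations

- The asymptotic Cochran–Armitage p is anticonservative on very small
  tables: the permutation null is lattice-valued and its ≥-tie tail can be
  about twice the asymptotic p on tables of a dozen subjects. The test
  suite's permutation cross-checks use small tables whose null has enough
  support for the approximation to hold; for real tables that small, use
  an exact or permutation test.
- Wald intervals are poor near zero cells; the printed `0 (0–NaN)`
  convention is reproduced deliberately rather than papered over.
- Strand-ambiguous SNPs are aligned on label match alone (see above); in
  real multi-array studies this can silently flip effects, and panels
  should avoid A/T and C/G SNPs or resolve them upstream.
- `mean_dose` missingness treats `OR^{2f}` as the missing factor, which is
  not the same as the population-mean factor 1 used by `skip`; with many
  missing genotypes the two policies diverge and the choice should be
  reported.
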