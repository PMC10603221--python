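# Methods

This note documents the statistical conventions, the synthetic-data
model, and the numerical choices behind `endoassoc`, in the spirit of a
model-description vignette.

## Study design being modelled

A hospital-based case-control study: 473 women with histologically
confirmed ovarian endometriosis (staged I–IV by the rASRM system) and 459
healthy female controls, genotyped at three biallelic *WTAP* SNPs
(rs1853259 A>G, rs7766006 G>T, rs9457712 G>A).  All analyses treat
case/control status as the outcome and genotype (or derived scores) as
exposure; age, gravidity and parity are the available covariates.
Controls carry no rASRM stage, so stage-stratified analyses compare
stage-restricted cases against the full control group.

## Single-locus statistics

* **Genotype orientation.** Major/minor alleles are declared per marker,
  never re-estimated, so the genotype classes (major-hom, het, minor-hom)
  keep a stable meaning in subsamples.
* **HWE.** 1-df Pearson goodness of fit of control genotype counts against
  (p², 2pq, q²) with p̂ estimated from the same counts.  An exact test
  (conditional enumeration of heterozygote counts given allele counts) is
  available for small groups via `hwe_exact`.  A monomorphic marker is
  flagged undefined rather than raising.
* **Genotype distribution.** 2-df Pearson χ² on the 2×3 table; genotype
  columns with zero total are dropped with a matching df reduction.
* **Trend.** Cochran–Armitage score test with scores (0, 1, 2);
  `T = Σtᵢrᵢ − (R/N)Σtᵢnᵢ`, `Var(T) = RS[NΣtᵢ²nᵢ − (Σtᵢnᵢ)²]/[N²(N−1)]`.
  The trend z² is always ≤ the 2-df Pearson statistic (it is its 1-df
  dose-response component); this is asserted as a property test.
* **Odds ratios.** Woolf estimate with Wald intervals using
  z = 1.959964.  A structural zero cell yields an undefined, flagged
  result (the "−" cell of haplotype tables); an optional continuity
  correction adds 0.5 to every cell instead.
* **Additive model.** The point estimate is the genotype-dosage (0/1/2)
  logistic coefficient, fitted as a binomial GLM on the three genotype
  rows; its p-value is the Cochran–Armitage p.  This pairing reproduces
  the convention of the anchoring study, where the printed additive
  p-values match the trend test exactly while the printed additive OR sits
  slightly above the allele-count OR.  The allele-count ("allelic") OR is
  also exposed.
* **Adjusted estimates.** Unconditional logistic regression
  (Newton–Raphson via statsmodels; max 100 iterations, tolerance 1e-10,
  Wald SEs from the inverse observed information), complete-case per
  contrast.  The covariate list is a parameter because the source tables
  footnote two different adjustment sets.  Perfect separation is flagged
  as non-convergence; rank-deficient designs raise an error naming the
  collinear columns.  Note that adjusted and crude ORs are *not* expected
  to coincide exactly even under null covariate effects (finite-sample
  covariate-genotype correlation, non-collapsibility of the OR); tests
  therefore check closeness and confounding-correction behaviour, not
  identity.

## Haplotype inference

EM over unphased multilocus genotypes, run separately within cases and
controls (group-specific frequencies are the direct analogue of published
group-specific chromosome counts; a pooled mode that splits expected
counts by group is available).  The E-step weights each compatible
unordered haplotype pair (h, k) by (2 − δ_hk)·f_h·f_k; the M-step divides
expected haplotype counts by 2n.  Initialisation is the
linkage-equilibrium product of single-locus allele frequencies plus five
seeded Dirichlet restarts (EM on three SNPs is mildly multimodal in small
samples); the best likelihood is kept.  Convergence: maximum frequency
change < 1e-8 or 1000 iterations; the per-iteration log-likelihood trace
is retained and asserted non-decreasing in tests.  Genotype patterns are
iterated in sorted order so results are exactly independent of subject
order.

Haplotype association contrasts expected chromosome counts against a
reference haplotype with the same Woolf/Wald machinery, treating
chromosomes as independent (this reproduces the published intervals);
counts are never rounded before analysis, and expected counts below 1e-3
chromosomes are treated as absent.  Adjusted haplotype ORs come from one
logistic fit on posterior-expected haplotype dosages (reference dosage
omitted as baseline), covariates added.  Pairwise LD is computed from
two-locus EM frequencies: D = f(AB) − p_A·p_B oriented on major alleles,
D′ = D/D_max, r² = D²/(p_A q_A p_B q_B).

## Combined risk genotypes

Each marker declares a risk-genotype set (here: rs1853259 AG/GG,
rs7766006 GG, rs9457712 AA); a subject's score is the count of markers at
which they carry one.  The default top-code of 2 makes the top category
"two or more", the only reading under which the published three categories
exhaust the full cohort.  Subjects missing any scored genotype are
excluded and tallied.  Per-category ORs use category 0 as reference; the
trend test runs over scores 0..top_code.

## Credibility statistics

* **Power.** With z_c the two-sided critical value at the observed
  p-value and δ = |ln OR_design|/SE: power = 1 − Φ(z_c − δ) + Φ(−z_c − δ).
  The design OR defaults to 1.50 for risk effects and 0.67 for protective
  effects (the anchoring study's stated values; 0.67 is kept verbatim
  rather than 1/1.5, and both conventions are reachable through
  parameters).  The observed p enters at printed precision when
  reproducing published tables, matching how such tables are built from
  reported values.
* **SE of ln OR.** From 2×2 counts (√Σ1/cell) when available, else from
  the reported CI: (ln high − ln low)/(2·1.959964).  `se_mode="auto"`
  prefers counts; printed-table reproductions use CI mode uniformly.
* **FPRP.** α(1−π) / (α(1−π) + power·π); noteworthy below 0.2.  Power 0
  maps to FPRP 1 by continuity.
* **BFDP.** Normal prior on the log OR whose 97.5% point sits at OR 1.5
  (W = (ln 1.5 / 1.959964)²; only |ln w| matters, so protective anchors
  work unchanged), ABF = √((V+W)/V)·exp(−θ̂²W/(2V(V+W))),
  BFDP = ABF·PO/(1+ABF·PO); noteworthy below 0.8, a threshold derived
  from weighting a false non-discovery four times a false discovery.
* FPRP and BFDP are strictly decreasing in the prior; FPRP is increasing
  in α and decreasing in power (property-tested).
* `credibility_table` rejects inputs that are not significant at the
  configured α (default 0.05) unless explicitly overridden — the override
  exists because published credibility tables sometimes include rows
  selected on an adjusted rather than crude p-value.

## Synthetic cohorts

The simulator emulates the study design, not any one dataset:

* Two haplotypes per subject drawn i.i.d. from a population haplotype
  frequency vector (default: the eight three-SNP haplotype frequencies
  implied by the published 918 control chromosomes), which fixes both
  allele frequencies and LD and makes genotypes Hardy–Weinberg at the
  population level.
* Disease from a prospective logistic liability: baseline logit −2.2
  (≈10% source-population prevalence) plus per-SNP effects (default
  per-allele ORs 1.28 / 0.78 / 1.0, the published crude additive
  estimates) plus optional covariate terms.  Subjects are accumulated by
  rejection sampling until exactly n_cases and n_controls are collected
  (default 473/459), emulating retrospective ascertainment; under
  case-control sampling the genotype ORs of the generating model are
  preserved, which the parameter-recovery test exercises at n=5000/5000.
* Covariates are independent of genotype by default: age from a truncated
  normal (mean 31.1, sd 7.0, bounds 18–55, matching the control
  descriptives), gravidity and parity from small categorical
  distributions calibrated to the published ≤1/>1 splits (85% / 88%).  A
  confounding switch adds a per-minor-allele shift to age for tests of
  covariate adjustment.  rASRM stage is sampled for cases only from the
  published distribution (73.78 / 21.99 / 3.17 / 1.06%), independent of
  genotype.
* Genotype calls are masked missing i.i.d. at rate 0.02 (within the >95%
  completion the study reports).
* One seeded generator drives everything; identical configurations give
  identical cohorts, byte-for-byte through write/read round-trips.

What the simulator does **not** model: genotyping-chemistry error
profiles, population stratification, relatedness, covariate-genotype
dependence (except the explicit confounding switch), genotype-dependent
stage, or missingness that is informative.  Passing tests on simulated
data therefore demonstrate correctness of the estimators under the stated
generative model, not robustness to those real-data complications.

## Published-table fixtures and their quirks

The published aggregate counts (genotype tables, stratum counts,
haplotype chromosome counts, and the credibility-table rows) ship as
machine-readable fixtures; all crude results are recomputed from them in
the test suite.  A small number of printed cells are internally
inconsistent with their own printed counts (single last-digit
discrepancies in several Wald CI bounds; two clearly corrupted stratified
rows, notably rs1853259 age ≤ 30, whose counts give OR 1.28 against a
printed 1.56; and a handful of power/BFDP entries irreproducible from
their own row's OR/CI/p under any Wald convention).  Tests assert the
stated tolerances wherever print and counts reconcile and pin the
recomputed value for the documented exceptions — the headline
noteworthiness tallies (15/17 FPRP-noteworthy and 17/17 BFDP-noteworthy
at π = 0.25; 4 noteworthy in both at π = 0.1; none at π = 0.01) reproduce
exactly.

## Numerical and scale choices

* Normal quantile 1.959964 for all 95% intervals.
* Chi-square p-values via `scipy.stats.chi2.sf`; no continuity
  corrections anywhere (matching the printed descriptive p-values).
* EM-vs-brute-force oracle checks run on ≤6-subject instances against a
  Nelder–Mead maximiser over the softmax-parameterised simplex with
  multiple restarts; agreement 1e-6 in log-likelihood, 1e-4 in
  frequencies.
* Property and calibration tests use deliberately modest sizes (e.g. 100
  HWE replicates at n=150+150, 200 null-coverage replicates at n=220+220,
  50 parameter-recovery replicates at n=5000+5000), chosen to give stable
  seeded verdicts at desk scale.
* The pipeline writes ORs/CIs to 2 decimals and p-values to 3 in rendered
  tables, keeping full precision in `summary.json` (rounded to 6
  decimals for byte-stable output).

## Known limitations

* No conditional or exact logistic regression; sparse strata are flagged
  undefined rather than analysed exactly.
* The EM implementation enumerates all 2^k haplotypes of k SNPs — fine
  for candidate-gene panels, not for dozens of markers (no
  partition-ligation).
* Haplotype-level variance treats chromosomes as independent; no
  subject-level correction is applied (by design, to match the anchoring
  convention).
* FPRP/BFDP are reported as credibility diagnostics, not a substitute
  for replication; no FDR/q-value machinery is included.
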