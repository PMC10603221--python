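# `run-all` output bundle

`endoassoc run-all` (or `endoassoc.pipeline.run_all`) writes the
following files into the output directory.  All TSVs are UTF-8 with a
header row; `NA` marks undefined statistics (flagged contrasts).  Odds
ratios and CI bounds are rendered to 2 decimals, p-values to 3.

| file | contents |
| --- | --- |
| `cohort.tsv` | the analysed cohort (only written when simulated) |
| `table_qc.tsv` | per SNP: call rate, control MAF, control HWE p, pass flag |
| `table1_descriptives.tsv` | covariate summaries with t / chi-square p-values |
| `table2_single_locus.tsv` | per SNP and contrast: OR, CI, p (crude and adjusted), HWE p, genotype-distribution p, trend p |
| `table2_combined_counts.tsv` | risk-score category counts per group |
| `table2_combined_assoc.tsv` | per-category ORs vs the zero-risk reference |
| `table3_stratified.tsv` | per stratum and SNP contrast: collapsed 2x2 counts, crude (and adjusted) OR/CI/p, defined flag |
| `table4_haplotypes.tsv` | expected chromosome counts per haplotype and haplotype-vs-reference OR/CI/p |
| `ld_pairwise.tsv` | D, D', r^2 per SNP pair |
| `table5_credibility.tsv` | per significant crude result: OR/CI/p, power, FPRP and BFDP per prior |
| `summary.json` | machine-readable summary (below) |

## `summary.json`

```jsonc
{
  "n_cases": 473,
  "n_controls": 459,
  "snps": ["rs1853259", "rs7766006", "rs9457712"],
  "seed": 2023,
  "qc": [
    {"snp_id": "...", "call_rate": 0.97, "maf_controls": 0.36,
     "hwe_p_controls": 0.11, "pass": true}
  ],
  "single_locus": [
    {"snp_id": "...", "contrast": "dominant", "or": 1.23, "p": 0.04,
     "adjusted": false}          // or/p null when undefined
  ],
  "combined_risk": {
    "labels": ["0", "1", "2+"], "cases": [..], "controls": [..],
    "p_trend": 0.01
  },
  "haplotype": {
    "reference": "AGG", "haplotypes": [..],
    "case_counts": [..], "control_counts": [..]   // expected chromosomes
  },
  "n_significant": 7,
  "credibility": [
    {"label": "...", "power": 0.4, "fprp": [..3 values..],
     "bfdp": [..3 values..]}     // at priors 0.25, 0.1, 0.01
  ]
}
```

Floats are rounded to 6 decimals; key order is sorted.  Two runs with
the same configuration and seed produce byte-identical bundles.
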