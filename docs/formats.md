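# File formats

All tables are UTF-8, tab-separated, `.` decimal separator, `NA` for
missing values.  Floats are written with `%.17g` and parsed with
round-trip precision, so every write/read pair is bit-identical.
Node indices are 0-based internally; node *labels* in files are the
1-based `regionNNN` names.

## Genotypes

- `dosages.tsv` — first column `subject_id`, one column per SNP id;
  cells are effect-allele counts in {0, 1, 2} or `NA`.
- `snp_meta.tsv` — index `snp_id`; columns `effect_allele`, `phenotype`,
  `phenotype_group` (psychiatric | neurological | behavior-cognition |
  brain-morphology-function | control), `gwas_p`, `maf`.

## Connectomes

One square TSV per subject (`connectome_<subject>.tsv`, row/column
headers are node labels) plus `manifest.tsv` with columns `subject_id`,
`file`.  Matrices must be symmetric within 1e-10.

## Covariates

`covariates.tsv` — index `subject_id`; columns `age` (years), `sex`
(0/1), `scanner` (categorical string), `gaf1..gafK` (continuous).

## Behaviors

`behaviors.tsv` — header row of variable names, then a second header row
starting with `type` declaring `continuous` or `dichotomous` per
variable, then one row per subject.

## Summary statistics

`sumstats.tsv` — columns `SNP`, `A1` (effect allele), `BETA`, `P`.

## Catalog / proxy tables (SNP selection)

Catalog: columns `snp_id`, `phenotype`, `phenotype_group`, `gwas_p`
(one row per SNP × phenotype).  Proxies: `index_snp_id`,
`proxy_snp_id`, `r_squared`.

## Derived outputs (run directory)

- `selected_snps.tsv` — selection with `provenance`
  (`direct` | `proxy-of-<snp>`) and `r_squared`.
- `edge_index.tsv` — `edge_id`, `node_i`, `node_j` (row-major upper
  triangle, 0-based).
- `canonical_scores.tsv` — per-subject `genetic_score`,
  `connectomic_score` (mode 1, oriented).
- `genetic_strengths.tsv` / `connection_strengths.tsv` —
  `feature_id`, `strength`, `p`, `q`, `group`.
- `mode_summary.json`, `prs_summary.json`, `behavior_summary.json`,
  `robustness.json`, `manifest.json` (stages, seeds, config hash).
- `ground_truth.json` — everything the generator planted.
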