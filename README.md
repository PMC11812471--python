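# conformalprs

Panel-based polygenic risk scores (PRS) with Mondrian cross-conformal
disease-status prediction, built around a 47-variant AMD (age-related
macular degeneration) risk panel.

The package covers the full diagnostic pipeline:

- **`conformalprs.panel`** — load a risk-variant panel (TSV), orient
  protective variants to risk (OR ≥ 1, effect weight = ln OR), and apply
  a low-coverage exclusion list. A 52-variant demonstration panel and its
  5-variant exclusion list are bundled.
- **`conformalprs.prs`** — extract risk-allele dosages from a VCF,
  strong-effect missingness QC, weighted PRS
  (`Σ dosage·w / mean(w)` — "risk alleles of average effect"), quintile
  thresholds (published constants `25.3 / 29.9 / 34.5 / 39.1` or derived
  from a reference cohort) and risk groups 1–5.
- **`conformalprs.cohort`** — synthetic cohorts: Hardy–Weinberg
  genotypes, logistic liability on dosage + age + sex, and a preset that
  reproduces the reference study's structure (1,667 / 1,148 training and
  14,209 / 16,566 validation cases / controls).
- **`conformalprs.conformal`** — k-fold Mondrian cross-conformal
  prediction of case/control from (PRS, age, sex): per-class p-values
  with class-conditional validity, prediction sets at significance ε,
  point labels and a probability of being affected. JSON model
  serialization.
- **`conformalprs.evaluate`** — sensitivity/specificity, error rates
  stratified by risk group × age bin × sex, conformal validity curves,
  quintile fractions and population projections.
- **`conformalprs.cli`** — `conformalprs` command-line front end.

## CLI

Every artifact is stamped with the seed and a configuration hash; fixed
seeds give byte-identical outputs.

```sh
conformalprs simulate --out sim/ --seed 7 --n-cases 500 --n-controls 500
conformalprs score    --vcf sim/cohort.vcf --out prs.tsv --thresholds preset
conformalprs fit      --prs prs.tsv --phenotypes sim/cohort.phenotypes.tsv \
                      --out model.json --k-folds 5 --seed 7
conformalprs predict  --model model.json --prs prs.tsv \
                      --phenotypes sim/cohort.phenotypes.tsv \
                      --out predictions.tsv --epsilon 0.2
conformalprs evaluate --predictions predictions.tsv --prs prs.tsv \
                      --phenotypes sim/cohort.phenotypes.tsv --out eval/
conformalprs project  --fraction 0.27 --base 300000
```

`simulate --preset` emits the full-size training/validation cohorts. A
YAML file via `--config` supplies per-subcommand option defaults.

## File formats

- Panel TSV: `rsid chrom pos ref alt risk_allele odds_ratio locus`
  (+ optional `risk_allele_freq`); exclusions TSV: `rsid reason`.
- Genotypes: VCF (GT genotypes, biallelic records).
- Phenotypes TSV: `id status age sex`; PRS TSV: `id prs n_missing
  risk_group`; predictions TSV: `id p_case p_control label_set
  point_label prob_affected`.
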