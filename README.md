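# sigstrat

Signature-based tumor stratification and survival analysis.

`sigstrat` turns two-condition expression data into directed gene
signatures, classifies tumor samples by thresholded signature-gene
counting with a one-sided Fisher exact test against the cohort average,
crosses two signatures (RA-decreased x ERK-increased) into a four-way
category, and relates categories — and stability-selected expression
clusters — to survival and relapse-free survival.

## What's inside

| module | purpose |
| --- | --- |
| `sigstrat.stats` | exact Fisher 2x2 (integer tail sums), BH adjustment, one-way ANOVA, Kruskal–Wallis, Wilcoxon rank-sum (exact/asymptotic), Pearson correlation matrix |
| `sigstrat.signatures` | fold-change + significance signature derivation, DE-table filtering, GMT / gene-list IO |
| `sigstrat.classify` | per-sample thresholded counting, Fisher calls vs cohort average, four-way category, Z-score classification, change-enrichment test, signature scores |
| `sigstrat.survival` | Kaplan–Meier estimator, k-group and pairwise log-rank, gatekept Kruskal–Wallis / Wilcoxon on uncensored times, events-only curves |
| `sigstrat.stability` | Lloyd k-means (best-of-n_init), bootstrap-Jaccard cluster stability, data-driven choice of k |
| `sigstrat.simulate` | synthetic cohorts with planted categories, anti-correlated signature scores, and proportional-hazards survival |
| `sigstrat.io` / `sigstrat.pipeline` / `sigstrat.cli` | TSV IO with validation, end-to-end driver with JSON manifest, `sigstrat` CLI |

Key conventions (all recorded in run manifests):

- "more than N-fold" is a strict inequality on the log2 mean difference;
  significance cutoffs are non-strict on adjusted p.
- Counting thresholds are inclusive (`-0.5` or under; `1` or over) and
  applied directly to the supplied (already normalized) log2 values.
- The per-sample Fisher table compares the sample's count to the rounded
  (ties-to-even) cohort-average count over the signature size, one-sided
  greater, positive call at p < 0.1.
- Survival ties: deaths precede censorings. The k-group log-rank reports
  sum (O-E)^2/E with df = k-1; pairwise tests use the hypergeometric
  variance form.
- Events-only curves condition on the outcome; they are descriptive, not
  estimates of the survival function.

## CLI

```bash
# synthetic cohort with planted truth
sigstrat simulate --seed 7 --out-dir sim/

# derive a signature (3-fold, ANOVA + BH-FDR 0.05)
sigstrat derive-signature --expr sim/expression.tsv --groups groups.tsv \
    --condition condition --control control --fold 3 --alpha 0.05 --out sig.gmt

# four-way classification
sigstrat classify --expr sim/expression.tsv --ra-sig sim/ra_signature.gmt \
    --erk-sig sim/erk_signature.gmt --low -0.5 --high 1 --alpha 0.1 --out strat.tsv

# KM curves + log-rank per category
sigstrat survival --clinical sim/clinical.tsv --strata strat.tsv \
    --endpoint os --out-dir surv/

# bootstrap-Jaccard stability over k = 2..10
sigstrat stability --expr sim/expression.tsv \
    --sigs sim/ra_signature.gmt,sim/erk_signature.gmt \
    --k-range 2:10 --n-boot 100 --seed 17 --out stability.tsv

# everything at once (here on a fresh simulated cohort)
sigstrat run-all --simulate --seed 7 --out-dir run/
```

Exit codes: 0 success, 2 validation error, 3 computation error. Every
pipeline run writes a `manifest.json` naming the package version, seed,
config hash, and the convention decisions above.

### File formats

- Expression TSV: first column `gene_id`, one column per sample, log2
  values, `NA` for missing.
- Clinical TSV: `sample_id, os_time, os_event, rfs_time, rfs_event,
  subtype` (events 0/1, `NA` allowed).
- Signatures: standard GMT or a one-gene-per-line text file.

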