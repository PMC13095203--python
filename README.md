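# clearseq

Molecular subtyping of clear-cell renal cell carcinoma (ccRCC) from bulk
expression data. Starting from a raw gene × sample count matrix, the package

1. **preprocesses** counts: CPM-based gene filter (CPM > 1 in ≥ 50 samples),
   library-depth sample filter (> 500,000 counts over retained genes),
   median-of-ratios size factors, a log-like variance-stabilizing transform,
   and parametric empirical-Bayes batch correction;
2. **scores eight gene signatures** (`ccrcc3_up`, `ccrcc3_down`, `ccrcc2_up`,
   `ccrcc1_up`, `ccrcc4_up`, `ccrcc1and4_up`, `cell_cycle`, `t_effector`) as
   the per-sample median (or mean, for single-cell data) of member-gene
   expression;
3. **assigns ccrcc1–4 subtype labels** with a four-step percentile decision
   tree (20/50/64/75 percentile rules for ccrcc3, then 50th-percentile
   ccrcc2 rule, then 40%-upper ccrcc4 rule), recording the realized cutoffs
   so they can be reapplied as absolute cutoffs to small cohorts or single
   samples;
4. **trains an SVM single-sample classifier** on decision-tree labels:
   subset to signature genes, rescale each sample to a constant sum, score,
   standardize, fit a linear SVM with Platt-coupled class probabilities
   ("confidence values"), evaluated by multiclass Matthews correlation;
5. **simulates synthetic cohorts** (negative-binomial counts with planted
   subtype archetypes and multiplicative batch effects, or direct
   signature-score matrices) so every stage is testable without external
   data.

## CLI

All tabular I/O is TSV with headers (matrices: first column = gene IDs,
header row = sample IDs); cutoffs, models, and configs are JSON. Signature
definitions are GMT or two-column TSV.

```sh
# synthetic cohort: counts.tsv, meta.tsv, truth.tsv, signatures.gmt
clearseq simulate --n-samples 300 --effect-size 4 --seed 1 --out-prefix sim/

# step by step
clearseq preprocess --counts sim/counts.tsv --meta sim/meta.tsv \
    --min-samples 20 --min-total 10000 --out expr.tsv
clearseq score --expr expr.tsv --signatures sim/signatures.gmt --out scores.tsv
clearseq classify --scores scores.tsv --out calls.tsv --out-cutoffs cutoffs.json

# single samples / small cohorts with previously realized cutoffs
clearseq classify --scores new_scores.tsv --mode fixed --cutoffs cutoffs.json \
    --out new_calls.tsv

# single-sample SVM
clearseq train-svm --expr expr.tsv --labels calls.tsv \
    --signatures sim/signatures.gmt --seed 7 --out model.json
clearseq predict --model model.json --expr new_expr.tsv \
    --signatures sim/signatures.gmt --out predictions.tsv

# compare two call sets (counts + row percentages)
clearseq concordance --calls-a calls.tsv --calls-b predictions.tsv --out table.tsv

# end-to-end with a config file (unknown keys rejected; flags override file)
clearseq run --counts sim/counts.tsv --meta sim/meta.tsv \
    --signatures sim/signatures.gmt --config config.json --outdir out/
```

The filter defaults (CPM 1 / 50 samples / 500,000 depth) assume a deeply
sequenced cohort of several hundred samples; scale them down for small or
shallow datasets (`--min-samples`, `--min-total`, or config keys).

## Library

```python
import clearseq as cs

cohort = cs.simulate_counts(cs.SyntheticSpec(n_samples=300, effect_size=4, seed=1))
expr = cs.run_preprocess(cohort.counts, cohort.metadata,
                         cs.PreprocessConfig(min_samples=20, min_total=10_000))
scores = cs.score_all(expr, cohort.registry)           # median aggregator
result = cs.classify_cohort(scores)                    # percentile tree
cutoffs = cs.extract_cutoffs(result)                   # fixed-cutoff reuse
bundle, heldout_mcc = cs.train_from_expression(
    expr, cohort.registry, result.labels, seed=1)
calls = cs.predict(bundle, expr, cohort.registry)      # works for 1 sample
```

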