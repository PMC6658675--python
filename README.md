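# cascadewx

Survival-aware gene selection for bulk transcriptome cohorts, built
around a cascaded classifier-weight screen and a neural
proportional-hazards evaluator.

## The problem

Given an RNA-seq expression matrix (samples × genes, RSEM-style
normalized counts) and right-censored clinical follow-up (time in days,
censoring indicator), which genes carry prognostic information? With
d ≈ 20,000 genes and only a few hundred patients, survival models
cannot be fit on everything at once; the practical route is to rank
genes first and evaluate growing top-k signatures.

## The method

**Cascaded selection.** Patients are dichotomised at widening year
cutoffs over three steps — died within 3 years vs lived beyond 3; then
2 vs 4; then 1 vs 5. A patient who died inside the death cutoff is
high risk; one who demonstrably lived past the survive cutoff (event
or censored) is low risk; everyone else carries no usable outcome at
that horizon and is excluded from the step. At each step a two-output
softmax (no hidden layer) is trained on the labeled samples, and each
gene j is scored by its discriminating power

DP_j = | w_HIGH,j · x̄_j(HIGH) − w_LOW,j · x̄_j(LOW) |,

the product of the trained input-to-output weights with the class-mean
normalized expression. Only the top quarter of genes passes to the
next step. The output is a total ranking of all input genes
(survivors first, then eliminated genes, later eliminations ranked
higher). A two-class Fisher criterion is available as a drop-in
alternative scorer.

**Evaluation.** Selected top-k signatures feed a Faraggi–Simon model:
Cox proportional hazards with the linear predictor replaced by a
one-hidden-layer network log-hazard f(X, θ), trained full-batch by the
negative log-partial likelihood

−log L(θ) = Σ_{i: C_i=0} [ log Σ_{j: S_j ≥ S_i} e^{f(X_j,θ)} − f(X_i,θ) ],

with Adam, early stopping, and the learning rate chosen by validation
c-index on a 20% holdout. Performance is measured by Harrell's
c-index and the log-rank test under stratified fivefold
cross-validation; per-fold rankings are merged by gene ranking points
Point_j = Σ_k (N − R_jk).

**Synthetic cohorts.** A generator produces cohorts with known causal
genes — lognormal right-skewed expression, exponential event times
driven by the normalized causal-gene values through a
proportional-hazards model, and censoring calibrated to a target
fraction — so the whole pipeline is testable end to end.

## Worked example

`examples/02_rank_genes_with_cascade.py` simulates 300 patients × 500
genes with 10 planted causal genes (|β| = 1.5) and runs the cascade:

```
step 1 (3 vs 3 years): 131 high / 81 low / 88 excluded
step 2 (2 vs 4 years): 103 high / 47 low / 150 excluded
step 3 (1 vs 5 years): 66 high / 25 low / 209 excluded

cascade: 500 -> 125 -> 31 genes
causal genes among the 31 final survivors: 4 of 10
causal genes in the top 25 of the full ranking: 4 (random expectation 0.5)
```

The cascade concentrates planted prognostic genes roughly eightfold
over chance in its top list. `examples/03_evaluate_signature.py` then
evaluates signatures of growing size with the survival model under
nested fivefold cross-validation (selection redone on every training
split):

```
k   mean c-index   fold range        log-rank p (median split)
...
7   0.6918        [0.634, 0.774]   0.023
...
best signature size k=7: mean test c-index 0.6918 (0.5 = chance)
```

A mean held-out c-index of 0.69 means the model orders ~69% of
comparable patient pairs correctly; the log-rank p-value tests whether
the predicted high- and low-risk halves have genuinely different
survival curves.

## Command line

```sh
cascadewx simulate --out-prefix sim/ --seed 0 --n-samples 300 --n-genes 500
cascadewx rank     --expression sim/expression.tsv --clinical sim/clinical.tsv \
                   --out-dir rank/ --seed 0
cascadewx evaluate --expression sim/expression.tsv --clinical sim/clinical.tsv \
                   --out-dir eval/ --seed 0 --k-max 20
```

Expression tables are TSV, genes in rows (firehose-style) or samples
in rows (`--orientation`); clinical tables carry `sample_id`,
`time_days`, `censored`. Every run writes a JSON manifest from which
its outputs are byte-reproducible.

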