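# Methods

## Data model and preprocessing

Inputs are a samples × genes matrix of non-negative expression values
(RSEM-style normalized counts) and per-sample follow-up: time in days
and a right-censoring indicator C (C = 1 means the death event was not
observed; the time is then only a lower bound). Internally all times
are days; cutoffs are stated in years and converted at 365.25
days/year.

Preprocessing is the standard count-scale recipe, in this order:

1. remove genes whose values are exactly identical across all samples
   (literal zero variance — count data make exact ties meaningful, so
   no tolerance is used);
2. x → log2(x + 1) to tame the right skew;
3. per-gene min-max onto [0, 1] over the whole cohort.

Min-max is per gene, not global: per-gene dynamic ranges differ by
orders of magnitude, and a global rescaling would leave most genes
near zero and the discriminating-power score degenerate. By default
normalization precedes the cross-validation split, matching the
pipeline the selection procedure was designed for;
`RunConfig(normalize_within_folds=True)` instead fits min-max on each
training split and applies it clipped to [0, 1] to held-out samples,
for leakage-sensitive protocols.

## Risk-group construction

Each cascade step uses a cutoff pair (death_cut, survive_cut) in
years, default steps (3, 3), (2, 4), (1, 5):

- HIGH: event observed and time ≤ death_cut (boundary counts as
  "within");
- LOW: time > survive_cut, censored or not — the patient demonstrably
  lived beyond the horizon, so censoring does not remove the label
  (time exactly equal to the cutoff does not count as "beyond");
- EXCLUDED: everyone else — censored at or before the survive cutoff
  (their outcome at the horizon is unknown), or an event falling
  between the two cutoffs (no unambiguous group, by symmetry with the
  censored-exclusion rule).

An empty HIGH or LOW group makes the step untrainable and is a hard
error naming the step.

## Scorers

**Softmax discriminating power (primary).** A two-output softmax with
no hidden layer is trained on the labeled samples' normalized
expression by full-batch Adam on cross-entropy: up to 100 epochs,
early stopping with patience 20 on validation cross-entropy, a
stratified 20% validation split, and the learning rate picked from
{1e-1, 1e-2, 1e-3, 1e-4} by best validation cross-entropy. This
mirrors the survival model's training protocol, which is the only
recipe specified anywhere in the pipeline's design. Gene j's score is

    DP_j = | w_HIGH,j · mean_j(HIGH) − w_LOW,j · mean_j(LOW) |

using class means of the matrix actually fed to the classifier. Bias
terms are trained but do not enter DP — the score is defined on the
input-to-output weights only. Scores are non-negative by
construction.

**Fisher criterion (alternative).** score_j =
Σ_c n_c (μ_jc − μ_j)² / Σ_c n_c σ²_jc over the two classes; a gene
with zero pooled within-class variance but separated means is placed
above every finite score (max finite + 1); a gene identical in both
classes scores 0.

Both scorers satisfy one contract — (matrix, labels) → one
non-negative score per gene — and are selectable by name, so the
cascade is scorer-agnostic. Rankings sort scores descending with ties
broken by ascending gene id, making every downstream artifact
deterministic.

## The cascade

Step s labels patients with cutoff pair s, trains the scorer on the
currently surviving genes restricted to labeled samples, and passes
the top ⌊keep_fraction · d_s⌋ genes (default quarter) to step s+1; a
floor of zero is a hard error. The final step scores and ranks its
input without further elimination, so with 1,600 genes the step sizes
are 1,600 → 400 → 100 and the 100 final-step genes carry provenance 0.
The output ranking covers every input gene: survivors first in
final-step score order, then eliminated genes grouped by step (later
eliminations above earlier ones), within a group by descending
elimination-step score. This makes the rank R_jk total, as the
cross-fold merge formula requires. Each step derives its training
seed from the master seed and the step index, so reruns are
bit-identical.

## Survival model

The evaluator is a Faraggi–Simon nonlinear proportional-hazards
model: the Cox linear predictor is replaced by a one-hidden-layer
feed-forward network f(X, θ) (default 8 sigmoid units, configurable;
an identity activation exposes the exact linear limit). "One hidden
layer" is the Faraggi–Simon architecture; a zero-hidden-layer reading
would be linear Cox and not nonlinear. The loss is the negative
log-partial likelihood

    −log L(θ) = Σ_{i: C_i=0} [ log Σ_{j: S_j ≥ S_i} e^{f_j} − f_i ],

with Breslow-style risk sets (S_j ≥ S_i exactly, ties included) and
max-subtraction stabilisation. Training is full batch — the
likelihood couples all samples through the risk sets — with Adam, up
to 100 epochs, early stopping with patience 20 on validation
c-index (the same criterion used to pick the learning rate, from the
decade grid {1e-1 … 1e-4} on a 20% holdout stratified on censoring),
and weights restored from the best epoch. Weights initialise from a
seeded uniform(−0.1, 0.1); a candidate rate whose loss goes non-finite
is discarded, and all rates diverging is a hard error. Both this
network and the softmax classifier are small enough that their
gradients are computed in closed form on numpy arrays; the gradient of
the partial likelihood with respect to f is the standard
events-minus-risk-set-softmax expression, backpropagated through the
single hidden layer.

## Evaluation machinery

**Harrell's c-index** is computed with an explicit convention: a pair
(i, j) is comparable when sample i's event was observed and
S_i < S_j strictly; it scores 1 if risk_i > risk_j, 0.5 on a risk tie.
The result carries exact concordant/discordant/tied counts. Tests
cross-check it against lifelines' implementation on tie-free data and
against exhaustive pair enumeration in general.

**Log-rank test and Kaplan–Meier** delegate to lifelines (two-group
log-rank with a chi-square(1) p-value; product-limit estimator).
When a gene set is evaluated for group separation, held-out patients
are dichotomised at the median predicted risk — the conventional
choice where no dichotomy is inherent.

**Cross-validation** is stratified fivefold on the censoring
indicator (the only binary sample attribute in scope; it preserves
per-fold event counts), via scikit-learn's StratifiedKFold with a
derived seed. Per-fold cascade rankings are merged by gene ranking
points Point_j = Σ_k (N − R_jk), sorted descending, ties by gene id.
The pipeline is nested and leakage-free: the selector sees only each
fold's training samples; the merged list is for reporting, while
per-fold lists drive per-fold evaluation. `evaluate_top_k_curve` also
accepts a single ranking applied to every fold, for screening
experiments where the comparison (e.g. against a random ranking) is
like-for-like.

## Synthetic cohorts

The generator emulates a bulk tumour cohort: per-gene lognormal
expression (log-location uniform on [0, 6], log-scale uniform on
[0.5, 1.5]) giving heavy right skew and order-of-magnitude dynamic
ranges; a chosen number of causal genes with log-hazard effects of
fixed magnitude and random sign; exponential event times with rate
baseline_hazard · exp(Σ β_g (z_g − z̄_g)), where z_g is the causal
gene's log2(1+x) value min-max normalized over the cohort — the exact
feature scale the selection pipeline sees. The effects are centred so
baseline_hazard (default 0.2 events/year, median survival ≈ 3.5 years
— placing the 3-year cutoff near the cohort median) remains the
hazard of the average patient no matter how many causal genes act;
uncentred effects would let a chance sign imbalance shift the whole
cohort's time scale and empty the long-survivor group. Censoring
times are uniform on (0, followup]; the follow-up horizon is found by
bisection so the realized censoring fraction hits the target (default
50%, within the 36–86% range typical of TCGA cohorts).

Defaults — 400 samples, 1,000 genes, 20 causal genes with |β| = 1 —
are the package's reference study conditions. What the generator does
not emulate: negative-binomial count noise, batch effects, and
correlated co-expression blocks. Passing tests therefore demonstrate
that the machinery recovers independent planted signals at realistic
dimensionality and censoring, not that it untangles correlated
pathways in real tumours.

Note the intrinsic scale of the planted effects: since z_g ∈ [0, 1]
has standard deviation ≈ 1/6 for Gaussian-shaped log-expression,
|β| = 1 is a per-gene effect of ≈ 0.17 log-hazard units — a hazard
ratio of e across a gene's whole expression range. At n = 400 and
d = 1,000 such effects sit near the detection floor of any marginal
screen: a univariate Cox score test using full follow-up information
places only ~9 of the 20 causal genes in its top 50 on average, and
the cascade — which additionally dichotomises outcomes and sets aside
excluded patients — concentrates causal genes several-fold over
chance without reaching that oracle ceiling. The cross-validated
c-index of its top-20 signature (~0.67) against a random ranking's
(~0.50) is the cleaner readout of selection quality at this effect
size.

## Determinism and problem sizes

One master seed derives every stochastic stage's seed via SHA-256 of
(seed, stage name), truncated below 2³¹: fold splitting, each cascade
step's classifier, each fold-and-k survival fit, and the simulation
stream. A full simulate → rank → evaluate run is byte-reproducible
from the seed, and the run manifest records config, seed and package
version. Tests and the acceptance script run on cohorts of 100–1,600
genes and 120–2,000 samples with three replicate seeds for headline
quantities — sizes at which every stage's behaviour (step bookkeeping,
recovery, calibration) is already stable and the whole suite completes
in minutes.

## Known limitations

- Efron tie handling is not implemented; risk sets are Breslow-style.
- The comparator selectors from the surrounding literature (random
  forests, boosting, ReliefF, elastic-net Cox, …) are out of scope;
  the Fisher criterion is the one built-in alternative scorer.
- The log-rank dichotomy at median predicted risk is a convention;
  other cutpoints (quartiles, optimal split with corrected p) are not
  provided.
- Competing risks and interval censoring are out of scope.
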