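"""Feature scorers for HIGH/LOW risk discriminability.

The primary scorer trains a two-output softmax (no hidden layer) on the
normalized expression of the labeled samples and converts its input
weights into a per-gene discriminating power

    DP_j = | w_HIGH,j * mean_j(HIGH)  -  w_LOW,j * mean_j(LOW) |,

where the means are class means of the matrix actually fed to the
classifier. A two-class Fisher criterion (between-class over pooled
within-class variance) is provided as an alternative behind the same
scorer contract: every scorer maps (matrix, labels) to one non-negative
score per gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Dict, Sequence, Tuple

import numpy as np

from ._optim import Adam
from ._seeds import derive_seed
from .containers import EXCLUDED, HIGH, LOW, ExpressionMatrix, FeatureRanking
from .risk import RiskLabelAssignment

DEFAULT_LEARNING_RATES = (1e-1, 1e-2, 1e-3, 1e-4)


@dataclass(frozen=True)
class ClassifierHyperparams:
    """Training protocol for the softmax classifier.

    Mirrors the survival model's recipe: full-batch Adam, up to
    ``max_epochs`` epochs, early stopping after ``early_stop_patience``
    epochs without validation improvement, learning rate chosen from
    ``learning_rates`` by best validation cross-entropy on a stratified
    ``validation_fraction`` split.
    """

    max_epochs: int = 100
    early_stop_patience: int = 20
    learning_rates: Tuple[float, ...] = DEFAULT_LEARNING_RATES
    validation_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_epochs < 1 or self.early_stop_patience < 1:
            raise ValueError("max_epochs and early_stop_patience must be >= 1")
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in (0, 1)")
        if len(self.learning_rates) == 0:
            raise ValueError("need at least one candidate learning rate")


@dataclass(frozen=True)
class TrainedSoftmaxWeights:
    """Input-to-output weights of a fitted two-class softmax."""

    gene_ids: np.ndarray
    w_high: np.ndarray
    w_low: np.ndarray
    biases: np.ndarray  # (bias_low, bias_high)
    training_log: dict = field(default_factory=dict)


@dataclass(frozen=True)
class DPScores:
    gene_ids: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if scores.shape != (np.asarray(self.gene_ids).size,):
            raise ValueError("scores must align with gene_ids")


def _stratified_split(
    y: np.ndarray, fraction: float, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-class holdout of ~fraction samples; every class keeps >= 1 in train."""
    train, val = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        n_val = int(round(fraction * idx.size))
        n_val = min(n_val, idx.size - 1)  # never empty the training side
        val.extend(idx[:n_val])
        train.extend(idx[n_val:])
    return np.sort(np.array(train, dtype=int)), np.sort(np.array(val, dtype=int))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _cross_entropy(p: np.ndarray, y: np.ndarray) -> float:
    return float(-np.mean(np.log(np.clip(p[np.arange(y.size), y], 1e-12, None))))


def _labeled_arrays(
    X: ExpressionMatrix, labels: RiskLabelAssignment
) -> Tuple[np.ndarray, np.ndarray]:
    if X.sample_ids.tolist() != labels.sample_ids.tolist():
        lab = {s: l for s, l in zip(labels.sample_ids.tolist(), labels.labels.tolist())}
        try:
            y_all = np.array([lab[s] for s in X.sample_ids.tolist()], dtype=object)
        except KeyError as exc:
            raise ValueError(f"sample {exc.args[0]!r} has no risk label") from None
    else:
        y_all = labels.labels
    keep = y_all != EXCLUDED
    Xs = X.values[keep, :]
    y = (y_all[keep] == HIGH).astype(int)  # 1 = HIGH, 0 = LOW
    if y.size == 0 or np.all(y == 1) or np.all(y == 0):
        raise ValueError("softmax training needs both HIGH and LOW samples")
    return Xs, y


def train_softmax_classifier(
    X: ExpressionMatrix,
    labels: RiskLabelAssignment,
    h: ClassifierHyperparams,
) -> TrainedSoftmaxWeights:
    """Fit the two-output softmax by full-batch Adam with early stopping.

    Deterministic given ``h.seed``: the validation split and each
    candidate rate's initialisation derive from it.
    """
    Xs, y = _labeled_arrays(X, labels)
    d = Xs.shape[1]
    split_rng = np.random.default_rng(derive_seed(h.seed, "softmax-split"))
    tr, va = _stratified_split(y, h.validation_fraction, split_rng)
    Xtr, ytr, Xva, yva = Xs[tr], y[tr], Xs[va], y[va]
    if Xva.shape[0] == 0:  # tiny inputs: validate on the training set
        Xva, yva = Xtr, ytr

    best = None  # (val_ce, rate_index, W, b, log)
    diverged = []
    for ri, lr in enumerate(h.learning_rates):
        init_rng = np.random.default_rng(derive_seed(h.seed, "softmax-init", ri))
        W = init_rng.uniform(-0.01, 0.01, size=(d, 2))
        b = init_rng.uniform(-0.01, 0.01, size=2)
        opt = Adam([W, b], lr=lr)
        best_val = np.inf
        best_Wb = (W.copy(), b.copy())
        best_epoch = 0
        stale = 0
        epochs_run = 0
        bad = False
        for epoch in range(1, h.max_epochs + 1):
            p = _softmax(Xtr @ W + b)
            loss = _cross_entropy(p, ytr)
            if not np.isfinite(loss):
                bad = True
                break
            resid = p.copy()
            resid[np.arange(ytr.size), ytr] -= 1.0
            resid /= ytr.size
            opt.step([W, b], [Xtr.T @ resid, resid.sum(axis=0)])
            val_ce = _cross_entropy(_softmax(Xva @ W + b), yva)
            epochs_run = epoch
            if val_ce < best_val:
                best_val = val_ce
                best_Wb = (W.copy(), b.copy())
                best_epoch = epoch
                stale = 0
            else:
                stale += 1
                if stale >= h.early_stop_patience:
                    break
        if bad or not np.isfinite(best_val):
            diverged.append(lr)
            continue
        log = {
            "learning_rate": lr,
            "epochs_run": epochs_run,
            "best_epoch": best_epoch,
            "best_val_cross_entropy": best_val,
            "seed": h.seed,
        }
        if best is None or best_val < best[0]:
            best = (best_val, ri, *best_Wb, log)
    if best is None:
        raise ValueError(
            f"training diverged (non-finite loss) at every learning rate: {diverged}"
        )
    _, _, W, b, log = best
    return TrainedSoftmaxWeights(
        gene_ids=X.gene_ids,
        w_high=W[:, 1].copy(),
        w_low=W[:, 0].copy(),
        biases=np.array([b[0], b[1]]),
        training_log=log,
    )


def classifier_accuracy(w: TrainedSoftmaxWeights, X: ExpressionMatrix,
                        labels: RiskLabelAssignment) -> float:
    Xs, y = _labeled_arrays(X, labels)
    W = np.column_stack([w.w_low, w.w_high])
    pred = np.argmax(Xs @ W + w.biases, axis=1)
    return float(np.mean(pred == y))


def _class_means(
    X: ExpressionMatrix, labels: RiskLabelAssignment
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    Xs, y = _labeled_arrays(X, labels)
    return Xs[y == 1].mean(axis=0), Xs[y == 0].mean(axis=0), Xs, y


def wx_dp_scores(
    w: TrainedSoftmaxWeights, X: ExpressionMatrix, labels: RiskLabelAssignment
) -> DPScores:
    """Discriminating power |w_HIGH * mean_HIGH - w_LOW * mean_LOW| per gene."""
    if w.gene_ids.tolist() != X.gene_ids.tolist():
        raise ValueError("classifier was trained on a different gene set")
    mu_high, mu_low, _, _ = _class_means(X, labels)
    dp = np.abs(w.w_high * mu_high - w.w_low * mu_low)
    return DPScores(X.gene_ids, dp)


def fisher_scores(X: ExpressionMatrix, labels: RiskLabelAssignment) -> DPScores:
    """Two-class Fisher criterion per gene.

    score_j = sum_c n_c (mu_jc - mu_j)^2 / sum_c n_c var_jc, with genes
    of zero pooled within-class variance but separated means placed
    above every finite score.
    """
    Xs, y = _labeled_arrays(X, labels)
    if np.sum(y == 1) < 2 or np.sum(y == 0) < 2:
        raise ValueError("fisher_scores needs >= 2 samples in each class")
    mu = Xs.mean(axis=0)
    num = np.zeros(Xs.shape[1])
    den = np.zeros(Xs.shape[1])
    for cls in (0, 1):
        Xc = Xs[y == cls]
        nc = Xc.shape[0]
        muc = Xc.mean(axis=0)
        num += nc * (muc - mu) ** 2
        den += nc * Xc.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = num / den
    scores[(den == 0) & (num == 0)] = 0.0
    sep = (den == 0) & (num > 0)
    if sep.any():
        finite_max = scores[~sep].max() if (~sep).any() else 0.0
        scores[sep] = finite_max + 1.0
    return DPScores(X.gene_ids, scores)


def rank_features(s: DPScores) -> FeatureRanking:
    """Descending-score order; ties broken by ascending gene id."""
    if np.any(np.isnan(s.scores)):
        raise ValueError("NaN score cannot be ranked")
    gene_list = np.asarray(s.gene_ids, dtype=object)
    order = sorted(range(gene_list.size), key=lambda i: (-s.scores[i], gene_list[i]))
    order = np.array(order, dtype=int)
    return FeatureRanking(gene_list[order], s.scores[order])


ScorerFn = Callable[..., DPScores]


def _wx_scorer(X: ExpressionMatrix, labels: RiskLabelAssignment,
               h: ClassifierHyperparams, seed: int) -> DPScores:
    w = train_softmax_classifier(X, labels, replace(h, seed=seed))
    return wx_dp_scores(w, X, labels)


def _fisher_scorer(X: ExpressionMatrix, labels: RiskLabelAssignment,
                   h: ClassifierHyperparams, seed: int) -> DPScores:
    return fisher_scores(X, labels)


SCORERS: Dict[str, ScorerFn] = {"wx": _wx_scorer, "fisher": _fisher_scorer}


def score_features(
    X: ExpressionMatrix,
    labels: RiskLabelAssignment,
    scorer_name: str,
    h: ClassifierHyperparams,
    seed: int,
) -> DPScores:
    """Run a named scorer under the shared (X, labels) -> DPScores contract."""
    try:
        scorer = SCORERS[scorer_name]
    except KeyError:
        raise ValueError(
            f"unknown scorer {scorer_name!r}; available: {sorted(SCORERS)}"
        ) from None
    return scorer(X, labels, h, seed)
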