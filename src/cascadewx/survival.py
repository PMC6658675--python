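"""Faraggi-Simon nonlinear proportional-hazards model.

The Cox linear predictor beta'X is replaced by a one-hidden-layer
feed-forward network f(X, theta) that outputs a per-sample log-hazard.
Training minimises the negative log-partial likelihood

    -log L = sum_{i: event} [ log sum_{j: S_j >= S_i} exp(f_j)  -  f_i ]

over the whole training set at once (the likelihood couples all samples
through the risk sets, so the batch is the full dataset). Ties are
handled Breslow-style: the risk set of event i is everyone with
S_j >= S_i. Optimisation uses Adam with early stopping on validation
concordance, and the learning rate is chosen from a candidate grid by
the best validation c-index on a stratified 20% holdout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

from ._optim import Adam
from ._seeds import derive_seed
from .containers import ExpressionMatrix, SurvivalData, check_aligned

DEFAULT_LEARNING_RATES = (1e-1, 1e-2, 1e-3, 1e-4)


@dataclass(frozen=True)
class SurvivalFitConfig:
    max_epochs: int = 100
    early_stop_patience: int = 20
    learning_rates: Tuple[float, ...] = DEFAULT_LEARNING_RATES
    validation_fraction: float = 0.2
    hidden_units: int = 8
    activation: str = "sigmoid"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_epochs < 1 or self.early_stop_patience < 1:
            raise ValueError("max_epochs and early_stop_patience must be >= 1")
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.activation not in ("sigmoid", "identity"):
            raise ValueError(f"unknown activation {self.activation!r}")


@dataclass(frozen=True)
class SurvivalModelParams:
    """Weights of the log-hazard network plus its training record."""

    gene_ids: np.ndarray
    W1: np.ndarray  # (d, hidden)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (hidden,)
    b2: float
    activation: str = "sigmoid"
    training_log: dict = field(default_factory=dict)

    @property
    def hidden_units(self) -> int:
        return self.W1.shape[1]


def neg_log_partial_likelihood(f_values: np.ndarray, surv: SurvivalData) -> float:
    """Breslow negative log-partial likelihood of per-sample log-hazards."""
    f = np.asarray(f_values, dtype=float)
    if f.shape != (surv.n_samples,):
        raise ValueError("f_values must align with survival data")
    if not np.all(np.isfinite(f)):
        raise ValueError("non-finite log-hazard values")
    event = surv.event_observed
    if not event.any():
        raise ValueError("partial likelihood needs at least one uncensored sample")
    t = surv.time_days
    # risk-set mask: R[i, j] = 1 iff S_j >= S_i, rows restricted to events
    R = t[None, :] >= t[event, None]
    fmax = np.max(np.where(R, f[None, :], -np.inf), axis=1)
    lse = fmax + np.log(np.sum(np.where(R, np.exp(f[None, :] - fmax[:, None]), 0.0), axis=1))
    return float(np.sum(lse - f[event]))


def _nlpl_grad(f: np.ndarray, t: np.ndarray, event: np.ndarray) -> Tuple[float, np.ndarray]:
    """Loss and d(loss)/d(f) in one pass (O(n_events * n))."""
    R = t[None, :] >= t[event, None]
    fmax = np.max(np.where(R, f[None, :], -np.inf), axis=1)
    w = np.where(R, np.exp(f[None, :] - fmax[:, None]), 0.0)
    wsum = w.sum(axis=1)
    loss = float(np.sum(fmax + np.log(wsum) - f[event]))
    grad = (w / wsum[:, None]).sum(axis=0)
    grad[event] -= 1.0
    return loss, grad


def _forward(X: np.ndarray, W1, b1, w2, b2, activation: str):
    z = X @ W1 + b1
    if activation == "sigmoid":
        h = 1.0 / (1.0 + np.exp(-z))
    else:
        h = z
    return h, h @ w2 + b2


def _fast_cindex(risk: np.ndarray, t: np.ndarray, event: np.ndarray) -> float:
    """Harrell c-index without pair bookkeeping, for validation monitoring."""
    conc = tied = total = 0
    for i in np.flatnonzero(event):
        later = t > t[i]
        if not later.any():
            continue
        diff = risk[i] - risk[later]
        conc += int(np.sum(diff > 0))
        tied += int(np.sum(diff == 0))
        total += int(later.sum())
    if total == 0:
        return np.nan
    return (conc + 0.5 * tied) / total


def fit_faraggi_simon(
    X: ExpressionMatrix, surv: SurvivalData, cfg: SurvivalFitConfig
) -> SurvivalModelParams:
    """Train the log-hazard network; deterministic given ``cfg.seed``."""
    check_aligned(X, surv)
    event = surv.event_observed
    if event.sum() < 2:
        raise ValueError("need at least two uncensored samples to fit")
    n, d = X.values.shape

    split_rng = np.random.default_rng(derive_seed(cfg.seed, "fs-split"))
    tr, va = [], []
    for cls in (0, 1):  # stratify the holdout on the censoring indicator
        idx = np.flatnonzero(surv.censored.astype(int) == cls)
        idx = split_rng.permutation(idx)
        n_val = min(int(round(cfg.validation_fraction * idx.size)), max(idx.size - 1, 0))
        va.extend(idx[:n_val])
        tr.extend(idx[n_val:])
    tr = np.sort(np.array(tr, dtype=int))
    va = np.sort(np.array(va, dtype=int))
    if event[tr].sum() < 2:
        raise ValueError("too few uncensored samples left after the validation split")
    if va.size == 0 or not event[va].any():
        # validation c-index needs an event; fall back to monitoring on train
        va = tr

    Xtr, ttr, etr = X.values[tr], surv.time_days[tr], event[tr]
    Xva, tva, eva = X.values[va], surv.time_days[va], event[va]

    best = None  # (val_cindex, rate_idx, params, log)
    for ri, lr in enumerate(cfg.learning_rates):
        rng = np.random.default_rng(derive_seed(cfg.seed, "fs-init", ri))
        W1 = rng.uniform(-0.1, 0.1, size=(d, cfg.hidden_units))
        b1 = rng.uniform(-0.1, 0.1, size=cfg.hidden_units)
        w2 = rng.uniform(-0.1, 0.1, size=cfg.hidden_units)
        b2 = np.array([rng.uniform(-0.1, 0.1)])
        opt = Adam([W1, b1, w2, b2], lr=lr)
        best_val = -np.inf
        best_params = None
        best_epoch = 0
        stale = 0
        epochs_run = 0
        bad = False
        for epoch in range(1, cfg.max_epochs + 1):
            h, f = _forward(Xtr, W1, b1, w2, b2[0], cfg.activation)
            loss, gf = _nlpl_grad(f, ttr, etr)
            if not np.isfinite(loss):
                bad = True
                break
            gw2 = h.T @ gf
            gb2 = np.array([gf.sum()])
            dh = np.outer(gf, w2)
            dz = dh * h * (1.0 - h) if cfg.activation == "sigmoid" else dh
            opt.step([W1, b1, w2, b2], [Xtr.T @ dz, dz.sum(axis=0), gw2, gb2])
            _, fva = _forward(Xva, W1, b1, w2, b2[0], cfg.activation)
            val_ci = _fast_cindex(fva, tva, eva)
            epochs_run = epoch
            if np.isfinite(val_ci) and val_ci > best_val:
                best_val = val_ci
                best_params = (W1.copy(), b1.copy(), w2.copy(), float(b2[0]))
                best_epoch = epoch
                stale = 0
            else:
                stale += 1
                if stale >= cfg.early_stop_patience:
                    break
        if bad or best_params is None:
            continue
        log = {
            "learning_rate": lr,
            "epochs_run": epochs_run,
            "best_epoch": best_epoch,
            "best_val_cindex": best_val,
            "seed": cfg.seed,
            "n_train": int(tr.size),
            "n_val": int(va.size),
        }
        if best is None or best_val > best[0]:
            best = (best_val, ri, best_params, log)
    if best is None:
        raise ValueError(
            f"training diverged at every candidate learning rate {cfg.learning_rates}"
        )
    _, _, (W1, b1, w2, b2v), log = best
    return SurvivalModelParams(
        gene_ids=X.gene_ids, W1=W1, b1=b1, w2=w2, b2=b2v,
        activation=cfg.activation, training_log=log,
    )


def predict_risk(m: SurvivalModelParams, X: ExpressionMatrix) -> np.ndarray:
    """Per-sample log-hazard f(X, theta); higher means higher risk."""
    if m.gene_ids.tolist() != X.gene_ids.tolist():
        raise ValueError("gene set does not match the fitted model")
    _, f = _forward(X.values, m.W1, m.b1, m.w2, m.b2, m.activation)
    return f


def save_model(m: SurvivalModelParams, path) -> None:
    payload = {
        "gene_ids": m.gene_ids.tolist(),
        "W1": m.W1.tolist(),
        "b1": m.b1.tolist(),
        "w2": m.w2.tolist(),
        "b2": m.b2,
        "activation": m.activation,
        "training_log": m.training_log,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path) -> SurvivalModelParams:
    with open(path) as fh:
        payload = json.load(fh)
    return SurvivalModelParams(
        gene_ids=np.asarray(payload["gene_ids"], dtype=object),
        W1=np.asarray(payload["W1"], dtype=float),
        b1=np.asarray(payload["b1"], dtype=float),
        w2=np.asarray(payload["w2"], dtype=float),
        b2=float(payload["b2"]),
        activation=payload["activation"],
        training_log=payload["training_log"],
    )
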