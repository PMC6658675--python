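"""Survival-evaluation machinery: concordance, log-rank, Kaplan-Meier,
stratified cross-validation, fold-rank merging and top-k curves.

Harrell's c-index is computed in-package with an explicit comparability
rule — a pair (i, j) is usable when sample i's death was observed and
S_i < S_j strictly; the pair scores 1 if i's predicted risk is strictly
higher, 0.5 on a risk tie — so that the exact concordant/discordant/tied
counts are reported. The log-rank test and the Kaplan-Meier estimator
are delegated to lifelines; fold construction uses scikit-learn's
StratifiedKFold on the censoring indicator.

Rankings from the k cross-validation folds are merged by gene ranking
points: Point_j = sum_k (N - R_jk), sorted descending, where R_jk is
gene j's rank in fold k and N the number of genes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Sequence, Union

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from sklearn.model_selection import StratifiedKFold

from ._seeds import derive_seed
from .containers import ExpressionMatrix, FeatureRanking, SurvivalData, check_aligned
from .survival import SurvivalFitConfig, fit_faraggi_simon, predict_risk


@dataclass(frozen=True)
class CIndexResult:
    value: float
    concordant: int
    discordant: int
    tied_risk: int

    @property
    def n_comparable(self) -> int:
        return self.concordant + self.discordant + self.tied_risk


def harrell_c_index(risk: np.ndarray, surv: SurvivalData) -> CIndexResult:
    """Concordance between predicted risk and observed survival."""
    risk = np.asarray(risk, dtype=float)
    if risk.shape != (surv.n_samples,):
        raise ValueError("risk scores must align with survival data")
    t = surv.time_days
    conc = disc = tied = 0
    for i in np.flatnonzero(surv.event_observed):
        later = t > t[i]
        if not later.any():
            continue
        diff = risk[i] - risk[later]
        conc += int(np.sum(diff > 0))
        tied += int(np.sum(diff == 0))
        disc += int(np.sum(diff < 0))
    total = conc + disc + tied
    if total == 0:
        raise ValueError("no comparable pairs (need an observed event before another time)")
    return CIndexResult((conc + 0.5 * tied) / total, conc, disc, tied)


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    p_value: float
    n_group0: int
    n_group1: int


def log_rank_test(surv: SurvivalData, group: np.ndarray) -> LogRankResult:
    """Two-group log-rank test; chi-square(1) p-value."""
    group = np.asarray(group).astype(bool)
    if group.shape != (surv.n_samples,):
        raise ValueError("group labels must align with survival data")
    if not group.any() or group.all():
        raise ValueError("both groups must be non-empty")
    if not surv.event_observed.any():
        raise ValueError("log-rank test needs at least one event")
    res = logrank_test(
        surv.time_days[~group], surv.time_days[group],
        event_observed_A=surv.event_observed[~group].astype(int),
        event_observed_B=surv.event_observed[group].astype(int),
    )
    return LogRankResult(
        float(res.test_statistic), float(res.p_value),
        int(np.sum(~group)), int(np.sum(group)),
    )


@dataclass(frozen=True)
class KaplanMeierCurve:
    """Product-limit survival estimate as a right-continuous step function."""

    times: np.ndarray      # step locations, starting at 0
    survival: np.ndarray   # S(t) at and after each step location

    def at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(idx, 0)])


def kaplan_meier(surv: SurvivalData) -> KaplanMeierCurve:
    kmf = KaplanMeierFitter()
    kmf.fit(surv.time_days, event_observed=surv.event_observed.astype(int))
    sf = kmf.survival_function_
    return KaplanMeierCurve(
        sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy(dtype=float)
    )


@dataclass(frozen=True)
class FoldSplit:
    """Partition of sample ids into k folds, stratified on censoring."""

    fold_ids: List[np.ndarray]  # per fold, the held-out (test) sample ids

    @property
    def k(self) -> int:
        return len(self.fold_ids)

    def train_test(self, fold: int) -> tuple:
        test = self.fold_ids[fold].tolist()
        train = [
            s for f, ids in enumerate(self.fold_ids) if f != fold for s in ids.tolist()
        ]
        return train, test


def stratified_kfold(surv: SurvivalData, k: int, seed: int) -> FoldSplit:
    if k < 2:
        raise ValueError("k must be >= 2")
    strata = surv.censored.astype(int)
    for cls in np.unique(strata):
        if np.sum(strata == cls) < k:
            raise ValueError(
                f"stratum censored={bool(cls)} has fewer than k={k} samples"
            )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = [
        surv.sample_ids[test] for _, test in skf.split(np.zeros(surv.n_samples), strata)
    ]
    return FoldSplit(folds)


@dataclass(frozen=True)
class MergedRanking:
    gene_ids: np.ndarray  # descending gene-ranking-point order
    points: np.ndarray    # integer points, aligned with gene_ids

    @property
    def n_genes(self) -> int:
        return self.gene_ids.size

    def top(self, k: int) -> list:
        return self.gene_ids[:k].tolist()


def merge_rankings(rankings: Sequence[FeatureRanking]) -> MergedRanking:
    """Merge fold rankings by gene ranking points sum_k (N - R_jk)."""
    if len(rankings) == 0:
        raise ValueError("need at least one ranking to merge")
    genes = sorted(rankings[0].gene_ids.tolist())
    N = len(genes)
    points = {g: 0 for g in genes}
    for r in rankings:
        if sorted(r.gene_ids.tolist()) != genes:
            raise ValueError("rankings cover different gene sets")
        for g, rank in r.ranks().items():
            points[g] += N - rank
    order = sorted(genes, key=lambda g: (-points[g], g))
    return MergedRanking(
        np.asarray(order, dtype=object),
        np.asarray([points[g] for g in order], dtype=int),
    )


@dataclass(frozen=True)
class TopKCurve:
    """Per-k cross-validated test concordance for growing gene signatures."""

    per_fold: pd.DataFrame  # columns: k, fold, cindex

    @property
    def mean_by_k(self) -> pd.Series:
        return self.per_fold.groupby("k")["cindex"].mean()


RankingOrPerFold = Union[FeatureRanking, Sequence[FeatureRanking]]


def evaluate_top_k_curve(
    X: ExpressionMatrix,
    surv: SurvivalData,
    ranking: RankingOrPerFold,
    folds: FoldSplit,
    ks: Union[int, Sequence[int]],
    cfg: SurvivalFitConfig,
) -> TopKCurve:
    """Fit the survival model on each fold's training half with the top-k
    genes and score test concordance, for each requested k.

    ``ranking`` may be a single ranking (used for every fold) or one
    ranking per fold (leakage-free nested protocol). ``ks`` may be a
    k_max (expanded to 1..k_max) or an explicit list of signature sizes.
    """
    check_aligned(X, surv)
    if isinstance(ks, (int, np.integer)):
        ks = list(range(1, int(ks) + 1))
    ks = [int(k) for k in ks]
    if isinstance(ranking, FeatureRanking):
        fold_rankings = [ranking] * folds.k
    else:
        fold_rankings = list(ranking)
        if len(fold_rankings) != folds.k:
            raise ValueError("need one ranking per fold")
    for r in fold_rankings:
        if max(ks) > r.n_genes:
            raise ValueError(f"k={max(ks)} exceeds the {r.n_genes}-gene ranking")
    rows = []
    for fold in range(folds.k):
        train_ids, test_ids = folds.train_test(fold)
        surv_tr, surv_te = surv.subset(train_ids), surv.subset(test_ids)
        for k in ks:
            top = fold_rankings[fold].top(k)
            Xtr = X.subset_samples(train_ids).subset_genes(top)
            Xte = X.subset_samples(test_ids).subset_genes(top)
            fit_cfg = replace(cfg, seed=derive_seed(cfg.seed, "topk", fold, k))
            try:
                model = fit_faraggi_simon(Xtr, surv_tr, fit_cfg)
                ci = harrell_c_index(predict_risk(model, Xte), surv_te)
            except ValueError as exc:
                raise ValueError(f"fold {fold}, k={k}: {exc}") from exc
            rows.append({"k": k, "fold": fold, "cindex": ci.value})
    return TopKCurve(pd.DataFrame(rows))


def median_split_log_rank(risk: np.ndarray, surv: SurvivalData) -> LogRankResult:
    """Log-rank test after dichotomising samples at the median predicted risk."""
    risk = np.asarray(risk, dtype=float)
    group = risk > np.median(risk)
    return log_rank_test(surv, group)
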