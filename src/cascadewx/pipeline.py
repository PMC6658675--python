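"""End-to-end workflows: preprocess -> per-fold cascade -> merge ->
top-k evaluation, with reproducible on-disk outputs and a run manifest.

These functions are the library face of the command-line tool: the CLI
parses arguments and calls straight into them. A single master seed
deterministically derives the fold split, every network initialisation
and the simulation stream, so a whole run is byte-reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .cascade import CascadeConfig, run_cascade
from .containers import ExpressionMatrix, FeatureRanking, SurvivalData, check_aligned
from .evaluation import (
    FoldSplit,
    MergedRanking,
    harrell_c_index,
    median_split_log_rank,
    merge_rankings,
    stratified_kfold,
)
from .io import apply_minmax, drop_zero_variance, fit_minmax, log2_plus_one
from .survival import SurvivalFitConfig, fit_faraggi_simon, predict_risk

logger = logging.getLogger("cascadewx")

FLOAT_FORMAT = "%.10g"


@dataclass(frozen=True)
class RunConfig:
    cascade: CascadeConfig = field(default_factory=CascadeConfig)
    fit: SurvivalFitConfig = field(default_factory=SurvivalFitConfig)
    n_folds: int = 5
    k_max: int = 20
    master_seed: int = 0
    normalize_within_folds: bool = False


def preprocess_cohort(
    X: ExpressionMatrix, train_ids: Optional[Sequence[str]] = None
) -> ExpressionMatrix:
    """drop zero-variance -> log2(x+1) -> min-max.

    When ``train_ids`` is given the min-max parameters are fitted on
    those samples only and applied (clipped to [0, 1]) to the rest, for
    leakage-sensitive protocols; the default fits on the whole cohort,
    matching the published pipeline where normalization precedes the
    cross-validation split.
    """
    X = log2_plus_one(drop_zero_variance(X))
    if train_ids is None:
        mins, ranges = fit_minmax(X)
        return apply_minmax(X, mins, ranges, clip=False)
    Xtr = drop_zero_variance(X.subset_samples(train_ids))
    X = X.subset_genes(Xtr.gene_ids.tolist())
    mins, ranges = fit_minmax(Xtr)
    return apply_minmax(X, mins, ranges, clip=True)


def ranking_to_frame(r: FeatureRanking) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "rank": np.arange(1, r.n_genes + 1),
            "gene_id": r.gene_ids.tolist(),
            "score": r.scores,
            "eliminated_at_step": r.provenance,
        }
    )


def merged_to_frame(m: MergedRanking) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "rank": np.arange(1, m.n_genes + 1),
            "gene_id": m.gene_ids.tolist(),
            "points": m.points,
        }
    )


def run_rank_pipeline(
    X_raw: ExpressionMatrix,
    surv: SurvivalData,
    run_cfg: RunConfig,
    out_dir: Optional[Path] = None,
) -> Tuple[List[FeatureRanking], MergedRanking, FoldSplit]:
    """Per-fold cascade rankings merged into one gene list.

    The cascade is trained on each fold's training samples only; the
    per-fold rankings are merged by gene ranking points for reporting.
    """
    check_aligned(X_raw, surv)
    seed = run_cfg.master_seed
    folds = stratified_kfold(surv, run_cfg.n_folds, derive_seed(seed, "folds"))
    X_all = None
    if not run_cfg.normalize_within_folds:
        X_all = preprocess_cohort(X_raw)
    rankings: List[FeatureRanking] = []
    for fold in range(folds.k):
        train_ids, _ = folds.train_test(fold)
        if run_cfg.normalize_within_folds:
            Xp = preprocess_cohort(X_raw, train_ids=train_ids).subset_samples(train_ids)
        else:
            Xp = X_all.subset_samples(train_ids)
        cascade_cfg = replace(
            run_cfg.cascade,
            classifier_hyperparams=replace(
                run_cfg.cascade.classifier_hyperparams,
                seed=derive_seed(seed, "cascade-fold", fold),
            ),
        )
        ranking = run_cascade(Xp, surv.subset(train_ids), cascade_cfg)
        logger.info(
            "fold %d: cascade ranked %d genes (scorer=%s)",
            fold, ranking.n_genes, run_cfg.cascade.scorer_name,
        )
        rankings.append(ranking)
    merged = merge_rankings(rankings)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for fold, r in enumerate(rankings):
            ranking_to_frame(r).to_csv(
                out_dir / f"ranking_fold{fold}.tsv", sep="\t", index=False,
                float_format=FLOAT_FORMAT,
            )
        merged_to_frame(merged).to_csv(
            out_dir / "ranking_merged.tsv", sep="\t", index=False,
            float_format=FLOAT_FORMAT,
        )
    return rankings, merged, folds


def run_evaluate_pipeline(
    X_raw: ExpressionMatrix,
    surv: SurvivalData,
    run_cfg: RunConfig,
    rankings: Optional[Sequence[FeatureRanking]] = None,
    out_dir: Optional[Path] = None,
) -> pd.DataFrame:
    """Top-k cross-validated concordance plus a median-split log-rank p per k.

    Returns a tidy table with one row per k: mean test c-index over the
    folds, per-fold minimum/maximum, and the log-rank p-value of the
    median-risk dichotomy of the pooled out-of-fold predictions.
    """
    check_aligned(X_raw, surv)
    seed = run_cfg.master_seed
    if rankings is None:
        rankings, _, folds = run_rank_pipeline(X_raw, surv, run_cfg, out_dir=out_dir)
    else:
        folds = stratified_kfold(surv, run_cfg.n_folds, derive_seed(seed, "folds"))
        rankings = list(rankings)
    if run_cfg.k_max > min(r.n_genes for r in rankings):
        raise ValueError(
            f"k_max={run_cfg.k_max} exceeds the number of ranked genes"
        )
    Xp = preprocess_cohort(X_raw)
    fit_cfg = replace(run_cfg.fit, seed=derive_seed(seed, "evaluate"))
    order = {s: i for i, s in enumerate(surv.sample_ids.tolist())}
    per_fold_rows = []
    rows = []
    for k in range(1, run_cfg.k_max + 1):
        risk = np.empty(surv.n_samples)  # pooled out-of-fold risks per k
        fold_ci = []
        for fold in range(folds.k):
            train_ids, test_ids = folds.train_test(fold)
            top = rankings[fold].top(k)
            surv_tr, surv_te = surv.subset(train_ids), surv.subset(test_ids)
            try:
                m = fit_faraggi_simon(
                    Xp.subset_samples(train_ids).subset_genes(top),
                    surv_tr,
                    replace(fit_cfg, seed=derive_seed(fit_cfg.seed, "topk", fold, k)),
                )
                pred = predict_risk(m, Xp.subset_samples(test_ids).subset_genes(top))
                ci = harrell_c_index(pred, surv_te).value
            except ValueError as exc:
                raise ValueError(f"fold {fold}, k={k}: {exc}") from exc
            for s, v in zip(test_ids, pred):
                risk[order[s]] = v
            fold_ci.append(ci)
            per_fold_rows.append({"k": k, "fold": fold, "cindex": ci})
        try:
            p = median_split_log_rank(risk, surv).p_value
        except ValueError:
            p = float("nan")
        rows.append(
            {
                "k": k,
                "mean_cindex": float(np.mean(fold_ci)),
                "min_cindex": float(np.min(fold_ci)),
                "max_cindex": float(np.max(fold_ci)),
                "logrank_p_median_split": p,
            }
        )
    table = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(
            out_dir / "topk_cindex.tsv", sep="\t", index=False,
            float_format=FLOAT_FORMAT,
        )
        pd.DataFrame(per_fold_rows).to_csv(
            out_dir / "topk_cindex_per_fold.tsv", sep="\t", index=False,
            float_format=FLOAT_FORMAT,
        )
    return table


def write_manifest(path: Path, run_cfg: RunConfig, extra: Optional[dict] = None) -> None:
    from . import __version__

    payload = {
        "package": "cascadewx",
        "version": __version__,
        "master_seed": run_cfg.master_seed,
        "config": asdict(run_cfg),
    }
    if extra:
        payload.update(extra)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, default=str)
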