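"""The cascaded feature-selection procedure.

Each step labels patients HIGH/LOW risk at progressively wider year
cutoffs — 3 vs 3, then 2 vs 4, then 1 vs 5 by default — trains the
scorer on the labeled samples and the currently surviving genes, and
passes the top quarter of genes to the next step. The final step scores
and ranks its input genes without further elimination; genes eliminated
earlier are appended below the survivors using their elimination-step
scores, with later eliminations ranked above earlier ones, so the
output is a total order over every input gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

from ._seeds import derive_seed
from .containers import ExpressionMatrix, FeatureRanking, SurvivalData, check_aligned
from .risk import CutoffPair, assign_risk_labels
from .scorers import ClassifierHyperparams, rank_features, score_features

DEFAULT_STEPS = (CutoffPair(3, 3), CutoffPair(2, 4), CutoffPair(1, 5))


@dataclass(frozen=True)
class CascadeConfig:
    steps: Tuple[CutoffPair, ...] = DEFAULT_STEPS
    keep_fraction: float = 0.25
    scorer_name: str = "wx"
    classifier_hyperparams: ClassifierHyperparams = field(
        default_factory=ClassifierHyperparams
    )

    def __post_init__(self) -> None:
        if len(self.steps) < 1:
            raise ValueError("cascade needs at least one step")
        if not 0 < self.keep_fraction <= 1:
            raise ValueError("keep_fraction must be in (0, 1]")


def run_cascade(
    X: ExpressionMatrix, surv: SurvivalData, cfg: CascadeConfig
) -> FeatureRanking:
    """Run the full cascade and return a total ranking of all input genes.

    ``X`` must already be preprocessed (log2, zero-variance-filtered,
    min-max normalized) and aligned with ``surv``. Deterministic given
    the classifier seed: step s trains with a seed derived from it.
    """
    check_aligned(X, surv)
    h = cfg.classifier_hyperparams
    current = X
    # (gene_id, score, step_of_elimination); step 0 = survived to the end
    eliminated: List[Tuple[str, float, int]] = []
    survivors: List[Tuple[str, float, int]] = []
    n_steps = len(cfg.steps)
    for s, cut in enumerate(cfg.steps, start=1):
        try:
            labels = assign_risk_labels(surv, cut)
        except ValueError as exc:
            raise ValueError(f"cascade step {s}: {exc}") from exc
        step_seed = derive_seed(h.seed, "step", s)
        try:
            scores = score_features(current, labels, cfg.scorer_name, h, step_seed)
        except ValueError as exc:
            raise ValueError(f"cascade step {s}: {exc}") from exc
        ranking = rank_features(scores)
        if s < n_steps:
            n_keep = math.floor(cfg.keep_fraction * current.n_genes)
            if n_keep < 1:
                raise ValueError(
                    f"cascade step {s}: keep_fraction {cfg.keep_fraction} reduces "
                    f"{current.n_genes} genes below 1"
                )
            kept = ranking.gene_ids[:n_keep].tolist()
            for g, sc in zip(ranking.gene_ids[n_keep:], ranking.scores[n_keep:]):
                eliminated.append((g, float(sc), s))
            current = current.subset_genes(kept)
        else:
            for g, sc in zip(ranking.gene_ids, ranking.scores):
                survivors.append((g, float(sc), 0))

    # survivors first (already in final-step score order), then eliminated
    # genes grouped by step, later eliminations above earlier ones; within a
    # group by descending score, ties by gene id.
    ordered = survivors + sorted(
        eliminated, key=lambda rec: (-rec[2], -rec[1], rec[0])
    )
    return FeatureRanking(
        np.asarray([g for g, _, _ in ordered], dtype=object),
        np.asarray([sc for _, sc, _ in ordered], dtype=float),
        np.asarray([st for _, _, st in ordered], dtype=int),
    )
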