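"""Synthetic survival-transcriptome cohorts with known causal genes.

The generator emulates the shape of a bulk RNA-seq tumour cohort:
hundreds of samples, heavy-right-skewed non-negative expression
(per-gene lognormal with gene-specific location and scale), a small set
of causal genes acting through a proportional-hazards model on event
times, and a tunable right-censoring fraction.

Event times are exponential with per-sample rate
``baseline_hazard * exp(sum_g beta_g (z_g - mean(z_g)))`` where z_g is
the causal gene's log2(1+x) value min-max normalized over the cohort —
the same feature scale the selection pipeline sees. Centring the
effects keeps ``baseline_hazard`` the hazard of the average patient
regardless of how many causal genes act. Censoring times are uniform
over (0, followup_max_years]; the follow-up horizon is tuned by
bisection so the realized censoring fraction hits the requested target.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from ._seeds import derive_seed
from .containers import DAYS_PER_YEAR, ExpressionMatrix, SurvivalData


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one simulated cohort."""

    n_samples: int = 400
    n_genes: int = 1000
    n_causal: int = 20
    causal_beta: float = 1.0          # log-hazard per normalized expression unit
    baseline_hazard: float = 0.2      # events / year at z = 0
    censor_rate_target: float = 0.5
    followup_max_years: Optional[float] = None  # None = tune to the target
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.n_causal <= self.n_genes:
            raise ValueError("need 0 < n_causal <= n_genes")
        if self.n_samples < 2:
            raise ValueError("need at least two samples")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be positive")
        if not 0 <= self.censor_rate_target < 1:
            raise ValueError("censor_rate_target must be in [0, 1)")


@dataclass(frozen=True)
class SyntheticTruth:
    causal_gene_ids: np.ndarray
    betas: np.ndarray
    censoring_fraction: float
    followup_max_years: float


def _minmax(v: np.ndarray) -> np.ndarray:
    rng_ = v.max() - v.min()
    if rng_ == 0:
        return np.zeros_like(v)
    return (v - v.min()) / rng_


def generate_cohort(
    cfg: SyntheticConfig,
) -> Tuple[ExpressionMatrix, SurvivalData, SyntheticTruth]:
    """Draw one cohort; bitwise-deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(derive_seed(cfg.seed, "cohort"))
    n, d = cfg.n_samples, cfg.n_genes
    width = max(4, len(str(d)))
    gene_ids = np.asarray([f"G{i:0{width}d}" for i in range(d)], dtype=object)
    sample_ids = np.asarray([f"S{i:04d}" for i in range(n)], dtype=object)

    # right-skewed counts: per-gene lognormal location/scale
    mu = rng.uniform(0.0, 6.0, size=d)
    sigma = rng.uniform(0.5, 1.5, size=d)
    values = rng.lognormal(mean=mu[None, :], sigma=sigma[None, :], size=(n, d))

    causal_idx = np.sort(rng.choice(d, size=cfg.n_causal, replace=False))
    betas = cfg.causal_beta * rng.choice([-1.0, 1.0], size=cfg.n_causal)

    z = np.column_stack(
        [_minmax(np.log2(1.0 + values[:, j])) for j in causal_idx]
    )
    # centred so baseline_hazard is the hazard of the average patient;
    # uncentred effects would shift the whole cohort's time scale
    linpred = (z - z.mean(axis=0)) @ betas
    rate = cfg.baseline_hazard * np.exp(linpred)
    event_years = rng.exponential(1.0 / rate)

    u = rng.uniform(1e-9, 1.0, size=n)

    def censored_fraction(followup: float) -> float:
        return float(np.mean(u * followup < event_years))

    if cfg.followup_max_years is not None:
        followup = cfg.followup_max_years
    elif cfg.censor_rate_target == 0:
        followup = float(np.inf)
    else:
        # realized censoring decreases as the follow-up horizon grows
        lo, hi = 1e-4, 1e5
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if censored_fraction(mid) > cfg.censor_rate_target:
                lo = mid
            else:
                hi = mid
        followup = 0.5 * (lo + hi)

    censor_years = u * followup
    censored = censor_years < event_years
    time_years = np.where(censored, censor_years, event_years)
    time_days = np.maximum(time_years * DAYS_PER_YEAR, 1e-3)

    surv = SurvivalData(sample_ids, time_days, censored)
    truth = SyntheticTruth(
        causal_gene_ids=gene_ids[causal_idx],
        betas=betas,
        censoring_fraction=float(np.mean(censored)),
        followup_max_years=float(followup),
    )
    return ExpressionMatrix(values, gene_ids, sample_ids), surv, truth
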