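from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cascadewx import (
    DAYS_PER_YEAR,
    ExpressionMatrix,
    SurvivalData,
    SyntheticConfig,
    generate_cohort,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_surv(times_years, censored, ids=None) -> SurvivalData:
    times_years = np.asarray(times_years, dtype=float)
    if ids is None:
        ids = [f"p{i+1}" for i in range(times_years.size)]
    return SurvivalData(
        np.asarray(ids, dtype=object),
        times_years * DAYS_PER_YEAR,
        np.asarray(censored, dtype=bool),
    )


def random_surv(rng: np.random.Generator, n: int, censor_frac: float = 0.3,
                tie_times: bool = False) -> SurvivalData:
    if tie_times:
        times = rng.integers(1, max(n // 2, 2), size=n).astype(float)
    else:
        times = rng.exponential(1000.0, size=n) + 1.0
    censored = rng.random(n) < censor_frac
    if censored.all():  # keep at least one event
        censored[int(rng.integers(n))] = False
    return SurvivalData(
        np.asarray([f"p{i}" for i in range(n)], dtype=object), times, censored
    )


@pytest.fixture(scope="session")
def small_cohort():
    """200 samples x 100 genes, 5 causal genes, ~50% censoring."""
    cfg = SyntheticConfig(n_samples=200, n_genes=100, n_causal=5, seed=11)
    return generate_cohort(cfg)


@pytest.fixture
def toy_expression() -> ExpressionMatrix:
    values = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
    return ExpressionMatrix(
        values,
        np.asarray(["TP53", "EGFR", "KRAS"], dtype=object),
        np.asarray(["s1", "s2"], dtype=object),
    )
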