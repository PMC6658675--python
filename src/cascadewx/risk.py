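"""Risk-group construction for one cascade step.

Each cascade step dichotomises patients by a pair of year cutoffs: a
patient who died within ``death_cut_years`` is high risk; a patient who
demonstrably lived beyond ``survive_cut_years`` (event or censored) is
low risk. Everyone else carries no usable outcome at these horizons —
censored before the survive cutoff, or an event falling between the two
cutoffs — and is excluded from that step's training.

Boundary convention: time exactly equal to the death cutoff counts as
"within" (HIGH if the event was observed); time exactly equal to the
survive cutoff does not count as "beyond" (not LOW).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import DAYS_PER_YEAR, EXCLUDED, HIGH, LOW, SurvivalData


@dataclass(frozen=True)
class CutoffPair:
    """Year cutoffs for one step, e.g. (3, 3), (2, 4) or (1, 5)."""

    death_cut_years: float
    survive_cut_years: float

    def __post_init__(self) -> None:
        if self.death_cut_years <= 0 or self.survive_cut_years <= 0:
            raise ValueError("cutoffs must be positive")
        if self.death_cut_years > self.survive_cut_years:
            raise ValueError(
                f"death cutoff {self.death_cut_years} exceeds survive cutoff "
                f"{self.survive_cut_years}"
            )


@dataclass(frozen=True)
class RiskLabelAssignment:
    sample_ids: np.ndarray
    labels: np.ndarray  # HIGH / LOW / EXCLUDED per sample
    cutoffs: CutoffPair

    @property
    def high_ids(self) -> list:
        return self.sample_ids[self.labels == HIGH].tolist()

    @property
    def low_ids(self) -> list:
        return self.sample_ids[self.labels == LOW].tolist()

    @property
    def labeled_ids(self) -> list:
        return self.sample_ids[self.labels != EXCLUDED].tolist()

    def counts(self) -> dict:
        return {
            lab: int(np.sum(self.labels == lab)) for lab in (HIGH, LOW, EXCLUDED)
        }


def assign_risk_labels(
    surv: SurvivalData, cut: CutoffPair, allow_empty: bool = False
) -> RiskLabelAssignment:
    """Label every sample HIGH, LOW or EXCLUDED for one cutoff pair.

    HIGH: event observed and time <= death cutoff. LOW: time > survive
    cutoff regardless of censoring. EXCLUDED: everyone else. With
    ``allow_empty=False`` an empty HIGH or LOW group is a hard error
    because the step would be untrainable.
    """
    years = surv.time_years
    event = surv.event_observed
    high = event & (years <= cut.death_cut_years)
    low = years > cut.survive_cut_years
    labels = np.full(surv.n_samples, EXCLUDED, dtype=object)
    labels[high] = HIGH
    labels[low] = LOW
    if not allow_empty:
        for name, mask in ((HIGH, high), (LOW, low)):
            if not mask.any():
                raise ValueError(
                    f"no {name}-risk samples at cutoffs "
                    f"({cut.death_cut_years}, {cut.survive_cut_years}) years"
                )
    return RiskLabelAssignment(surv.sample_ids, labels, cut)
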