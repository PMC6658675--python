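"""Core in-memory containers for survival-transcriptome cohorts.

The package works on two aligned tables: a samples x genes expression
matrix and a per-sample clinical record holding a follow-up time in days
and a right-censoring indicator (1 = censored, 0 = death observed).
Feature rankings produced by the selection machinery are total orders
over gene identifiers and carry, per gene, the score that placed it and
the cascade step at which it was eliminated (0 = survived to the end).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

DAYS_PER_YEAR = 365.25

HIGH = "HIGH"
LOW = "LOW"
EXCLUDED = "EXCLUDED"


def _as_str_array(ids: Iterable[str], what: str) -> np.ndarray:
    arr = np.asarray(list(ids), dtype=object)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{what} must be a non-empty 1-D sequence")
    if len(set(arr.tolist())) != arr.size:
        seen: set = set()
        for x in arr.tolist():
            if x in seen:
                raise ValueError(f"duplicate {what[:-1]}: {x!r}")
            seen.add(x)
    return arr


@dataclass(frozen=True)
class ExpressionMatrix:
    """Samples x genes matrix of non-negative, finite expression values."""

    values: np.ndarray
    gene_ids: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", _as_str_array(self.gene_ids, "gene_ids"))
        object.__setattr__(
            self, "sample_ids", _as_str_array(self.sample_ids, "sample_ids")
        )
        if values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n, d = values.shape
        if n != self.sample_ids.size or d != self.gene_ids.size:
            raise ValueError(
                f"shape {values.shape} does not match {self.sample_ids.size} samples "
                f"x {self.gene_ids.size} genes"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("expression values must be finite")
        if np.any(values < 0):
            raise ValueError("expression values must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene_ids: Sequence[str]) -> np.ndarray:
        pos: Mapping[str, int] = {g: i for i, g in enumerate(self.gene_ids.tolist())}
        try:
            return np.array([pos[g] for g in gene_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown gene id {exc.args[0]!r}") from None

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_index(gene_ids)
        return ExpressionMatrix(
            self.values[:, idx], np.asarray(list(gene_ids), dtype=object), self.sample_ids
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids.tolist())}
        try:
            idx = np.array([pos[s] for s in sample_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from None
        return ExpressionMatrix(
            self.values[idx, :], self.gene_ids, np.asarray(list(sample_ids), dtype=object)
        )


@dataclass(frozen=True)
class SurvivalData:
    """Right-censored follow-up: time in days and a censoring indicator.

    ``censored[i]`` is True when the death event was NOT observed within
    follow-up; the recorded time is then only a lower bound.
    """

    sample_ids: np.ndarray
    time_days: np.ndarray
    censored: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sample_ids", _as_str_array(self.sample_ids, "sample_ids")
        )
        time = np.asarray(self.time_days, dtype=float)
        cens = np.asarray(self.censored, dtype=bool)
        object.__setattr__(self, "time_days", time)
        object.__setattr__(self, "censored", cens)
        if time.shape != (self.sample_ids.size,) or cens.shape != time.shape:
            raise ValueError("sample_ids, time_days and censored must align 1:1")
        if not np.all(np.isfinite(time)) or np.any(time <= 0):
            raise ValueError("survival times must be finite and > 0")

    @property
    def n_samples(self) -> int:
        return self.sample_ids.size

    @property
    def event_observed(self) -> np.ndarray:
        return ~self.censored

    @property
    def time_years(self) -> np.ndarray:
        return self.time_days / DAYS_PER_YEAR

    def subset(self, sample_ids: Sequence[str]) -> "SurvivalData":
        pos = {s: i for i, s in enumerate(self.sample_ids.tolist())}
        try:
            idx = np.array([pos[s] for s in sample_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from None
        return SurvivalData(
            np.asarray(list(sample_ids), dtype=object),
            self.time_days[idx],
            self.censored[idx],
        )


def check_aligned(expr: ExpressionMatrix, surv: SurvivalData) -> None:
    """Require identical sample ids in identical order."""
    if expr.sample_ids.tolist() != surv.sample_ids.tolist():
        raise ValueError("expression matrix and survival data sample ids do not align")


@dataclass(frozen=True)
class FeatureRanking:
    """Total order over genes; position 0 is rank 1 (most prognostic).

    ``provenance[i]`` is the cascade step at which the gene at rank i+1
    was eliminated; 0 means it survived to the final step.
    """

    gene_ids: np.ndarray
    scores: np.ndarray
    provenance: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", _as_str_array(self.gene_ids, "gene_ids"))
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if scores.shape != (self.gene_ids.size,):
            raise ValueError("scores must align with gene_ids")
        prov = self.provenance
        if prov is None:
            prov = np.zeros(self.gene_ids.size, dtype=int)
        prov = np.asarray(prov, dtype=int)
        if prov.shape != (self.gene_ids.size,):
            raise ValueError("provenance must align with gene_ids")
        object.__setattr__(self, "provenance", prov)

    @property
    def n_genes(self) -> int:
        return self.gene_ids.size

    def ranks(self) -> dict:
        """Map gene id -> rank (1-based)."""
        return {g: i + 1 for i, g in enumerate(self.gene_ids.tolist())}

    def top(self, k: int) -> list:
        if not 1 <= k <= self.n_genes:
            raise ValueError(f"k={k} outside 1..{self.n_genes}")
        return self.gene_ids[:k].tolist()
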