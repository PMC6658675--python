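"""Reading, writing and preprocessing of expression and clinical tables.

Expression tables are tab-separated text with one header row. The
firehose-style dialect puts genes in rows (first column gene ids, header
of sample ids); the transposed dialect puts samples in rows. Clinical
tables carry ``sample_id``, ``time_days`` and ``censored`` (0/1)
columns.

Preprocessing follows the standard RNA-seq recipe for count-scale data:
x -> log2(x + 1) to tame the right skew, removal of genes with no
variance, then per-gene min-max normalization onto [0, 1].
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, SurvivalData

GENES_IN_ROWS = "genes_in_rows"
SAMPLES_IN_ROWS = "samples_in_rows"


def _read_tsv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty expression table: {path}") from None
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"expression table has no data rows/columns: {path}")
    return df


def read_expression_table(path, orientation: str = GENES_IN_ROWS) -> ExpressionMatrix:
    """Read a TSV expression table into a samples x genes matrix.

    ``orientation`` names the layout of the *file*; the returned matrix
    is always samples x genes.
    """
    if orientation not in (GENES_IN_ROWS, SAMPLES_IN_ROWS):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_tsv(path)
    if orientation == GENES_IN_ROWS:
        df = df.T  # now samples x genes
    # duplicate ids: genes are columns after orientation fix
    for axis, what in ((df.columns, "gene id"), (df.index, "sample id")):
        dup = axis[axis.duplicated()]
        if len(dup):
            raise ValueError(f"duplicate {what}: {dup[0]!r}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at sample {df.index[i]!r}, gene {df.columns[j]!r}: "
            f"{df.iat[i, j]!r}"
        )
    if numeric.isna().to_numpy().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(f"missing value at sample {df.index[i]!r}, gene {df.columns[j]!r}")
    return ExpressionMatrix(
        numeric.to_numpy(dtype=float),
        np.asarray(df.columns.tolist(), dtype=object),
        np.asarray(df.index.tolist(), dtype=object),
    )


def write_expression_table(m: ExpressionMatrix, path, orientation: str = GENES_IN_ROWS) -> None:
    df = pd.DataFrame(m.values, index=m.sample_ids.tolist(), columns=m.gene_ids.tolist())
    if orientation == GENES_IN_ROWS:
        df = df.T
        df.index.name = "gene_id"
    elif orientation == SAMPLES_IN_ROWS:
        df.index.name = "sample_id"
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    df.to_csv(path, sep="\t")


def read_clinical_table(path) -> SurvivalData:
    """Read a clinical TSV with columns sample_id, time_days, censored."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty clinical table: {path}") from None
    for col in ("sample_id", "time_days", "censored"):
        if col not in df.columns:
            raise ValueError(f"clinical table missing column {col!r}")
    time = pd.to_numeric(df["time_days"], errors="coerce")
    if time.isna().any():
        raise ValueError(
            f"non-numeric time_days for sample {df['sample_id'][time.isna().idxmax()]!r}"
        )
    if (time <= 0).any():
        raise ValueError(
            f"non-positive time_days for sample {df['sample_id'][(time <= 0).idxmax()]!r}"
        )
    cens_raw = pd.to_numeric(df["censored"], errors="coerce")
    if cens_raw.isna().any() or not cens_raw.isin([0, 1]).all():
        bad = df["sample_id"][~cens_raw.isin([0, 1])].iloc[0]
        raise ValueError(f"censored must be 0 or 1; offending sample {bad!r}")
    return SurvivalData(
        np.asarray(df["sample_id"].tolist(), dtype=object),
        time.to_numpy(dtype=float),
        cens_raw.to_numpy(dtype=int).astype(bool),
    )


def write_clinical_table(surv: SurvivalData, path) -> None:
    pd.DataFrame(
        {
            "sample_id": surv.sample_ids.tolist(),
            "time_days": surv.time_days,
            "censored": surv.censored.astype(int),
        }
    ).to_csv(path, sep="\t", index=False)


def log2_plus_one(m: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise x -> log2(x + 1); shape and identifiers unchanged."""
    if np.any(m.values < 0):
        raise ValueError("log2_plus_one requires non-negative input")
    return ExpressionMatrix(np.log2(m.values + 1.0), m.gene_ids, m.sample_ids)


def fit_minmax(m: ExpressionMatrix) -> Tuple[np.ndarray, np.ndarray]:
    """Per-gene (min, range) over all samples; errors on zero-range genes."""
    mins = m.values.min(axis=0)
    ranges = m.values.max(axis=0) - mins
    zero = np.flatnonzero(ranges == 0)
    if zero.size:
        raise ValueError(
            f"gene {m.gene_ids[zero[0]]!r} has zero range; drop zero-variance genes first"
        )
    return mins, ranges


def apply_minmax(
    m: ExpressionMatrix, mins: np.ndarray, ranges: np.ndarray, clip: bool = True
) -> ExpressionMatrix:
    out = (m.values - mins) / ranges
    if clip:  # keeps held-out samples inside [0, 1]
        out = np.clip(out, 0.0, 1.0)
    return ExpressionMatrix(out, m.gene_ids, m.sample_ids)


def minmax_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene min-max scaling onto [0, 1] over all samples."""
    mins, ranges = fit_minmax(m)
    return apply_minmax(m, mins, ranges, clip=False)


def drop_zero_variance(m: ExpressionMatrix) -> ExpressionMatrix:
    """Remove genes whose values are exactly identical across samples."""
    keep = np.flatnonzero(np.any(m.values != m.values[0, :], axis=0))
    if keep.size == 0:
        raise ValueError("all genes have zero variance")
    if keep.size == m.n_genes:
        return m
    return ExpressionMatrix(m.values[:, keep], m.gene_ids[keep], m.sample_ids)


def preprocess(m: ExpressionMatrix) -> ExpressionMatrix:
    """Full default recipe: drop zero-variance, log2(x+1), min-max."""
    return minmax_normalize(log2_plus_one(drop_zero_variance(m)))
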