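"""Expression matrix I/O and preprocessing.

Reads tab-delimited expression matrices (rows = probes or genes, columns =
samples, VSN-style normalized intensities), collapses probes to genes by
averaging, and splits samples into the two phenotype groups that all
downstream correlation work compares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

MIN_GROUP_SIZE = 3


class ExpressionError(ValueError):
    """Raised for malformed or degenerate expression inputs."""


@dataclass
class ExpressionMatrix:
    """A genes x samples intensity table with a two-group sample labelling.

    Attributes
    ----------
    values : pandas.DataFrame
        Float intensities, index = gene (or probe) ids, columns = sample ids,
        on the normalized scale the source provides.
    group_of : dict
        sample_id -> group label; exactly two distinct labels, each backing
        at least ``MIN_GROUP_SIZE`` samples (Pearson r on fewer than three
        observations is degenerate).
    """

    values: pd.DataFrame
    group_of: dict[str, str] = field(repr=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        df = self.values
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ExpressionError(f"duplicate row ids: {dups[:5]}")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ExpressionError(f"duplicate sample ids: {dups[:5]}")
        missing = [s for s in df.columns if s not in self.group_of]
        if missing:
            raise ExpressionError(f"samples without a group label: {missing[:5]}")
        labels = {self.group_of[s] for s in df.columns}
        if len(labels) != 2:
            raise ExpressionError(
                f"expected exactly 2 group labels among samples, got {sorted(labels)}"
            )
        for lab in sorted(labels):
            n = sum(1 for s in df.columns if self.group_of[s] == lab)
            if n < MIN_GROUP_SIZE:
                raise ExpressionError(
                    f"group {lab!r} has {n} samples; at least {MIN_GROUP_SIZE} required"
                )
        if df.isna().any().any():
            raise ExpressionError("matrix contains missing values after preprocessing")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def group_labels(self) -> tuple[str, str]:
        labs = sorted({self.group_of[s] for s in self.sample_ids})
        return labs[0], labs[1]


def _read_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, compression="infer")
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    return df


def load_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column (sample_id, group) tab-delimited file."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ExpressionError(f"labels file {path} needs 2 columns, found {df.shape[1]}")
    if df.iloc[:, :2].isna().any().any():
        raise ExpressionError(f"labels file {path} has rows with missing fields")
    return {str(r[0]).strip(): str(r[1]).strip() for r in df.itertuples(index=False)}


def load_expression(matrix_path: str | Path, labels_path: str | Path) -> ExpressionMatrix:
    """Load and validate an expression matrix with its group labels.

    The matrix is tab-delimited with a header row of sample ids and the
    first column holding probe/gene ids; labels map every sample to one of
    exactly two groups. Sample order is preserved as in the file. Rows with
    any missing value are dropped (complete-case) with a logged warning,
    since correlations over differing sample subsets would break the common
    evaluation grid downstream.
    """
    df = _read_table(matrix_path)
    if df.shape[1] < 2 * MIN_GROUP_SIZE:
        raise ExpressionError(
            f"{matrix_path}: only {df.shape[1]} samples; two groups of >= {MIN_GROUP_SIZE} needed"
        )
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ExpressionError(f"{matrix_path}: non-numeric cells ({exc})") from exc

    n_na = int(df.isna().any(axis=1).sum())
    if n_na:
        logger.warning("dropping %d rows with missing values (complete-case)", n_na)
        df = df.dropna(axis=0)

    labels = load_labels(labels_path)
    return ExpressionMatrix(values=df, group_of=labels)


def write_expression(m: ExpressionMatrix, matrix_path: str | Path, labels_path: str | Path) -> None:
    """Write the matrix and its labels in the formats :func:`load_expression` reads."""
    m.values.to_csv(matrix_path, sep="\t")
    with open(labels_path, "w") as fh:
        for s in m.sample_ids:
            fh.write(f"{s}\t{m.group_of[s]}\n")


def load_probe_map(path: str | Path) -> dict[str, str]:
    """Read a two-column (probe_id, gene_id) tab-delimited file."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2 or df.iloc[:, :2].isna().any().any():
        raise ExpressionError(f"probe map {path} must have 2 complete columns")
    out: dict[str, str] = {}
    for probe, gene in zip(df.iloc[:, 0], df.iloc[:, 1]):
        probe, gene = probe.strip(), gene.strip()
        if probe in out and out[probe] != gene:
            raise ExpressionError(f"probe {probe!r} maps to multiple genes")
        out[probe] = gene
    return out


def collapse_probes(raw: ExpressionMatrix, probe_map: dict[str, str]) -> ExpressionMatrix:
    """Collapse probe-level rows to one row per gene by arithmetic mean.

    Microarray platforms interrogate a gene with several probes; the
    per-sample gene intensity is the mean of its probes' intensities,
    computed on the normalized scale as provided.
    """
    unmapped = [p for p in raw.values.index if p not in probe_map]
    if unmapped:
        raise ExpressionError(f"probes without gene assignment: {unmapped[:10]}")
    genes = pd.Index([probe_map[p] for p in raw.values.index], name=raw.values.index.name)
    collapsed = raw.values.groupby(genes, sort=True).mean()
    return ExpressionMatrix(values=collapsed, group_of=dict(raw.group_of))


def split_groups(m: ExpressionMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition the samples into the two groups (label-sorted order).

    Returns the sub-matrices for the lexicographically first and second
    group labels; gene order is identical in both.
    """
    a_lab, b_lab = m.group_labels
    a_cols = [s for s in m.sample_ids if m.group_of[s] == a_lab]
    b_cols = [s for s in m.sample_ids if m.group_of[s] == b_lab]
    return m.values[a_cols], m.values[b_cols]


def group_submatrix(m: ExpressionMatrix, label: str) -> pd.DataFrame:
    """The sub-matrix of samples carrying ``label``."""
    if label not in m.group_labels:
        raise ExpressionError(f"unknown group label {label!r}; have {m.group_labels}")
    cols = [s for s in m.sample_ids if m.group_of[s] == label]
    return m.values[cols]
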