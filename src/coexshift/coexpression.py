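"""Pairwise coexpression: absolute Pearson correlation per group.

The coexpression level of a gene pair within one phenotype group is
``C(i,j) = |cor(x_i, x_j)|`` — the absolute Pearson correlation of the two
genes' expression profiles across that group's samples. Absolute values are
used because a strong negative correlation is as much a biological
relationship as a strong positive one; levels live in [0, 1].
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: column order of the serialized pair table
PAIR_COLUMNS = ["gene_i", "gene_j", "c_normal", "c_disease"]


class CoexpressionError(ValueError):
    pass


def abs_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Absolute Pearson correlation of two profiles, in [0, 1].

    Zero-variance input is a named degenerate condition (the correlation is
    undefined), raised rather than silently mapped to 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise CoexpressionError("profiles must be 1-D and equally long")
    if x.size < 3:
        raise CoexpressionError("need at least 3 samples for a meaningful correlation")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.sqrt(xc @ xc))
    sy = float(np.sqrt(yc @ yc))
    if sx == 0.0 or sy == 0.0:
        raise CoexpressionError("zero-variance profile: Pearson correlation undefined")
    return min(abs(float(xc @ yc) / (sx * sy)), 1.0)


def _abs_corr_matrix(sub: pd.DataFrame) -> np.ndarray:
    """|r| over all row pairs of a genes x samples block, clamped to [0, 1]."""
    r = np.corrcoef(sub.to_numpy(dtype=float))
    return np.clip(np.abs(r), 0.0, 1.0)


def pairwise_coexpression(
    disease: pd.DataFrame, normal: pd.DataFrame, genes: list[str]
) -> pd.DataFrame:
    """Coexpression table over all unordered candidate gene pairs.

    Parameters
    ----------
    disease, normal : DataFrame
        Per-group sub-matrices (genes x samples) containing every gene in
        ``genes``.
    genes : list of str
        Candidate genes; pairs are enumerated in lexicographic order with
        ``gene_i < gene_j``.

    Returns
    -------
    DataFrame with columns gene_i, gene_j, c_normal, c_disease, one row per
    pair, n*(n-1)/2 rows for n surviving genes. Genes with zero variance in
    either group are removed first (logged) and the pair universe rebuilt
    from the survivors.
    """
    for name, sub in (("disease", disease), ("normal", normal)):
        missing = [g for g in genes if g not in sub.index]
        if missing:
            raise CoexpressionError(f"{name} sub-matrix lacks genes: {missing[:5]}")
        if sub.shape[1] < 3:
            raise CoexpressionError(f"{name} group has fewer than 3 samples")

    genes = sorted(genes)
    d = disease.loc[genes]
    n = normal.loc[genes]
    ok = (d.std(axis=1, ddof=0) > 0) & (n.std(axis=1, ddof=0) > 0)
    if not ok.all():
        logger.warning("removing %d zero-variance genes before pairing", int((~ok).sum()))
        genes = [g for g, keep in zip(genes, ok) if keep]
    if len(genes) < 2:
        raise CoexpressionError("fewer than 2 genes survive the variance filter")

    cd = _abs_corr_matrix(d.loc[genes])
    cn = _abs_corr_matrix(n.loc[genes])
    iu, ju = np.triu_indices(len(genes), k=1)
    garr = np.asarray(genes, dtype=object)
    return pd.DataFrame(
        {
            "gene_i": garr[iu],
            "gene_j": garr[ju],
            "c_normal": cn[iu, ju],
            "c_disease": cd[iu, ju],
        }
    )


def write_pairs(table: pd.DataFrame, path: str | Path) -> None:
    """Serialize the pair table as TSV; levels at 6 decimal places."""
    out = table.copy()
    for col in out.columns:
        if col.startswith("c_"):
            out[col] = out[col].map(lambda v: f"{v:.6f}")
    out.to_csv(path, sep="\t", index=False)


def read_pairs(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
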