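"""Candidate gene selection from a TF -> target-gene reference.

The candidates are the genes regulated concurrently by every requested
transcription factor (e.g. E2F1, E2F2, E2F3 and MYC), restricted to genes
actually measured on the array. Gene symbols are matched exactly after
upper-casing and whitespace stripping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .expression_io import ExpressionMatrix

logger = logging.getLogger(__name__)


class TargetSelectionError(ValueError):
    pass


def normalize_symbol(g: str) -> str:
    return str(g).strip().upper()


@dataclass
class RegulatoryReference:
    """Mapping TF name -> set of target gene symbols (case-normalized)."""

    tf_targets: dict[str, set[str]]

    def __post_init__(self) -> None:
        for tf, targets in self.tf_targets.items():
            if not targets:
                raise TargetSelectionError(f"TF {tf!r} has an empty target set")

    @property
    def tfs(self) -> list[str]:
        return sorted(self.tf_targets)


def load_tf_targets(path: str | Path) -> RegulatoryReference:
    """Read a two-column (TF, target_gene) TSV; duplicate rows collapse."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.empty:
        raise TargetSelectionError(f"TF-target reference {path} is empty")
    if df.shape[1] < 2 or df.iloc[:, :2].isna().any().any():
        raise TargetSelectionError(f"{path}: rows with missing TF or gene fields")
    mapping: dict[str, set[str]] = {}
    for tf, gene in zip(df.iloc[:, 0], df.iloc[:, 1]):
        mapping.setdefault(normalize_symbol(tf), set()).add(normalize_symbol(gene))
    return RegulatoryReference(tf_targets=mapping)


def write_tf_targets(ref: RegulatoryReference, path: str | Path) -> None:
    with open(path, "w") as fh:
        for tf in ref.tfs:
            for gene in sorted(ref.tf_targets[tf]):
                fh.write(f"{tf}\t{gene}\n")


def common_targets(ref: RegulatoryReference, tfs: list[str]) -> set[str]:
    """Intersection of the target sets of all requested TFs (may be empty)."""
    if not tfs:
        raise TargetSelectionError("at least one TF must be requested")
    result: set[str] | None = None
    for tf in tfs:
        key = normalize_symbol(tf)
        if key not in ref.tf_targets:
            raise TargetSelectionError(f"unknown TF {tf!r} (not in reference)")
        targets = ref.tf_targets[key]
        result = set(targets) if result is None else result & targets
    assert result is not None
    return result


def restrict_to_measured(candidates: set[str], m: ExpressionMatrix) -> list[str]:
    """Sorted list of candidate genes present in the expression matrix.

    Raises when fewer than two candidates are measured — pair-level
    coexpression needs at least one gene pair.
    """
    measured = {normalize_symbol(g): g for g in m.gene_ids}
    kept = sorted(measured[normalize_symbol(c)] for c in candidates
                  if normalize_symbol(c) in measured)
    dropped = len(candidates) - len(kept)
    if dropped:
        logger.info("dropped %d candidate genes absent from the matrix", dropped)
    if len(kept) < 2:
        raise TargetSelectionError(
            f"only {len(kept)} candidate gene(s) measured; need at least 2 to form pairs"
        )
    return kept
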