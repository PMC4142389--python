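"""Synthetic inputs with the statistical structure the pipeline assumes.

The generator emulates a small two-group microarray study: two groups of
8-10 samples, a few dozen to a few thousand genes on a normalized intensity
scale, and a block of genes that is strongly coexpressed in one group and
decorrelated in the other. Block genes follow a single-factor
equicorrelation model per group,

    x_g,s = baseline + noise_sd * (sqrt(rho) * z_s + sqrt(1 - rho) * eps_g,s),

which gives every block pair population correlation rho within that group;
non-block genes are independent noise. Defaults mirror an 8-normal /
9-disease CD34+ design.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment_mapping import write_gmt
from .expression_io import ExpressionMatrix
from .target_selection import RegulatoryReference, write_tf_targets

BASELINE_INTENSITY = 8.0  # typical VSN-scale level; shifts nothing correlation-wise

DEFAULT_TFS = ("E2F1", "E2F2", "E2F3", "MYC")


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study.

    rho_normal / rho_disease are the within-block target correlations per
    group, in [0, 1); the defaults (0.85 vs 0.0) encode a coexpression
    module present in the normal state and dissolved in disease.
    """

    n_genes: int = 60
    n_block: int = 12
    rho_normal: float = 0.85
    rho_disease: float = 0.0
    n_normal: int = 8
    n_disease: int = 9
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.n_block <= self.n_genes:
            raise ValueError("need 0 < n_block <= n_genes")
        for rho in (self.rho_normal, self.rho_disease):
            if not 0.0 <= rho < 1.0:
                raise ValueError(f"correlation {rho} outside [0, 1)")
        if min(self.n_normal, self.n_disease) < 3:
            raise ValueError("each group needs at least 3 samples")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(1, self.n_genes + 1)]

    @property
    def block_genes(self) -> list[str]:
        return self.gene_ids[: self.n_block]


def _group_block(rng: np.random.Generator, n_genes: int, n_block: int,
                 n_samples: int, rho: float, noise_sd: float) -> np.ndarray:
    x = rng.standard_normal((n_genes, n_samples))
    if rho > 0:
        z = rng.standard_normal(n_samples)
        x[:n_block] = np.sqrt(rho) * z + np.sqrt(1.0 - rho) * x[:n_block]
    return BASELINE_INTENSITY + noise_sd * x


def generate_expression(spec: SyntheticSpec) -> ExpressionMatrix:
    """Deterministic (per seed) expression matrix with normal/disease labels."""
    rng = np.random.default_rng(spec.seed)
    normal = _group_block(rng, spec.n_genes, spec.n_block, spec.n_normal,
                          spec.rho_normal, spec.noise_sd)
    disease = _group_block(rng, spec.n_genes, spec.n_block, spec.n_disease,
                           spec.rho_disease, spec.noise_sd)
    normal_ids = [f"N{i:02d}" for i in range(1, spec.n_normal + 1)]
    disease_ids = [f"D{i:02d}" for i in range(1, spec.n_disease + 1)]
    values = pd.DataFrame(
        np.hstack([normal, disease]),
        index=pd.Index(spec.gene_ids, name="gene"),
        columns=normal_ids + disease_ids,
    )
    groups = {s: "normal" for s in normal_ids} | {s: "disease" for s in disease_ids}
    return ExpressionMatrix(values=values, group_of=groups)


def generate_reference(genes: list[str], tfs: list[str] = list(DEFAULT_TFS),
                       coverage: float = 0.5, seed: int = 0,
                       block: list[str] | None = None) -> RegulatoryReference:
    """TF -> target reference whose all-TF intersection contains the block.

    Each TF receives an independent random subset of ``coverage`` of the
    genes; the correlated block is forced into every TF's target set so the
    common-target intersection recovers it by construction.
    """
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    block = list(block or [])
    mapping: dict[str, set[str]] = {}
    n_pick = max(1, int(round(coverage * len(genes))))
    for tf in tfs:
        picked = set(rng.choice(genes, size=n_pick, replace=False))
        mapping[tf] = picked | set(block)
    ref = RegulatoryReference(tf_targets=mapping)
    for tf in tfs:  # construction guarantee
        assert set(block) <= ref.tf_targets[tf]
    return ref


def generate_gene_sets(genes: list[str], block: list[str], n_sets: int = 8,
                       set_size: int = 10, seed: int = 0) -> dict[str, set[str]]:
    """Gene-set collection with one block-enriched "signal" set.

    The signal set draws at least half its members from the correlated
    block; the remaining sets are uniform draws from all genes.
    """
    if set_size > len(genes):
        raise ValueError("set_size exceeds the number of genes")
    rng = np.random.default_rng(seed)
    n_signal = min(len(block), max(set_size // 2, (set_size + 1) // 2))
    signal = set(rng.choice(block, size=n_signal, replace=False))
    rest = [g for g in genes if g not in signal]
    signal |= set(rng.choice(rest, size=set_size - n_signal, replace=False))
    sets = {"signal_set": signal}
    for i in range(1, n_sets):
        sets[f"random_set_{i:02d}"] = set(rng.choice(genes, size=set_size, replace=False))
    return sets


def write_synthetic_inputs(spec: SyntheticSpec, out_dir: str | Path,
                           tfs: tuple[str, ...] = DEFAULT_TFS,
                           coverage: float = 0.5, n_sets: int = 8,
                           set_size: int = 10) -> dict[str, Path]:
    """Generate and write every pipeline input under ``out_dir``.

    Returns the paths of the expression matrix, labels, TF reference and
    GMT collection. All derived seeds come from ``spec.seed``.
    """
    from .expression_io import write_expression

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    m = generate_expression(spec)
    paths = {
        "expression": out / "expression.tsv",
        "labels": out / "labels.tsv",
        "tf_reference": out / "tf_targets.tsv",
        "gene_sets": out / "gene_sets.gmt",
    }
    write_expression(m, paths["expression"], paths["labels"])
    ref = generate_reference(spec.gene_ids, list(tfs), coverage=coverage,
                             seed=spec.seed + 1, block=spec.block_genes)
    write_tf_targets(ref, paths["tf_reference"])
    sets = generate_gene_sets(spec.gene_ids, spec.block_genes, n_sets=n_sets,
                              set_size=set_size, seed=spec.seed + 2)
    write_gmt(sets, paths["gene_sets"])
    return paths
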