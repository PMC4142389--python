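"""End-to-end orchestration: load -> select -> correlate -> cut -> classify
-> enrich -> export, with a machine-readable run report.

Every output is reproducible byte-identically given the same inputs: the
report is JSON with sorted keys and contains no timestamps or paths that
vary between runs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

from . import coexpression, cutoff_classification, enrichment_mapping
from .enrichment_mapping import annotated_pairs, load_gene_sets, results_frame, run_enrichment
from .expression_io import (
    collapse_probes,
    group_submatrix,
    load_expression,
    load_probe_map,
)
from .network_export import export_mapped_networks
from .target_selection import common_targets, load_tf_targets, restrict_to_measured

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage."""


@dataclass
class RunConfig:
    expression: str
    labels: str
    tf_reference: str
    gene_sets: str
    tfs: list[str]
    probe_map: str | None = None
    normal_label: str = "normal"
    disease_label: str = "disease"
    cutoff_override: float | None = None
    fdr_threshold: float = 0.05
    output_dir: str = "coexshift_out"
    network_class: str = "normal_specific_strong"

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_threshold < 1.0:
            raise ValueError("fdr_threshold must lie in (0, 1)")
        if not self.tfs:
            raise ValueError("at least one TF required")

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        if isinstance(raw.get("tfs"), str):
            raw["tfs"] = [t.strip() for t in raw["tfs"].split(",") if t.strip()]
        return cls(**raw)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                logger.info("stage %s", name)
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis; write report.json, pairs.tsv,
    enrichment.tsv and networks/ under the output directory; return the
    report dict."""
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    m = _stage("load")(load_expression)(cfg.expression, cfg.labels)
    if cfg.probe_map:
        pm = _stage("probe_map")(load_probe_map)(cfg.probe_map)
        m = _stage("collapse")(collapse_probes)(m, pm)
    if set(m.group_labels) != {cfg.normal_label, cfg.disease_label}:
        raise PipelineError(
            f"stage 'load' failed: group labels {m.group_labels} do not match "
            f"configured ({cfg.normal_label!r}, {cfg.disease_label!r})"
        )

    ref = _stage("tf_reference")(load_tf_targets)(cfg.tf_reference)
    candidates = _stage("candidate_selection")(
        lambda: restrict_to_measured(common_targets(ref, cfg.tfs), m)
    )()

    normal = group_submatrix(m, cfg.normal_label)
    disease = group_submatrix(m, cfg.disease_label)
    table = _stage("coexpression")(coexpression.pairwise_coexpression)(
        disease, normal, candidates
    )

    ks = _stage("ks_cutoff")(cutoff_classification.ks_max_deviation)(
        table["c_disease"].to_numpy(), table["c_normal"].to_numpy()
    )
    cutoff = cfg.cutoff_override if cfg.cutoff_override is not None else ks.C
    cls = _stage("classification")(cutoff_classification.classify_pairs)(table, cutoff)
    counts = cutoff_classification.count_classes(cls)
    chi2, chi2_p = _stage("chi_square")(cutoff_classification.chi2_proportions)(counts)

    collection = _stage("gene_sets")(load_gene_sets)(cfg.gene_sets, len(m.gene_ids))
    results = _stage("enrichment")(run_enrichment)(
        collection, candidates, cls, cfg.fdr_threshold
    )

    set_pairs = {r.set_name: annotated_pairs(collection.sets[r.set_name], candidates)
                 for r in results}
    _stage("network_export")(export_mapped_networks)(
        set_pairs, cls, out_dir / "networks", cfg.network_class
    )

    coexpression.write_pairs(cls, out_dir / "pairs.tsv")
    results_frame(results).to_csv(out_dir / "enrichment.tsv", sep="\t", index=False,
                                  float_format="%.6g")

    report = {
        "n_genes_measured": len(m.gene_ids),
        "n_samples": {cfg.normal_label: normal.shape[1], cfg.disease_label: disease.shape[1]},
        "n_candidate_genes": len(candidates),
        "n_pairs": int(len(table)),
        "ks": ks.to_dict(),
        "cutoff_used": float(cutoff),
        "cutoff_overridden": cfg.cutoff_override is not None,
        "class_counts": counts.to_dict(),
        "chi2": {"statistic": chi2, "p_value": chi2_p},
        "enrichment": [
            {
                "set": r.set_name,
                "a": r.counts.a, "b": r.counts.b, "c": r.counts.c, "d": r.counts.d,
                "annotated_gene_count": r.annotated_gene_count,
                "annotated_pair_count": r.annotated_pair_count,
                "hypergeom_p": r.hypergeom_p,
                "fisher_p": r.fisher_p,
                "fdr": r.fdr,
                "significant": r.significant,
            }
            for r in results
        ],
        "fdr_threshold": cfg.fdr_threshold,
        "tfs": list(cfg.tfs),
    }
    report_path = out_dir / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("report written to %s", report_path)
    return report


REPORT_REQUIRED_KEYS = {
    "n_genes_measured", "n_samples", "n_candidate_genes", "n_pairs", "ks",
    "cutoff_used", "cutoff_overridden", "class_counts", "chi2", "enrichment",
    "fdr_threshold", "tfs",
}


def validate_report(report: dict) -> bool:
    """Schema check used by the CLI exit-code contract."""
    return REPORT_REQUIRED_KEYS <= set(report)
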