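"""Candidate selection, pairwise coexpression, and the KS-derived cutoff.

Loads the simulated inputs, intersects the four TFs' target sets against
the measured genes, computes |r| for every candidate pair in each group,
locates the cutoff C at the maximum deviation D of the two survival
functions, classifies pairs, and chi-square-tests the strong/weak
proportions. Writes results/pairs.tsv, results/candidates.txt and
results/cutoff_report.json.
"""

import json
from pathlib import Path

import coexshift as cx
from coexshift.coexpression import write_pairs
from coexshift.expression_io import group_submatrix

ROOT = Path(__file__).resolve().parent.parent / "results"
TFS = ["E2F1", "E2F2", "E2F3", "MYC"]


def main() -> None:
    m = cx.load_expression(ROOT / "inputs" / "expression.tsv", ROOT / "inputs" / "labels.tsv")
    ref = cx.load_tf_targets(ROOT / "inputs" / "tf_targets.tsv")
    candidates = cx.restrict_to_measured(cx.common_targets(ref, TFS), m)
    print(f"{len(candidates)} candidate genes targeted by all of {', '.join(TFS)}")

    normal = group_submatrix(m, "normal")
    disease = group_submatrix(m, "disease")
    table = cx.pairwise_coexpression(disease, normal, candidates)
    print(f"{len(table)} unordered gene pairs correlated in both groups")

    ks = cx.ks_max_deviation(table["c_disease"].to_numpy(), table["c_normal"].to_numpy())
    cls = cx.classify_pairs(table, ks.C)
    counts = cx.count_classes(cls)
    chi2, chi2_p = cx.chi2_proportions(counts)
    print(f"max deviation D={ks.D:.4f} at cutoff C={ks.C:.3f} (KS p={ks.p_value:.3g})")
    print(f"strong pairs: normal {counts.strong_normal}, disease {counts.strong_disease} "
          f"(chi2={chi2:.1f}, p={chi2_p:.3g})")

    write_pairs(cls, ROOT / "pairs.tsv")
    (ROOT / "candidates.txt").write_text("\n".join(candidates) + "\n")
    with open(ROOT / "cutoff_report.json", "w") as fh:
        json.dump({"ks": ks.to_dict(), "class_counts": counts.to_dict(),
                   "chi2": {"statistic": chi2, "p_value": chi2_p},
                   "n_candidates": len(candidates), "n_pairs": len(table)},
                  fh, indent=2, sort_keys=True)
        fh.write("\n")


if __name__ == "__main__":
    main()
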