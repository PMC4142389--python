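"""Gene-set annotation, pair mapping, and one-sided Fisher enrichment.

Candidate genes are annotated against named gene sets (GMT collections,
standing in for curated process networks). Each set's annotated genes are
paired exhaustively; those pairs are mapped onto the four group-specific
coexpression classes, giving a 2x2 table

    a  mapped normal-specific strongly coexpressed pairs
    b  mapped normal-specific weakly coexpressed pairs
    c  mapped disease-specific strongly coexpressed pairs
    d  mapped disease-specific weakly coexpressed pairs

with a = d and b = c by the class identities. A one-sided Fisher's exact
test (upper tail in a) asks whether the set's pairs are preferentially
coexpressed in the normal group; Benjamini-Hochberg FDR controls across
sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .target_selection import normalize_symbol

logger = logging.getLogger(__name__)


class EnrichmentError(ValueError):
    pass


@dataclass
class GeneSetCollection:
    """Named gene sets over an annotation universe of ``universe_size`` genes."""

    sets: dict[str, set[str]]
    universe_size: int

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise EnrichmentError(f"gene set {name!r} is empty")
            if len(genes) > self.universe_size:
                raise EnrichmentError(
                    f"gene set {name!r} larger than the universe ({self.universe_size})"
                )


@dataclass
class MappedPairCounts:
    a: int  # mapped normal-specific strong
    b: int  # mapped normal-specific weak
    c: int  # mapped disease-specific strong
    d: int  # mapped disease-specific weak

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise EnrichmentError("negative pair count")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass
class EnrichmentResult:
    set_name: str
    counts: MappedPairCounts
    fisher_p: float
    fdr: float
    annotated_gene_count: int
    annotated_pair_count: int
    hypergeom_p: float
    significant: bool


def load_gene_sets(path: str | Path, universe_size: int) -> GeneSetCollection:
    """Read a GMT file (set_name TAB description TAB gene...) or two-column TSV.

    A line with three or more fields is treated as GMT; two fields as a
    (set_name, gene) pair row.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) >= 3:
                name, _desc, *genes = fields
                sets.setdefault(name.strip(), set()).update(
                    normalize_symbol(g) for g in genes if g.strip()
                )
            elif len(fields) == 2:
                sets.setdefault(fields[0].strip(), set()).add(normalize_symbol(fields[1]))
            else:
                raise EnrichmentError(f"{path}: malformed line {line!r}")
    if not sets:
        raise EnrichmentError(f"gene-set file {path} is empty")
    return GeneSetCollection(sets=sets, universe_size=universe_size)


def write_gmt(sets: dict[str, set[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            genes = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")


def hypergeometric_enrichment(candidates: set[str], annot_set: set[str],
                              universe_size: int) -> float:
    """Upper-tail hypergeometric p for the candidate/set intersection.

    ``P(X >= k)`` where ``k = |candidates ∩ annot_set|``, drawing
    ``|candidates|`` genes from a universe containing ``|annot_set|``
    successes.
    """
    if len(candidates) > universe_size or len(annot_set) > universe_size:
        raise EnrichmentError("universe smaller than candidate or annotation set")
    k = len(candidates & annot_set)
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, universe_size, len(annot_set), len(candidates)))


def annotated_pairs(annot_set: set[str], candidates: list[str]) -> set[tuple[str, str]]:
    """All unordered pairs of annotated candidate genes, canonical (i < j) order."""
    members = sorted(set(candidates) & annot_set)
    return {(members[i], members[j])
            for i in range(len(members)) for j in range(i + 1, len(members))}


def map_pairs(annotated: set[tuple[str, str]], cls: pd.DataFrame) -> MappedPairCounts:
    """Intersect an annotated pair set with the four specific pair classes."""
    universe = set(zip(cls["gene_i"], cls["gene_j"]))
    inside = annotated & universe
    outside = len(annotated) - len(inside)
    if outside:
        logger.info("%d annotated pairs outside the classified universe dropped", outside)
    idx = cls.set_index(["gene_i", "gene_j"])
    sub = idx.loc[sorted(inside)] if inside else idx.iloc[:0]
    return MappedPairCounts(
        a=int(sub["normal_specific_strong"].sum()),
        b=int(sub["normal_specific_weak"].sum()),
        c=int(sub["disease_specific_strong"].sum()),
        d=int(sub["disease_specific_weak"].sum()),
    )


def fisher_one_sided(counts: MappedPairCounts) -> float:
    """One-sided Fisher's exact p for [[a, b], [c, d]], upper tail in a.

    Probability, with all margins fixed, of a table whose a-cell is at least
    as large as observed; computed exactly from the hypergeometric law. An
    all-zero table returns 1.0 by convention.
    """
    a, b, c, d = counts.as_tuple()
    n = a + b + c + d
    if n == 0:
        logger.info("all-zero mapped pair table; Fisher p set to 1")
        return 1.0
    return float(stats.hypergeom.sf(a - 1, n, a + b, a + c))


def bh_fdr(p_values: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted values, order-preserving."""
    if any(not 0.0 <= p <= 1.0 for p in p_values):
        raise EnrichmentError("p-values must lie in [0, 1]")
    if not p_values:
        return []
    _, adj, _, _ = multipletests(p_values, method="fdr_bh")
    return [float(q) for q in adj]


def run_enrichment(collection: GeneSetCollection, candidates: list[str],
                   cls: pd.DataFrame, fdr_threshold: float = 0.05) -> list[EnrichmentResult]:
    """One enrichment row per gene set; significance at BH-FDR < threshold.

    Sets with fewer than two annotated candidate genes yield no pairs and
    are reported with p = 1 rather than dropped, keeping the
    multiple-testing family explicit.
    """
    if not collection.sets:
        raise EnrichmentError("empty gene-set collection")
    cand_set = set(candidates)
    names = sorted(collection.sets)
    rows = []
    for name in names:
        genes = collection.sets[name]
        hyper_p = hypergeometric_enrichment(cand_set, genes, collection.universe_size)
        pairs = annotated_pairs(genes, candidates)
        counts = map_pairs(pairs, cls)
        rows.append((name, genes, hyper_p, pairs, counts, fisher_one_sided(counts)))
    fdrs = bh_fdr([r[5] for r in rows])
    results = []
    for (name, genes, hyper_p, pairs, counts, p), q in zip(rows, fdrs):
        results.append(EnrichmentResult(
            set_name=name,
            counts=counts,
            fisher_p=p,
            fdr=q,
            annotated_gene_count=len(genes & cand_set),
            annotated_pair_count=len(pairs),
            hypergeom_p=hyper_p,
            significant=bool(q < fdr_threshold),
        ))
    return results


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabular view mirroring the a/b/c/d + Fisher p + FDR report layout."""
    return pd.DataFrame(
        {
            "set": [r.set_name for r in results],
            "annotated_genes": [r.annotated_gene_count for r in results],
            "a": [r.counts.a for r in results],
            "b": [r.counts.b for r in results],
            "c": [r.counts.c for r in results],
            "d": [r.counts.d for r in results],
            "hypergeom_p": [r.hypergeom_p for r in results],
            "fisher_p": [r.fisher_p for r in results],
            "fdr": [r.fdr for r in results],
            "significant": [r.significant for r in results],
        }
    )
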