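"""Disease-specific coexpression cutoff and pair classification.

The two groups' coexpression levels form two empirical distributions. Both
are summarized by survival functions ``F(c) = Prob(level >= c)``; the
cutoff ``C`` is the level at which the two survival functions deviate most,

    D = max_c |F_d(c) - F_n(c)|,

i.e. the two-sample Kolmogorov-Smirnov statistic, read off at observed
levels. Pairs with level >= C in a group are "strong" there, others "weak";
pairs strong in exactly one group are that group's specific pairs. A
chi-square test on the 2x2 strong/weak x group table asks whether the two
groups differ in their proportion of strongly coexpressed pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import kolmogorov

logger = logging.getLogger(__name__)

STRONG = "strong"
WEAK = "weak"

#: boolean flag columns added by classify_pairs
FLAG_COLUMNS = [
    "normal_specific_strong",
    "disease_specific_strong",
    "normal_specific_weak",
    "disease_specific_weak",
]


@dataclass
class KSCutoffResult:
    """Maximum deviation D, the cutoff C attaining it, and the KS p-value."""

    D: float
    C: float
    p_value: float
    grid: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {"D": self.D, "C": self.C, "p_value": self.p_value,
                "grid_size": int(self.grid.size)}


@dataclass
class ClassCountTable:
    strong_normal: int
    weak_normal: int
    strong_disease: int
    weak_disease: int

    def __post_init__(self) -> None:
        if self.strong_normal + self.weak_normal != self.strong_disease + self.weak_disease:
            raise ValueError("group rows must tally the same pair universe")

    @property
    def total_pairs(self) -> int:
        return self.strong_normal + self.weak_normal

    def as_2x2(self) -> np.ndarray:
        return np.array(
            [[self.strong_normal, self.weak_normal],
             [self.strong_disease, self.weak_disease]], dtype=float
        )

    def to_dict(self) -> dict:
        return {
            "strong_normal": self.strong_normal,
            "weak_normal": self.weak_normal,
            "strong_disease": self.strong_disease,
            "weak_disease": self.weak_disease,
        }


def survival_value(sample: np.ndarray, c: float) -> float:
    """Fraction of sample values >= c (ties included via the >=)."""
    sample = np.asarray(sample, dtype=float)
    if sample.size == 0:
        raise ValueError("empty sample")
    return float(np.count_nonzero(sample >= c)) / sample.size


def ks_max_deviation(c_d: np.ndarray, c_n: np.ndarray) -> KSCutoffResult:
    """Locate the cutoff at the maximum deviation of the two survival curves.

    The evaluation grid is the sorted union of all observed levels from both
    groups — empirical survival functions are step functions, so deviation
    extrema occur at observed points. When several grid values attain the
    maximum, the smallest is reported as C (deterministic tie-break). The
    returned D equals the classical two-sample KS statistic; the p-value is
    filled by :func:`ks_asymptotic_pvalue`.
    """
    c_d = np.asarray(c_d, dtype=float)
    c_n = np.asarray(c_n, dtype=float)
    if c_d.size == 0 or c_n.size == 0:
        raise ValueError("both level samples must be non-empty")

    grid = np.union1d(c_d, c_n)  # sorted, unique
    d_sorted = np.sort(c_d)
    n_sorted = np.sort(c_n)
    # F(c) = P(level >= c) = 1 - (# values < c)/n, via searchsorted on the left
    f_d = 1.0 - np.searchsorted(d_sorted, grid, side="left") / c_d.size
    f_n = 1.0 - np.searchsorted(n_sorted, grid, side="left") / c_n.size
    dev = np.abs(f_d - f_n)
    best = int(np.argmax(dev))  # argmax returns the first = smallest grid value
    D = float(dev[best])
    C = float(grid[best])
    p = ks_asymptotic_pvalue(D, c_d.size, c_n.size)
    return KSCutoffResult(D=D, C=C, p_value=p, grid=grid)


def ks_asymptotic_pvalue(D: float, n: int, m: int) -> float:
    """Asymptotic two-sample KS p-value.

    Evaluates the Kolmogorov tail series
    ``p = 2 * sum_{k>=1} (-1)^(k-1) exp(-2 k^2 lambda^2)`` at
    ``lambda = D * sqrt(n*m/(n+m))``, clamped to [0, 1]. No small-sample
    bias terms are applied, so late digits may differ from implementations
    that apply them.
    """
    if not 0.0 <= D <= 1.0:
        raise ValueError(f"D={D} outside [0, 1]")
    if n < 1 or m < 1:
        raise ValueError("sample sizes must be >= 1")
    lam = D * np.sqrt(n * m / (n + m))
    return float(min(max(kolmogorov(lam), 0.0), 1.0))


def classify_pairs(table: pd.DataFrame, C: float) -> pd.DataFrame:
    """Label every pair strong/weak per group and derive the specific flags.

    A pair is *strong* in a group when its level is >= C there (ties go to
    strong). Normal-specific strong pairs (strong in normal, weak in
    disease) coincide with the disease-specific weak pairs, and vice versa;
    both namings are kept because each carries its own reading — lost
    physiological connections versus disease-acquired ones.
    """
    if not 0.0 <= C <= 1.0:
        raise ValueError(f"cutoff {C} outside [0, 1]")
    out = table.copy()
    strong_n = out["c_normal"].to_numpy() >= C
    strong_d = out["c_disease"].to_numpy() >= C
    out["class_normal"] = np.where(strong_n, STRONG, WEAK)
    out["class_disease"] = np.where(strong_d, STRONG, WEAK)
    out["normal_specific_strong"] = strong_n & ~strong_d
    out["disease_specific_strong"] = strong_d & ~strong_n
    out["normal_specific_weak"] = out["disease_specific_strong"]
    out["disease_specific_weak"] = out["normal_specific_strong"]
    return out


def count_classes(cls: pd.DataFrame) -> ClassCountTable:
    """Tally strong/weak pairs per group from a classified table."""
    sn = int((cls["class_normal"] == STRONG).sum())
    sd = int((cls["class_disease"] == STRONG).sum())
    total = len(cls)
    return ClassCountTable(
        strong_normal=sn,
        weak_normal=total - sn,
        strong_disease=sd,
        weak_disease=total - sd,
    )


def chi2_proportions(t: ClassCountTable) -> tuple[float, float]:
    """Pearson chi-square (df=1, no continuity correction) on the 2x2 table.

    Tests whether the proportion of strongly coexpressed pairs differs
    between the groups.
    """
    obs = t.as_2x2()
    if obs.sum(axis=0).min() == 0 or obs.sum(axis=1).min() == 0:
        raise ValueError("zero marginal in the 2x2 class table")
    chi2, p, _, expected = stats.chi2_contingency(obs, correction=False)
    if expected.min() <= 0:
        raise ValueError("zero expected cell count")
    return float(chi2), float(p)
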