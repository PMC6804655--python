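"""Normality-gated paired testing with Bonferroni correction.

Each metric set is screened with a Shapiro-Wilk test at alpha = 0.05; the
paired comparison then uses a paired t test when the differences look
normal and a Wilcoxon signed-rank test otherwise.  Family-wise error is
controlled by Bonferroni: the per-comparison threshold is
alpha_family / n_comparisons (0.05 / 3 = 0.0166..., conventionally quoted
truncated as 0.016).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class PairedComparison:
    label: str
    values_a: np.ndarray
    values_b: np.ndarray
    test_used: str          # "t" or "wilcoxon"
    p: float
    adjusted_alpha: float
    significant: bool

    def __post_init__(self) -> None:
        self.values_a = np.asarray(self.values_a, dtype=float)
        self.values_b = np.asarray(self.values_b, dtype=float)
        if len(self.values_a) != len(self.values_b):
            raise ValueError("paired vectors must have equal length")
        if len(self.values_a) < 3:
            raise ValueError("need at least 3 pairs")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p out of [0, 1]")


def normality_gate(x: np.ndarray, alpha: float = 0.05) -> str:
    """Shapiro-Wilk screen: 'normal' or 'non-normal' at the given alpha.

    Constant vectors are degenerate for the test and are reported as
    non-normal with a warning.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("normality test needs n >= 3")
    if np.ptp(x) == 0:
        warnings.warn("constant metric vector; treating as non-normal")
        return "non-normal"
    _, p = sps.shapiro(x)
    return "normal" if p >= alpha else "non-normal"


def paired_compare(
    a: np.ndarray,
    b: np.ndarray,
    label: str = "",
    alpha_family: float = 0.05,
    n_comparisons: int = 3,
) -> PairedComparison:
    """Normality-gated paired test with Bonferroni-adjusted significance.

    Zero differences are dropped by the Wilcoxon test (signed-rank
    convention); an all-zero difference vector short-circuits to p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired vectors must have equal length")
    adjusted = alpha_family / n_comparisons
    diffs = a - b
    if np.all(diffs == 0):
        warnings.warn("all paired differences are zero; p set to 1")
        return PairedComparison(label, a, b, "wilcoxon", 1.0, adjusted, False)
    gate = normality_gate(diffs)
    if gate == "normal":
        test_used = "t"
        _, p = sps.ttest_rel(a, b)
    else:
        test_used = "wilcoxon"
        nz = diffs[diffs != 0]
        _, p = sps.wilcoxon(nz)
    p = float(p)
    return PairedComparison(label, a, b, test_used, p, adjusted, p < adjusted)


def pearson_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation, in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in correlation input")
    r, _ = sps.pearsonr(x, y)
    return float(r * r)
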