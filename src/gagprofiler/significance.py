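"""Random-match significance testing of annotated components.

Under the null hypothesis that a component is absent, each of its n
theoretical peaks lying inside the experimental m/z range matches an
experimental peak only by chance, with per-peak probability

    p_m = sum_i (2 * ppm * 1e-6 * mz_i) / (experimental m/z span),

the total tolerance-window width divided by the spectrum span.  The
number of random matches then follows Binomial(n, p_m), and the p-value
of observing k matched peaks is the upper tail P(X >= k).  P-values are
Benjamini-Hochberg adjusted across the candidate-component family of the
spectrum and reported as -log10(p_adj); components above 3 are flagged
reliable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SignificanceResult",
    "random_match_prob",
    "binomial_pvalue",
    "bh_adjust",
    "reliability_flag",
    "assess_components",
]

RELIABLE_THRESHOLD = 3.0


@dataclass
class SignificanceResult:
    """Per-component significance of its peak matches."""

    n_theoretical: int
    k_matched: int
    p_random: float
    p_value: float
    p_adj: float = float("nan")

    @property
    def neg_log10_padj(self) -> float:
        if self.p_adj == 0:
            return float("inf")
        return -math.log10(self.p_adj)

    @property
    def reliable(self) -> bool:
        return reliability_flag(self.neg_log10_padj)


def random_match_prob(
    theoretical_mzs: Sequence[float],
    ppm: float,
    range_lo: float,
    range_hi: float,
) -> float:
    """Probability that one theoretical peak matches by chance.

    Only theoretical peaks inside [range_lo, range_hi] contribute; each
    adds its two-sided tolerance window 2*ppm*1e-6*mz to the numerator.
    """
    if not range_hi > range_lo:
        raise ValueError("degenerate experimental m/z range")
    mzs = np.asarray(theoretical_mzs, dtype=float)
    mzs = mzs[(mzs >= range_lo) & (mzs <= range_hi)]
    if mzs.size == 0:
        return 0.0
    windows = 2.0 * ppm * 1e-6 * mzs
    return float(min(1.0, windows.sum() / (range_hi - range_lo)))


def binomial_pvalue(n: int, k: int, p_random: float) -> float:
    """Upper-tail binomial probability P(X >= k), X ~ B(n, p_random)."""
    if not 0 <= k <= n:
        raise ValueError("k must satisfy 0 <= k <= n")
    if k == 0:
        return 1.0
    # survival function is P(X > k-1) = P(X >= k)
    return float(stats.binom.sf(k - 1, n, p_random))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (clipped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in adjusted]


def reliability_flag(neg_log10_padj: float) -> bool:
    """A component is reliable iff -log10(p_adj) exceeds 3."""
    return bool(neg_log10_padj > RELIABLE_THRESHOLD)


def assess_components(
    per_component: Sequence[tuple[int, int]],
    p_randoms: Sequence[float],
) -> list[SignificanceResult]:
    """Significance of several components of one spectrum.

    ``per_component`` holds (n_theoretical, k_matched) per candidate and
    ``p_randoms`` the per-component random-match probabilities; p-values
    are BH-adjusted across the whole family.
    """
    results = []
    for (n, k), p_m in zip(per_component, p_randoms):
        if n == 0 or p_m <= 0.0:
            p_value = 1.0
        else:
            p_value = binomial_pvalue(n, k, p_m)
        results.append(
            SignificanceResult(n_theoretical=n, k_matched=k, p_random=p_m, p_value=p_value)
        )
    if results:
        adjusted = bh_adjust([r.p_value for r in results])
        for r, adj in zip(results, adjusted):
            r.p_adj = adj
    return results
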