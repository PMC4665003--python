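"""Shared statistical helpers: 2x2 contingency tables and multiple testing.

The 2x2 layout throughout the package is::

              in-category   not-in-category
    up / A        a               b
    non / B       c               d

with odds ratio ad/bc, Woolf log-OR confidence interval (Haldane-Anscombe
+0.5 continuity correction when any cell is zero), and Fisher exact p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def cells(self):
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    def _corrected(self):
        if min(self.a, self.b, self.c, self.d) == 0:
            return self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5
        return float(self.a), float(self.b), float(self.c), float(self.d)

    @property
    def odds_ratio(self) -> float:
        if self.b * self.c == 0:
            a, b, c, d = self._corrected()
            return (a * d) / (b * c)
        return (self.a * self.d) / (self.b * self.c)

    def ci95(self) -> tuple:
        """Woolf 95% CI on the odds ratio (log-OR +/- 1.96 SE)."""
        a, b, c, d = self._corrected()
        log_or = np.log((a * d) / (b * c))
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        return float(np.exp(log_or - 1.96 * se)), float(np.exp(log_or + 1.96 * se))

    def log_or_se(self) -> tuple:
        a, b, c, d = self._corrected()
        return (float(np.log((a * d) / (b * c))),
                float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)))

    def fisher_p(self, alternative: str = "two-sided") -> float:
        return float(sps.fisher_exact(self.cells, alternative=alternative)[1])


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def cochran_q(log_ors, ses) -> tuple:
    """Cochran's Q heterogeneity test over per-covariate log odds ratios.

    Returns (Q, p) with Q ~ chi2 on k-1 df under homogeneity.
    """
    y = np.asarray(log_ors, dtype=float)
    w = 1.0 / np.asarray(ses, dtype=float) ** 2
    if y.size < 2:
        return float("nan"), float("nan")
    ybar = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - ybar) ** 2))
    p = float(sps.chi2.sf(q, df=y.size - 1))
    return q, p
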