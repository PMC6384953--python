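"""Shared statistical utilities: normality gate, paired tests, BH-FDR."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class TestReport:
    """Outcome of a single hypothesis test."""

    test_name: str
    statistic: float
    p: float
    n: int
    alternative: str = "two-sided"
    corrected_p: float | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise ValueError(f"p-value out of range: {self.p}")


def ks_normal(x, alpha: float = 0.05) -> bool:
    """Kolmogorov-Smirnov gate: does ``x`` look Gaussian?

    The sample is standardized before testing against the standard normal;
    constant samples fail the gate.
    """
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1) if x.size > 1 else 0.0
    if not np.isfinite(sd) or sd == 0:
        return False
    z = (x - x.mean()) / sd
    return sps.kstest(z, "norm").pvalue > alpha


def _wilcoxon(d: np.ndarray) -> TestReport:
    n = d.size
    method = "exact" if n <= 25 and not np.any(d == 0) else "approx"
    res = sps.wilcoxon(d, alternative="two-sided", method=method, correction=(method == "approx"))
    return TestReport("wilcoxon", float(res.statistic), float(res.pvalue), n)


def paired_compare(a, b, normality_alpha: float = 0.05) -> TestReport:
    """Two-sided paired comparison with a KS normality gate on the differences.

    Normal-looking differences go to the paired t-test, anything else to the
    Wilcoxon signed-rank test. All-zero differences are degenerate and are
    reported with p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 3:
        raise ValueError("paired_compare needs at least 3 pairs")
    d = a - b
    if np.allclose(d, 0.0):
        return TestReport("wilcoxon", 0.0, 1.0, d.size, degenerate=True)
    if np.ptp(d) == 0.0:
        # exact constant shift: zero-variance differences, t statistic diverges
        return TestReport(
            "paired_t", float(np.sign(d[0]) * np.inf), 0.0, d.size, degenerate=True
        )
    if ks_normal(d, alpha=normality_alpha):
        res = sps.ttest_rel(a, b)
        return TestReport("paired_t", float(res.statistic), float(res.pvalue), d.size)
    return _wilcoxon(d)


def bh_fdr(pvalues, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance mask at FDR level ``q``."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if not (0 < q < 1):
        raise ValueError("q must lie in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    thresh = q * (np.arange(1, m + 1)) / m
    below = p[order] <= thresh
    mask = np.zeros(m, dtype=bool)
    if np.any(below):
        k = np.max(np.nonzero(below)[0])
        mask[order[: k + 1]] = True
    return mask


def bh_adjusted(pvalues) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up q-values)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adj, 0, 1)
    return out
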