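"""Shared statistical primitives.

The empirical-null machinery used both for interactor calling and for the
cluster-separation permutation test is built on a kernel density estimate
with the Epanechnikov kernel K(u) = 0.75 (1 - u^2) on |u| <= 1.  Because the
kernel is a polynomial with compact support, the CDF of the estimate has an
exact piecewise closed form; no numerical integration is needed.
"""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests


class EpanechnikovKDE:
    """Kernel density estimate with an Epanechnikov kernel and exact CDF.

    Parameters
    ----------
    values : array-like
        Observed support points (e.g. normalized control intensities).
    bandwidth : float or "auto"
        Kernel half-width h. ``"auto"`` applies Silverman's rule of thumb
        on the values, with a small positive floor for degenerate data.
    """

    def __init__(self, values, bandwidth="auto"):
        values = np.asarray(values, dtype=float)
        values = values[np.isfinite(values)]
        if values.size < 2:
            raise ValueError(
                "need at least 2 finite values to fit an empirical null"
            )
        self.support = np.sort(values)
        if bandwidth == "auto":
            bandwidth = silverman_bandwidth(self.support)
        bandwidth = float(bandwidth)
        if bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        self.bandwidth = bandwidth

    def pdf(self, x):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        u = (x[:, None] - self.support[None, :]) / self.bandwidth
        k = np.where(np.abs(u) <= 1.0, 0.75 * (1.0 - u * u), 0.0)
        out = k.mean(axis=1) / self.bandwidth
        return out if out.size > 1 else float(out[0])

    def cdf(self, x):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        u = (x[:, None] - self.support[None, :]) / self.bandwidth
        u = np.clip(u, -1.0, 1.0)
        # integral of the kernel: W(u) = 0.5 + 0.75 u - 0.25 u^3 on [-1, 1]
        w = 0.5 + 0.75 * u - 0.25 * u**3
        out = w.mean(axis=1)
        return out if out.size > 1 else float(out[0])

    def sf(self, x):
        """Upper-tail probability 1 - CDF(x)."""
        return 1.0 - self.cdf(x)


def silverman_bandwidth(values) -> float:
    """Silverman's rule-of-thumb bandwidth, floored away from zero."""
    values = np.asarray(values, dtype=float)
    n = values.size
    sd = values.std(ddof=1) if n > 1 else 0.0
    q75, q25 = np.percentile(values, [75, 25])
    iqr = q75 - q25
    spread_candidates = [s for s in (sd, iqr / 1.34) if s > 0]
    spread = min(spread_candidates) if spread_candidates else 0.0
    h = 0.9 * spread * n ** (-0.2)
    if h <= 0:
        # degenerate (near-constant) data: fall back to a tiny positive width
        h = 1e-6 * max(1.0, float(np.abs(values).max(initial=0.0)))
    return float(h)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if pvals.size == 0:
        return pvals.copy()
    if np.any((pvals < 0) | (pvals > 1) | ~np.isfinite(pvals)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def fisher_combine(pvals) -> float:
    """Fisher's method for combining independent p-values."""
    from scipy import stats

    pvals = np.asarray(pvals, dtype=float)
    pvals = pvals[np.isfinite(pvals)]
    if pvals.size == 0:
        return float("nan")
    if pvals.size == 1:
        return float(pvals[0])
    stat = -2.0 * np.sum(np.log(np.clip(pvals, 1e-300, 1.0)))
    return float(stats.chi2.sf(stat, df=2 * pvals.size))
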