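"""Posterior summaries and convergence diagnostics.

Implements the quantities the pipeline reports: highest posterior density
intervals (HPDI), kernel-density posterior modes, the Gelman-Rubin potential
scale reduction factor (R-hat), and Raftery's evidence bands for Bayes
factors.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import gaussian_kde

__all__ = ["hpdi", "posterior_mode", "rhat", "rhat_flag", "raftery_band"]

MIN_DRAWS = 100

#: Raftery evidence bands for BF10 (upper-open on the alternative side).
#: Band boundaries follow bracket semantics: [3, 20) positive, [20, 150)
#: strong, >= 150 very strong; reciprocals for the null side with the
#: closed/open ends mirrored: (0.05, 0.33] positive-null, (0.0067, 0.05]
#: strong-null, <= 0.0067 very-strong-null.
_BANDS_ALT = [(150.0, "very strong"), (20.0, "strong"), (3.0, "positive")]


def raftery_band(bf10: float) -> str:
    """Classify a Bayes factor BF10 into Raftery's evidence bands."""
    bf10 = float(bf10)
    if not np.isfinite(bf10) or bf10 <= 0:
        raise ValueError(f"BF10 must be a positive finite number, got {bf10}")
    if bf10 >= 150.0:
        return "very strong"
    if bf10 >= 20.0:
        return "strong"
    if bf10 >= 3.0:
        return "positive"
    if bf10 > 1.0:
        return "weak (alternative)"
    if bf10 == 1.0:
        return "none"
    if bf10 >= 0.33:
        return "weak (null)"
    if bf10 > 0.05:
        return "positive (null)"
    if bf10 > 0.0067:
        return "strong (null)"
    return "very strong (null)"


def hpdi(draws, mass: float = 0.99) -> tuple[float, float]:
    """Shortest contiguous interval holding ``mass`` of the draws.

    The interval is found by sliding a window of ``floor(mass * n)`` index
    steps over the sorted draws and taking the narrowest; ties break to the
    lowest start.
    """
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n < MIN_DRAWS:
        raise ValueError(f"need at least {MIN_DRAWS} draws, got {n}")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie in (0, 1)")
    k = int(np.floor(mass * n))
    if k >= n:
        k = n - 1
    widths = x[k:] - x[: n - k]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k])


def posterior_mode(draws) -> float:
    """Posterior mode via a Gaussian KDE (Scott's bandwidth rule).

    The KDE is evaluated on a 512-point grid spanning the draws; degenerate
    (constant) draws return the unique value directly.
    """
    x = np.asarray(draws, dtype=float).ravel()
    if x.size < MIN_DRAWS:
        raise ValueError(f"need at least {MIN_DRAWS} draws, got {x.size}")
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        return lo
    kde = gaussian_kde(x)
    grid = np.linspace(lo, hi, 512)
    dens = kde(grid)
    return float(grid[int(np.argmax(dens))])


def rhat(chains) -> float:
    """Gelman-Rubin potential scale reduction factor.

    ``chains`` is an (n_chains, n_draws) array. With m chains of length n,
    W = mean within-chain variance, B/n = variance of chain means, and

        rhat = sqrt( ((n - 1)/n * W + B/n) / W ).

    Values near 1 indicate the chains have mixed; the convergence flag is
    half-open at 1.1.
    """
    c = np.atleast_2d(np.asarray(chains, dtype=float))
    m, n = c.shape
    if m < 2:
        raise ValueError("R-hat needs at least 2 chains")
    if n < 2:
        raise ValueError("R-hat needs at least 2 draws per chain")
    means = c.mean(axis=1)
    W = c.var(axis=1, ddof=1).mean()
    B_over_n = means.var(ddof=1)
    if W == 0.0:
        return 1.0 if B_over_n == 0.0 else np.inf
    v_hat = (n - 1) / n * W + B_over_n
    return float(np.sqrt(v_hat / W))


def rhat_flag(value: float) -> bool:
    """True iff the chains count as converged (rhat < 1.1, half-open)."""
    return bool(value < 1.1)
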