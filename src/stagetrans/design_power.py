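"""Cluster-design utilities: design effect, effective sample size and
normal-approximation power for a standardized two-sample comparison."""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["design_effect", "effective_n", "power_two_sample"]


def design_effect(m: float, icc: float) -> float:
    """Variance inflation from cluster sampling: DEFF = 1 + (m - 1) * icc,
    with m the mean cluster size and icc the intraclass correlation."""
    if m < 1:
        raise ValueError("mean cluster size must be >= 1")
    if not 0.0 <= icc <= 1.0:
        raise ValueError("icc must lie in [0, 1]")
    return float(1.0 + (m - 1.0) * icc)


def effective_n(n_total: float, m: float, icc: float) -> float:
    """Effective sample size n / DEFF of a cluster sample."""
    return float(n_total) / design_effect(m, icc)


def power_two_sample(d: float, alpha: float, n_eff: float) -> float:
    """Power of a two-sided two-sample z-test for standardized difference d.

    The effective sample is split equally between arms, so the
    noncentrality is ``d * sqrt(n_eff / 4)`` and

        power = Phi(delta - z_{1-a/2}) + Phi(-delta - z_{1-a/2}).

    At d = 0 the power equals the level alpha.
    """
    if n_eff < 4:
        raise ValueError("effective sample size must be >= 4")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    delta = d * np.sqrt(n_eff / 4.0)
    return float(stats.norm.cdf(delta - z) + stats.norm.cdf(-delta - z))
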