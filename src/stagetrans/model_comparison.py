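"""Fit indices and the restrained-vs-unrestrained likelihood-ratio
comparison of nested Markov fits.

Everything flows from the deviance G^2 = -2 * loglik: AIC = G^2 + 2p,
BIC = G^2 + p ln(n) with n the analysis sample, and the nested-model
difference test Delta G^2 ~ chi-square(Delta df).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .markov_model import MarkovFit

__all__ = ["aic", "bic", "lrt", "compare", "ComparisonReport", "NestingError"]


class NestingError(ValueError):
    """Raised when the two fits cannot be compared as nested models."""


def aic(g2: float, p: int) -> float:
    """Akaike information criterion from the deviance: G^2 + 2p."""
    if p < 0:
        raise ValueError("free-parameter count must be >= 0")
    return float(g2 + 2 * p)


def bic(g2: float, p: int, n: int) -> float:
    """Bayesian information criterion: G^2 + p ln(n)."""
    if n < 1:
        raise ValueError("sample size must be >= 1")
    if p < 0:
        raise ValueError("free-parameter count must be >= 0")
    return float(g2 + p * np.log(n))


def lrt(g2_restrained: float, g2_unrestrained: float, ddf: int) -> tuple[float, float]:
    """G^2 difference test for nested fits.

    Returns ``(delta_g2, p)`` with p the upper chi-square tail at ``ddf``
    degrees of freedom. A negative difference beyond numerical tolerance
    signals a nesting (or optimization) violation.
    """
    if ddf < 1:
        raise ValueError("difference in free parameters must be >= 1")
    delta = float(g2_restrained - g2_unrestrained)
    if delta < -1e-6:
        raise NestingError(
            f"restrained deviance {g2_restrained} below unrestrained {g2_unrestrained}: "
            "models are not nested at their optima"
        )
    delta = max(delta, 0.0)
    return delta, float(stats.chi2.sf(delta, ddf))


@dataclass
class ComparisonReport:
    """Paired-model fit indices plus the difference test."""

    g2: tuple[float, float]  # (restrained, unrestrained)
    loglik: tuple[float, float]
    n_free: tuple[int, int]
    aic: tuple[float, float]
    bic: tuple[float, float]
    n: int
    delta_g2: float
    delta_df: int
    p: float
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, label in enumerate(("restrained (Model 1)", "unrestrained (Model 2)")):
            rows.append(
                {
                    "model": label,
                    "G2": round(self.g2[i], 2),
                    "loglik": round(self.loglik[i], 2),
                    "n_free": self.n_free[i],
                    "AIC": round(self.aic[i], 2),
                    "BIC": round(self.bic[i], 2),
                }
            )
        rows.append(
            {
                "model": "difference",
                "G2": round(self.delta_g2, 2),
                "n_free": self.delta_df,
                "AIC": "",
                "BIC": "",
                "loglik": "",
            }
        )
        return pd.DataFrame(rows)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        body = self.to_frame().to_string(index=False)
        tail = f"\nG2 difference test: delta={self.delta_g2:.2f}, df={self.delta_df}, p={self.p:.3f}"
        if self.degenerate:
            tail += "\n(warning: models have identical deviance and df — degenerate comparison)"
        return body + tail


def compare(fit_restrained: MarkovFit, fit_unrestrained: MarkovFit, n: int) -> ComparisonReport:
    """Full fit-index report for a nested pair of Markov fits.

    ``fit_restrained`` must have fewer free parameters than
    ``fit_unrestrained`` and both must come from the same panel (checked
    via the contributing sample size).
    """
    p1, p2 = fit_restrained.n_free, fit_unrestrained.n_free
    if fit_restrained.n_used != fit_unrestrained.n_used:
        raise NestingError(
            "fits use different samples "
            f"({fit_restrained.n_used} vs {fit_unrestrained.n_used})"
        )
    degenerate = False
    if p1 == p2:
        if abs(fit_restrained.g2 - fit_unrestrained.g2) < 1e-9:
            degenerate = True
            ddf = 1
            delta, p = 0.0, 1.0
        else:
            raise NestingError("fits have equal parameter counts but differ: not nested")
    elif p1 > p2:
        raise NestingError("restrained fit has more parameters than the unrestrained one")
    else:
        ddf = p2 - p1
        delta, p = lrt(fit_restrained.g2, fit_unrestrained.g2, ddf)
    return ComparisonReport(
        g2=(fit_restrained.g2, fit_unrestrained.g2),
        loglik=(fit_restrained.loglik, fit_unrestrained.loglik),
        n_free=(p1, p2),
        aic=(aic(fit_restrained.g2, p1), aic(fit_unrestrained.g2, p2)),
        bic=(bic(fit_restrained.g2, p1, n), bic(fit_unrestrained.g2, p2, n)),
        n=n,
        delta_g2=delta,
        delta_df=ddf,
        p=p,
        degenerate=degenerate,
    )
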