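"""Descriptive statistics: Somers' D, a categorical MCAR test, VIF and
report-style table builders."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .data_model import Stage, StagePanel, crosstab

__all__ = [
    "OrdinalAssociation",
    "somers_d",
    "MCARTestUndefined",
    "mcar_chi2",
    "vif",
    "stage_distribution_table",
    "baseline_table",
]


@dataclass
class OrdinalAssociation:
    """Somers' D with its asymptotic standard error and normal p-value."""

    d: float
    se: float
    p: float

    def __iter__(self):
        yield from (self.d, self.se, self.p)


def somers_d(table) -> OrdinalAssociation:
    """Somers' D for a 2 x K group-by-ordered-category count table.

    Direction is D(category | group): concordant-minus-discordant
    cross-group pairs over the number of pairs untied on the group row.
    Row 0 is the intervention group; d > 0 means the intervention row sits
    higher on the column ordering.

    The variance is the standard consistent estimator (as in SAS PROC
    FREQ): with w = n^2 - sum_i r_i^2 the untied-pair weight,
    P/Q the ordered concordant/discordant pair counts and A_ij/D_ij the
    per-cell concordant/discordant sums,
    var = 4/w^4 * sum_ij n_ij [w (A_ij - D_ij) - (P - Q)(n - r_i)]^2.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != 2 or t.shape[1] < 2:
        raise ValueError("somers_d expects a 2 x K table with K >= 2")
    if (t.sum(axis=1) <= 0).any():
        raise ValueError("both group rows need positive totals")

    # row 0 = intervention; treat its row score as the *higher* group value
    # so that concordance means intervention sits higher on the ordering.
    scored = t[::-1]  # row index now increases with the group score
    nrow, ncol = scored.shape
    n = scored.sum()
    r = scored.sum(axis=1)

    A = np.zeros_like(scored)
    D = np.zeros_like(scored)
    for i in range(nrow):
        for j in range(ncol):
            A[i, j] = scored[:i, :j].sum() + scored[i + 1 :, j + 1 :].sum()
            D[i, j] = scored[:i, j + 1 :].sum() + scored[i + 1 :, :j].sum()
    P = float((scored * A).sum())
    Q = float((scored * D).sum())
    w = n**2 - (r**2).sum()
    d = (P - Q) / w

    resid = w * (A - D) - (P - Q) * (n - r)[:, None]
    var = 4.0 / w**4 * float((scored * resid**2).sum())
    se = float(np.sqrt(var))
    if se > 0:
        p = 2.0 * stats.norm.sf(abs(d) / se)
    else:
        p = 1.0 if d == 0 else 0.0
    return OrdinalAssociation(d=float(d), se=se, p=float(p))


class MCARTestUndefined(ValueError):
    """Raised when the panel has a single missingness pattern."""


def mcar_chi2(panel: StagePanel) -> tuple[float, int, float]:
    """Chi-square test of the missing-completely-at-random assumption.

    Categorical analogue of Little's test for the two stage variables:
    under MCAR the distribution of each observed stage is homogeneous
    across the missingness patterns of the other wave. The statistic sums
    two Pearson homogeneity chi-squares — stage at W2 split by whether W3
    is missing, and stage at W3 split by whether W2 is missing — with
    their degrees of freedom.

    Returns ``(statistic, df, p)``. Raises :class:`MCARTestUndefined` for
    a complete panel (single pattern).
    """
    df_ = panel.data
    m2 = df_["stage_w2"].isna().to_numpy()
    m3 = df_["stage_w3"].isna().to_numpy()
    if not (m2.any() or m3.any()):
        raise MCARTestUndefined("no missing stages: the MCAR test is undefined")

    stat, dof = 0.0, 0
    for obs_col, miss in (("stage_w2", m3), ("stage_w3", m2)):
        s = df_[obs_col]
        ok = s.notna().to_numpy()
        tab = pd.crosstab(miss[ok], s[ok].astype(int)).to_numpy()
        tab = tab[tab.sum(axis=1) > 0][:, tab.sum(axis=0) > 0]
        if tab.shape[0] > 1 and tab.shape[1] > 1:
            res = stats.chi2_contingency(tab, correction=False)
            stat += float(res.statistic)
            dof += int(res.dof)
    if dof == 0:
        raise MCARTestUndefined(
            "missingness patterns carry no observed-stage contrast; test undefined"
        )
    return stat, dof, float(stats.chi2.sf(stat, dof))


def vif(design) -> pd.Series:
    """Variance inflation factor per covariate column.

    VIF_j = 1 / (1 - R^2_j) where R^2_j is from the OLS regression of
    column j on the remaining columns plus a constant. Exactly collinear
    columns report ``inf``.
    """
    X = pd.DataFrame(design)
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least two covariates")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("VIF needs more rows than covariates")
    out = {}
    for col in X.columns:
        others = sm.add_constant(X.drop(columns=[col]).to_numpy())
        r2 = sm.OLS(X[col].to_numpy(), others).fit().rsquared
        out[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="VIF")


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------


def stage_distribution_table(panel: StagePanel) -> pd.DataFrame:
    """Per-wave, per-arm stage distribution with Somers' D, in the shape of
    the published distribution table (intervention row first per wave)."""
    blocks = []
    for wave in panel.waves:
        tab = crosstab(panel, wave)
        assoc = somers_d(tab.loc[[1, 0]].to_numpy())
        for arm, label in ((1, "intervention"), (0, "control")):
            row = tab.loc[arm]
            total = int(row.sum())
            rec = {"wave": wave, "group": label, "n": total}
            for s in Stage:
                c = int(row[s.name])
                pct = 100.0 * c / total if total else 0.0
                rec[s.name.lower()] = f"{c} ({pct:.1f})"
            rec["somers_d"] = round(assoc.d, 3) if arm == 1 else ""
            rec["p"] = round(assoc.p, 3) if arm == 1 else ""
            blocks.append(rec)
    return pd.DataFrame(blocks)


def baseline_table(panel: StagePanel) -> pd.DataFrame:
    """Baseline covariate summary by arm: mean (SD) for numeric columns
    with more than a handful of levels, n (%) otherwise."""
    df = panel.data
    rows = []
    for col in panel.covariate_columns:
        s = df[col]
        numeric = pd.api.types.is_numeric_dtype(s) and s.nunique() > 6
        for arm, label in ((1, "intervention"), (0, "control")):
            sub = s[df["arm"] == arm].dropna()
            if numeric:
                rows.append(
                    {
                        "variable": col,
                        "group": label,
                        "summary": f"{sub.mean():.1f} ± {sub.std():.1f}",
                    }
                )
            else:
                total = len(sub)
                for level, cnt in sub.value_counts().sort_index().items():
                    rows.append(
                        {
                            "variable": f"{col}={level}",
                            "group": label,
                            "summary": f"{cnt} ({100.0 * cnt / total:.1f}%)",
                        }
                    )
    return pd.DataFrame(rows)
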