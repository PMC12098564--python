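"""Intervention-efficacy odds ratios on stage membership and transitions.

Two routes to the same quantities:

* closed-form from a pair of per-arm transition matrices (a pure function
  of within-row odds, so invariant to row rescaling), and
* from a fitted multigroup Markov model, where with the stay-reference
  coding each transition odds ratio is ``exp(g_jk)`` with a Wald interval
  from the cluster-robust covariance.

The "successful transition" contrast collapses each origin row to a
binary outcome: for both pre-intenders and intenders the unsuccessful
cell is ending (or staying) in pre-intention, success is everything
else — forward movement for pre-intenders, staying or moving forward for
intenders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import Stage
from .markov_model import Z_95, MarkovFit, MarkovParams, TransitionMatrix, implied_matrices

__all__ = [
    "EffectEstimate",
    "or_from_matrices",
    "success_or",
    "or_table_from_fit",
    "membership_or_from_fit",
    "transition_diagram_dot",
]


@dataclass
class EffectEstimate:
    """Odds ratio with a 95% Wald interval and two-sided p-value."""

    contrast: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    estimable: bool = True

    def as_row(self) -> dict:
        return {
            "contrast": self.contrast,
            "OR": round(self.odds_ratio, 2),
            "ci_low": round(self.ci_low, 2),
            "ci_high": round(self.ci_high, 2),
            "p": round(self.p, 3),
            "estimable": self.estimable,
        }


def _cell(matrix: TransitionMatrix, frm: Stage, to: Stage) -> float:
    return float(matrix.probs[int(frm) - 1, int(to) - 1])


def or_from_matrices(
    control: TransitionMatrix,
    intervention: TransitionMatrix,
    frm: Stage,
    to: Stage,
    ref: Stage,
) -> float:
    """Transition odds ratio between arms for one origin row.

    ``[P_int(to|frm)/P_int(ref|frm)] / [P_ctl(to|frm)/P_ctl(ref|frm)]``.
    """
    if frm == Stage.ACTION:
        raise ValueError("the action stage is absorbing: no transition contrast")
    if to == ref:
        raise ValueError("destination and reference stage must differ")
    denom = _cell(control, frm, ref) * _cell(intervention, frm, ref)
    if denom <= 0:
        raise ZeroDivisionError("zero reference cell: odds ratio undefined")
    num_i, num_c = _cell(intervention, frm, to), _cell(control, frm, to)
    return (num_i / _cell(intervention, frm, ref)) / (num_c / _cell(control, frm, ref))


def _success_odds(matrix: TransitionMatrix, frm: Stage) -> float:
    row = matrix.row(frm)
    success = float(row[1] + row[2])  # intention + action destinations
    failure = float(row[0])  # ending in pre-intention
    if failure <= 0 or success <= 0:
        raise ZeroDivisionError("degenerate success probability (0 or 1) in an arm")
    return success / failure


def success_or(
    control: TransitionMatrix, intervention: TransitionMatrix, frm: Stage
) -> float:
    """Odds ratio of a successful transition (intervention vs control).

    Success means a forward move for pre-intenders and staying-or-forward
    for intenders; in both cases failure is ending in pre-intention.
    """
    if frm not in (Stage.PRE_INTENTION, Stage.INTENTION):
        raise ValueError("success contrast defined for pre-intention and intention only")
    return _success_odds(intervention, frm) / _success_odds(control, frm)


# ---------------------------------------------------------------------------
# fit-based tables
# ---------------------------------------------------------------------------


def _wald(contrast: str, est: float, se: float) -> EffectEstimate:
    if not np.isfinite(se) or se <= 0:
        return EffectEstimate(contrast, float(np.exp(est)), np.nan, np.nan, np.nan, False)
    z = est / se
    return EffectEstimate(
        contrast=contrast,
        odds_ratio=float(np.exp(est)),
        ci_low=float(np.exp(est - Z_95 * se)),
        ci_high=float(np.exp(est + Z_95 * se)),
        p=float(2.0 * stats.norm.sf(abs(z))),
    )


def _delta_log_se(fun, theta: np.ndarray, vcov: np.ndarray) -> float:
    """Delta-method SE of a smooth log-scale function of the parameters."""
    g = np.zeros_like(theta)
    for l in range(theta.size):
        h = 1e-6 * max(1.0, abs(theta[l]))
        tp, tm = theta.copy(), theta.copy()
        tp[l] += h
        tm[l] -= h
        g[l] = (fun(tp) - fun(tm)) / (2 * h)
    return float(np.sqrt(g @ vcov @ g))


def or_table_from_fit(fit: MarkovFit) -> pd.DataFrame:
    """Transition-efficacy odds ratios from a multigroup stay-reference fit.

    Per-cell ORs are ``exp(g_jk)`` with cluster-robust Wald intervals; the
    successful-transition ORs are closed-form from the fitted per-arm
    matrices with delta-method intervals.
    """
    spec = fit.spec
    if spec.mode != "multigroup":
        raise ValueError("transition efficacy requires a multigroup fit (g parameters)")
    if spec.u2_reference != "stay":
        raise ValueError("transition efficacy table expects the stay-reference coding")
    names = spec.param_names
    est = fit.params.as_series()
    se = fit.se()
    rows = []
    stage_of = {"pre_intention": Stage.PRE_INTENTION, "intention": Stage.INTENTION, "action": Stage.ACTION}
    for name in names:
        if name.startswith("u2[") and name.endswith(":arm"):
            cell = name[len("u2[") : name.index("]")]
            frm_s, to_s = cell.split("->")
            contrast = f"{stage_of[frm_s].name} -> {stage_of[to_s].name} (vs stay)"
            rows.append(_wald(contrast, est[name], se[name]).as_row())

    theta = fit.params.theta
    for frm in (Stage.PRE_INTENTION, Stage.INTENTION):

        def log_sor(th, frm=frm):
            mats = implied_matrices(MarkovParams(spec, th))
            return float(np.log(success_or(mats[0], mats[1], frm)))

        se_l = _delta_log_se(log_sor, theta, fit.vcov)
        rows.append(
            _wald(f"{frm.name}: successful transition", log_sor(theta), se_l).as_row()
        )
    return pd.DataFrame(rows)


def membership_or_from_fit(fit: MarkovFit) -> pd.DataFrame:
    """Stage-membership odds ratios at W2 (intervention vs control), one per
    non-reference stage, from the U1 arm coefficients."""
    est = fit.params.as_series()
    se = fit.se()
    rows = []
    for name in fit.spec.param_names:
        if name.startswith("u1[") and name.endswith(":arm"):
            stage = name[len("u1[") : name.index("]")].upper()
            contrast = f"W2 membership {stage} (vs {fit.spec.u1_reference.name})"
            rows.append(_wald(contrast, est[name], se[name]).as_row())
    if not rows:
        raise ValueError("fit does not include the arm in the membership model")
    return pd.DataFrame(rows)


def transition_diagram_dot(matrices: dict[int, TransitionMatrix]) -> str:
    """Per-arm transition diagram in DOT format: node labels carry the stay
    probabilities, solid edges are forward moves, dashed edges backward."""
    arm_names = {0: "control", 1: "intervention"}
    lines = ["digraph transitions {", "  rankdir=LR;"]
    for arm, mat in sorted(matrices.items()):
        g = arm_names.get(arm, str(arm))
        lines.append(f"  subgraph cluster_{arm} {{")
        lines.append(f'    label="{g}";')
        for s in Stage:
            stay = mat.probs[int(s) - 1, int(s) - 1]
            lines.append(f'    {g}_{s.name} [label="{s.name}\\nstay {stay:.3f}", shape=circle];')
        for j in Stage:
            for k in Stage:
                if j == k or j == Stage.ACTION:
                    continue
                p = mat.probs[int(j) - 1, int(k) - 1]
                style = "solid" if int(k) > int(j) else "dashed"
                lines.append(
                    f'    {g}_{j.name} -> {g}_{k.name} [label="{p:.3f}", style={style}];'
                )
        lines.append("  }")
    lines.append("}")
    return "\n".join(lines)
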