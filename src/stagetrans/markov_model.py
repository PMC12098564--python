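"""First-order manifest Markov chain of stage transitions.

The model is two linked multinomial logistic regressions over the three
ordered HAPA stages (pre-intention, intention, action):

* **U1** — stage membership at the first wave (W2), a multinomial logit
  with reference category *action* and the trial arm (plus any baseline
  covariates) in the linear predictor.
* **U2** — the W2 -> W3 transition, a conditional multinomial logit per
  non-absorbing origin stage. *Action is absorbing*: its transition row is
  structurally fixed at (0, 0, 1) and carries no parameters.

Two model modes mirror the restrained/unrestrained comparison of the
trial analysis:

* ``mode="covariate"`` (Model 1, restrained): the arm enters U1 only; both
  arms share one transition matrix.
* ``mode="multigroup"`` (Model 2, unrestrained): U2 cell logits are
  ``b_jk + g_jk * arm``, i.e. group-specific transition matrices. The
  ``g_jk`` slopes are the intervention-efficacy parameters; with the
  stay-on-the-diagonal reference, ``exp(g_jk)`` is the transition odds
  ratio for intervention vs control.

Estimation is full-information maximum likelihood: a record missing W3
contributes its U1 term only (the transition marginalizes out by
row-stochasticity); a record missing W2 contributes the mixture
``sum_j P(W2=j) P(W3=k | j)``. Records missing both waves must have been
excluded upstream. Standard errors come from a clinic-clustered sandwich
estimator A^-1 B A^-1 with cluster-summed scores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .data_model import PanelError, Stage, StagePanel

__all__ = [
    "TransitionMatrix",
    "MarkovSpec",
    "MarkovParams",
    "MarkovFit",
    "loglik",
    "fit",
    "entropy",
    "reparameterize",
]

_STAGE_NAMES = {0: "pre_intention", 1: "intention", 2: "action"}
_ACTION = 2  # 0-based index of the absorbing stage

#: z for 95% Wald intervals (two-sided).
Z_95 = 1.959964


class TransitionMatrix:
    """Row-stochastic 3x3 matrix of P(stage at W3 = k | stage at W2 = j).

    Rows are normalized on construction (printed probability tables can
    sum to 0.999/1.001 from rounding; every odds-based quantity is
    invariant to that rescaling). The action row must be the point mass
    (0, 0, 1) when ``enforce_absorbing`` is set.
    """

    def __init__(self, probs, enforce_absorbing: bool = True):
        p = np.asarray(probs, dtype=float)
        if p.shape != (3, 3):
            raise ValueError(f"transition matrix must be 3x3, got {p.shape}")
        if (p < 0).any():
            raise ValueError("transition probabilities must be non-negative")
        rowsum = p.sum(axis=1)
        if (rowsum <= 0).any():
            raise ValueError("each transition row needs positive mass")
        p = p / rowsum[:, None]
        if enforce_absorbing and not np.allclose(p[_ACTION], [0.0, 0.0, 1.0], atol=1e-9):
            raise ValueError("action row must be the absorbing point mass (0, 0, 1)")
        self.probs = p

    def __getitem__(self, idx):
        return self.probs[idx]

    def row(self, stage: Stage) -> np.ndarray:
        return self.probs[int(stage) - 1]

    def to_frame(self) -> pd.DataFrame:
        names = [Stage(i + 1).name for i in range(3)]
        return pd.DataFrame(self.probs, index=names, columns=names)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"TransitionMatrix(\n{np.array_str(self.probs, precision=4)})"


@dataclass(frozen=True)
class MarkovSpec:
    """Model definition: mode, reference categories, covariates."""

    mode: str = "multigroup"  # "covariate" (restrained) | "multigroup"
    u2_reference: str = "stay"  # "stay" (diagonal) | "action"
    u1_reference: Stage = Stage.ACTION
    covariates: tuple[str, ...] = ()

    def __post_init__(self):
        if self.mode not in ("covariate", "multigroup"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.u2_reference not in ("stay", "action"):
            raise ValueError(f"unknown u2_reference {self.u2_reference!r}")

    # -- parameter bookkeeping --------------------------------------------
    @property
    def u1_free_stages(self) -> list[int]:
        ref = int(self.u1_reference) - 1
        return [s for s in range(3) if s != ref]

    def u2_reference_for_row(self, j: int) -> int:
        return j if self.u2_reference == "stay" else _ACTION

    def u2_free_dests(self, j: int) -> list[int]:
        ref = self.u2_reference_for_row(j)
        return [k for k in range(3) if k != ref]

    @property
    def x1_columns(self) -> list[str]:
        return ["const", "arm", *self.covariates]

    @property
    def x2_columns(self) -> list[str]:
        cols = ["const"]
        if self.mode == "multigroup":
            cols.append("arm")
        cols.extend(self.covariates)
        return cols

    @property
    def param_names(self) -> list[str]:
        names = []
        for m in self.u1_free_stages:
            for c in self.x1_columns:
                names.append(f"u1[{_STAGE_NAMES[m]}]:{c}")
        for j in (0, 1):
            for k in self.u2_free_dests(j):
                for c in self.x2_columns:
                    names.append(f"u2[{_STAGE_NAMES[j]}->{_STAGE_NAMES[k]}]:{c}")
        return names

    @property
    def n_free(self) -> int:
        return len(self.param_names)


@dataclass
class MarkovParams:
    """Flat parameter vector plus its naming, tied to a :class:`MarkovSpec`."""

    spec: MarkovSpec
    theta: np.ndarray

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.shape != (self.spec.n_free,):
            raise ValueError(
                f"theta has length {self.theta.size}, spec expects {self.spec.n_free}"
            )

    def as_series(self) -> pd.Series:
        return pd.Series(self.theta, index=self.spec.param_names)

    def __getitem__(self, name: str) -> float:
        return float(self.as_series()[name])


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


class _Design:
    """Pre-extracted arrays for fast vectorized likelihood evaluation."""

    def __init__(self, panel: StagePanel, spec: MarkovSpec):
        df = panel.data
        both_missing = df["stage_w2"].isna() & df["stage_w3"].isna()
        if both_missing.any():
            raise PanelError(
                "records missing both waves must be excluded before fitting: "
                f"pids {df.loc[both_missing, 'pid'].head().tolist()}"
            )
        w2 = df["stage_w2"].fillna(0).astype(int).to_numpy() - 1
        w2[df["stage_w2"].isna().to_numpy()] = -1
        w3 = df["stage_w3"].fillna(0).astype(int).to_numpy() - 1
        w3[df["stage_w3"].isna().to_numpy()] = -1
        bad = (w2 == _ACTION) & (w3 >= 0) & (w3 != _ACTION)
        if bad.any():
            raise PanelError(
                "records leave the absorbing action stage: "
                f"pids {df.loc[bad, 'pid'].head().tolist()}"
            )
        self.w2, self.w3 = w2, w3
        self.n = len(df)
        arm = df["arm"].to_numpy(dtype=float)
        for c in spec.covariates:
            if c not in df.columns:
                raise PanelError(f"covariate column {c!r} not in panel")
        covs = (
            df[list(spec.covariates)].to_numpy(dtype=float)
            if spec.covariates
            else np.empty((self.n, 0))
        )
        if np.isnan(covs).any():
            raise PanelError("covariates must be complete (no missing values)")
        ones = np.ones((self.n, 1))
        self.X1 = np.hstack([ones, arm[:, None], covs])
        self.X2 = (
            np.hstack([ones, arm[:, None], covs])
            if spec.mode == "multigroup"
            else np.hstack([ones, covs])
        )
        self.clinic = pd.factorize(df["clinic"])[0]
        self.spec = spec
        # index blocks into theta
        p1, p2 = self.X1.shape[1], self.X2.shape[1]
        pos = 0
        self.u1_slices: dict[int, slice] = {}
        for m in spec.u1_free_stages:
            self.u1_slices[m] = slice(pos, pos + p1)
            pos += p1
        self.u2_slices: dict[tuple[int, int], slice] = {}
        for j in (0, 1):
            for k in spec.u2_free_dests(j):
                self.u2_slices[(j, k)] = slice(pos, pos + p2)
                pos += p2
        self.n_free = pos

    # -- probability surfaces ---------------------------------------------
    def _softmax_rows(self, eta: np.ndarray) -> np.ndarray:
        eta = eta - eta.max(axis=1, keepdims=True)
        e = np.exp(eta)
        return e / e.sum(axis=1, keepdims=True)

    def probabilities(self, theta: np.ndarray):
        """Membership probabilities pi (n x 3) and transition rows P[j] (n x 3)."""
        eta1 = np.zeros((self.n, 3))
        for m, sl in self.u1_slices.items():
            eta1[:, m] = self.X1 @ theta[sl]
        pi = self._softmax_rows(eta1)
        P = []
        for j in (0, 1):
            eta2 = np.zeros((self.n, 3))
            for k in self.spec.u2_free_dests(j):
                eta2[:, k] = self.X2 @ theta[self.u2_slices[(j, k)]]
            P.append(self._softmax_rows(eta2))
        return pi, P

    # -- likelihood, scores ------------------------------------------------
    def loglik_score(self, theta: np.ndarray, want_scores: bool = False):
        pi, P = self.probabilities(theta)
        w2, w3, n = self.w2, self.w3, self.n
        rows = np.arange(n)

        obs2 = w2 >= 0
        obs3 = w3 >= 0
        # U1 posterior weights over the W2 stage
        W1 = np.zeros((n, 3))
        W1[obs2, w2[obs2]] = 1.0
        # U2 destination weights per origin row
        Wd = [np.zeros((n, 3)), np.zeros((n, 3))]
        ll = np.zeros(n)

        # boundary-bound logits can underflow a cell to exactly 0 during a
        # line search; the resulting log(0) = -inf is rejected by the
        # search itself, so the divide warning is suppressed
        with np.errstate(divide="ignore"):
            # fully / W3-missing records with W2 observed
            ll[obs2] = np.log(pi[obs2, w2[obs2]])
            for j in (0, 1):
                m = obs2 & obs3 & (w2 == j)
                ll[m] += np.log(P[j][m, w3[m]])
                Wd[j][m, w3[m]] = 1.0
            # W2 == action, W3 observed contributes log 1 from U2 (validated)

            # W2 missing: mixture over origins
            miss2 = ~obs2
            if miss2.any():
                k = w3[miss2]
                comp = np.stack(
                    [
                        pi[miss2, 0] * P[0][miss2, k],
                        pi[miss2, 1] * P[1][miss2, k],
                        pi[miss2, 2] * (k == _ACTION),
                    ],
                    axis=1,
                )
                L = comp.sum(axis=1)
                ll[miss2] = np.log(L)
                post = comp / L[:, None]
                W1[miss2] = post
                for j in (0, 1):
                    Wd[j][miss2, k] = post[:, j]

        total = float(ll.sum())
        if not want_scores:
            return total, None, None

        # score in eta space, then chain through the design matrices
        S1 = W1 - pi  # d loglik / d eta1 (only free columns used)
        Sd = [Wd[j] - Wd[j].sum(axis=1, keepdims=True) * P[j] for j in (0, 1)]

        S = np.zeros((n, self.n_free))
        for m, sl in self.u1_slices.items():
            S[:, sl] = self.X1 * S1[:, [m]]
        for (j, k), sl in self.u2_slices.items():
            S[:, sl] = self.X2 * Sd[j][:, [k]]
        return total, S.sum(axis=0), S

    def neg_loglik_grad(self, theta: np.ndarray):
        ll, g, _ = self.loglik_score(theta, want_scores=True)
        return -ll, -g

    def hessian(self, theta: np.ndarray) -> np.ndarray:
        """Observed Hessian of the log-likelihood by central differences of
        the analytic gradient."""
        p = theta.size
        H = np.zeros((p, p))
        for l in range(p):
            h = 1e-5 * max(1.0, abs(theta[l]))
            tp, tm = theta.copy(), theta.copy()
            tp[l] += h
            tm[l] -= h
            _, gp, _ = self.loglik_score(tp, want_scores=True)
            _, gm, _ = self.loglik_score(tm, want_scores=True)
            H[:, l] = (gp - gm) / (2 * h)
        return (H + H.T) / 2.0

    def posteriors(self, theta: np.ndarray):
        """Per-record posterior over the missing stage (None if complete)."""
        pi, P = self.probabilities(theta)
        out: list[np.ndarray | None] = []
        for i in range(self.n):
            if self.w2[i] >= 0 and self.w3[i] >= 0:
                out.append(None)
            elif self.w3[i] < 0:  # missing W3: predicted transition row
                j = self.w2[i]
                row = np.array([0.0, 0.0, 1.0]) if j == _ACTION else P[j][i]
                out.append(row)
            else:  # missing W2: posterior origin given observed W3
                k = self.w3[i]
                comp = np.array(
                    [
                        pi[i, 0] * P[0][i, k],
                        pi[i, 1] * P[1][i, k],
                        pi[i, 2] * (k == _ACTION),
                    ]
                )
                out.append(comp / comp.sum())
        return out


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def loglik(params: MarkovParams, panel: StagePanel, spec: MarkovSpec | None = None) -> float:
    """Full-information log-likelihood of ``panel`` under ``params``."""
    spec = spec or params.spec
    d = _Design(panel, spec)
    ll, _, _ = d.loglik_score(params.theta)
    return ll


@dataclass
class MarkovFit:
    """Fitted manifest Markov model."""

    spec: MarkovSpec
    params: MarkovParams
    vcov: np.ndarray
    loglik: float
    n_free: int
    n_used: int
    matrices: dict[int, TransitionMatrix]
    u1_probs: dict[int, np.ndarray]
    converged: bool
    n_starts_agreeing: int
    clusters: int = 0

    @property
    def g2(self) -> float:
        return -2.0 * self.loglik

    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.vcov)), index=self.spec.param_names)

    def summary(self) -> pd.DataFrame:
        est = self.params.as_series()
        se = self.se()
        frame = pd.DataFrame({"estimate": est, "se": se})
        frame["z"] = frame["estimate"] / frame["se"]
        frame["ci_low"] = frame["estimate"] - Z_95 * frame["se"]
        frame["ci_high"] = frame["estimate"] + Z_95 * frame["se"]
        return frame

    def to_dict(self) -> dict:
        return {
            "mode": self.spec.mode,
            "u2_reference": self.spec.u2_reference,
            "covariates": list(self.spec.covariates),
            "param_names": self.spec.param_names,
            "estimates": self.params.theta.tolist(),
            "vcov": self.vcov.tolist(),
            "loglik": self.loglik,
            "g2": self.g2,
            "n_free": self.n_free,
            "n_used": self.n_used,
            "clusters": self.clusters,
            "converged": self.converged,
            "n_starts_agreeing": self.n_starts_agreeing,
            "matrices": {str(a): m.probs.tolist() for a, m in self.matrices.items()},
            "u1_probs": {str(a): p.tolist() for a, p in self.u1_probs.items()},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "MarkovFit":
        spec = MarkovSpec(
            mode=d["mode"],
            u2_reference=d["u2_reference"],
            covariates=tuple(d["covariates"]),
        )
        return cls(
            spec=spec,
            params=MarkovParams(spec, np.asarray(d["estimates"])),
            vcov=np.asarray(d["vcov"]),
            loglik=d["loglik"],
            n_free=d["n_free"],
            n_used=d["n_used"],
            matrices={int(a): TransitionMatrix(m) for a, m in d["matrices"].items()},
            u1_probs={int(a): np.asarray(p) for a, p in d["u1_probs"].items()},
            converged=d["converged"],
            n_starts_agreeing=d["n_starts_agreeing"],
            clusters=d.get("clusters", 0),
        )

    @classmethod
    def from_json(cls, path) -> "MarkovFit":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _empirical_start(design: _Design, spec: MarkovSpec) -> np.ndarray:
    """Moment-based start: logits of complete-case empirical proportions.

    For the saturated (no-covariate) model on complete data this is the
    MLE itself, so the optimizer only has to polish it; covariate slopes
    start at zero.
    """
    theta = np.zeros(design.n_free)
    w2, w3 = design.w2, design.w3
    arm = design.X1[:, 1]
    eps = 0.5  # additive smoothing so boundary cells stay finite

    def logit_table(mask):
        counts = np.array([(mask & (w2 == s)).sum() for s in range(3)], float) + eps
        p = counts / counts.sum()
        ref = int(spec.u1_reference) - 1
        return np.log(p / p[ref])

    l0 = logit_table(arm == 0)
    l1 = logit_table(arm == 1)
    for m, sl in design.u1_slices.items():
        block = np.zeros(sl.stop - sl.start)
        block[0] = l0[m]
        block[1] = l1[m] - l0[m]
        theta[sl] = block

    for j in (0, 1):
        ref = spec.u2_reference_for_row(j)

        def row_logits(mask):
            counts = (
                np.array(
                    [(mask & (w2 == j) & (w3 == k)).sum() for k in range(3)],
                    float,
                )
                + eps
            )
            p = counts / counts.sum()
            return np.log(p / p[ref])

        if spec.mode == "multigroup":
            r0 = row_logits((arm == 0) & (w3 >= 0))
            r1 = row_logits((arm == 1) & (w3 >= 0))
            for k in spec.u2_free_dests(j):
                sl = design.u2_slices[(j, k)]
                block = np.zeros(sl.stop - sl.start)
                block[0] = r0[k]
                block[1] = r1[k] - r0[k]
                theta[sl] = block
        else:
            r = row_logits(w3 >= 0)
            for k in spec.u2_free_dests(j):
                sl = design.u2_slices[(j, k)]
                block = np.zeros(sl.stop - sl.start)
                block[0] = r[k]
                theta[sl] = block
    return theta


def fit(
    panel: StagePanel,
    spec: MarkovSpec | None = None,
    n_starts: int = 5,
    seed: int | None = None,
    compute_vcov: bool = True,
) -> MarkovFit:
    """Maximize the FIML likelihood from multiple starting points.

    One start is moment-based (empirical logits); the remaining
    ``n_starts - 1`` are drawn uniformly on [-2, 2] per slope from the
    given seed, guarding against local optima. The covariance is the
    clinic-clustered sandwich A^-1 B A^-1 (A = observed information,
    B = outer product of cluster-summed scores).
    """
    if spec is None:
        spec = MarkovSpec()
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    design = _Design(panel, spec)
    rng = np.random.default_rng(seed)

    starts = [_empirical_start(design, spec)]
    for _ in range(n_starts - 1):
        starts.append(rng.uniform(-2.0, 2.0, size=design.n_free))

    results = []
    for x0 in starts:
        res = minimize(
            design.neg_loglik_grad,
            x0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 1000, "ftol": 1e-13, "gtol": 1e-8},
        )
        results.append(res)
    best = max(results, key=lambda r: -r.fun)
    theta, ll = _newton_polish(design, best.x)
    agree = sum(1 for r in results if abs(-r.fun - ll) < 1e-4)

    if compute_vcov:
        _, _, S = design.loglik_score(theta, want_scores=True)
        H = design.hessian(theta)
        A = -H
        cluster_scores = np.zeros((design.clinic.max() + 1, design.n_free))
        np.add.at(cluster_scores, design.clinic, S)
        B = cluster_scores.T @ cluster_scores
        try:
            Ainv = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            Ainv = np.linalg.pinv(A)
        vcov = Ainv @ B @ Ainv
    else:
        vcov = np.full((design.n_free, design.n_free), np.nan)

    matrices, u1_probs = _implied_by_arm(design, spec, theta)
    return MarkovFit(
        spec=spec,
        params=MarkovParams(spec, theta),
        vcov=vcov,
        loglik=ll,
        n_free=design.n_free,
        n_used=design.n,
        matrices=matrices,
        u1_probs=u1_probs,
        converged=bool(best.success),
        n_starts_agreeing=agree,
        clusters=int(design.clinic.max() + 1),
    )


def _newton_polish(design: _Design, theta: np.ndarray, max_iter: int = 50):
    """Newton refinement with halving line search; the quasi-Newton optimum
    is good to ~1e-7 in probabilities, Newton steps push the gradient to
    machine precision so saturated fits match empirical proportions."""
    ll, g, _ = design.loglik_score(theta, want_scores=True)
    for _ in range(max_iter):
        if np.max(np.abs(g)) < 1e-9:
            break
        H = design.hessian(theta)
        try:
            step = np.linalg.solve(-H, g)
        except np.linalg.LinAlgError:
            break
        if not np.isfinite(step).all():
            break
        scale = 1.0
        improved = False
        for _ in range(30):
            cand = theta + scale * step
            ll_new, g_new, _ = design.loglik_score(cand, want_scores=True)
            if ll_new >= ll - 1e-12:
                theta, ll, g = cand, ll_new, g_new
                improved = True
                break
            scale *= 0.5
        if not improved:
            break
    return theta, ll


def _implied_by_arm(design: _Design, spec: MarkovSpec, theta: np.ndarray):
    """Per-arm transition matrices and membership probabilities at the
    reference covariate profile (all covariates zero)."""
    matrices: dict[int, TransitionMatrix] = {}
    u1_probs: dict[int, np.ndarray] = {}
    q = len(spec.covariates)
    for a in (0, 1):
        x1 = np.concatenate([[1.0, float(a)], np.zeros(q)])
        x2 = (
            np.concatenate([[1.0, float(a)], np.zeros(q)])
            if spec.mode == "multigroup"
            else np.concatenate([[1.0], np.zeros(q)])
        )
        eta1 = np.zeros(3)
        for m, sl in design.u1_slices.items():
            eta1[m] = x1 @ theta[sl]
        e = np.exp(eta1 - eta1.max())
        u1_probs[a] = e / e.sum()
        P = np.zeros((3, 3))
        P[_ACTION, _ACTION] = 1.0
        for j in (0, 1):
            eta2 = np.zeros(3)
            for k in spec.u2_free_dests(j):
                eta2[k] = x2 @ theta[design.u2_slices[(j, k)]]
            e = np.exp(eta2 - eta2.max())
            P[j] = e / e.sum()
        matrices[a] = TransitionMatrix(P)
    return matrices, u1_probs


def entropy(fit_result: MarkovFit, panel: StagePanel) -> float:
    """Normalized posterior-classification certainty in [0, 1].

    ``1 - sum_i H(posterior_i) / (n log 3)`` where the posterior of a
    record is over its missing stage (the predicted transition row when
    W3 is missing; the Bayes posterior over the W2 origin when W2 is
    missing). Fully observed records have degenerate posteriors and
    contribute zero entropy, so a complete panel scores exactly 1.
    """
    design = _Design(panel, fit_result.spec)
    posts = design.posteriors(fit_result.params.theta)
    h = 0.0
    for p in posts:
        if p is None:
            continue
        q = p[p > 0]
        h += float(-(q * np.log(q)).sum())
    return 1.0 - h / (design.n * np.log(3.0))


# ---------------------------------------------------------------------------
# reparameterization between U2 reference codings
# ---------------------------------------------------------------------------

# For origin row j the map between stay-reference logits (lambda, relative
# to the diagonal) and action-reference logits (eta, relative to the action
# column) is linear, so it applies column-by-column to every U2 coefficient
# block (intercept b, arm slope g, covariate slopes alike).
_STAY_TO_ACTION = {
    # row pre: stay dests (int, act) -> action dests (pre, int)
    0: np.array([[0.0, -1.0], [1.0, -1.0]]),
    # row int: stay dests (pre, act) -> action dests (pre, int)
    1: np.array([[1.0, -1.0], [0.0, -1.0]]),
}


def reparameterize(obj: MarkovFit | MarkovParams) -> MarkovParams:
    """Convert fitted U2 parameters between the stay- and action-reference
    codings. The implied transition matrices are identical under both; only
    which logit contrasts are reported changes."""
    params = obj.params if isinstance(obj, MarkovFit) else obj
    spec = params.spec
    new_ref = "action" if spec.u2_reference == "stay" else "stay"
    new_spec = replace(spec, u2_reference=new_ref)
    # rebuild slice maps without data
    dummy = _slices_only(spec)
    dummy_new = _slices_only(new_spec)
    theta_new = np.zeros(new_spec.n_free)
    # U1 block unchanged
    for m in spec.u1_free_stages:
        theta_new[dummy_new.u1[m]] = params.theta[dummy.u1[m]]
    for j in (0, 1):
        M = _STAY_TO_ACTION[j]
        if spec.u2_reference == "action":
            M = np.linalg.inv(M)
        old = np.stack(
            [params.theta[dummy.u2[(j, k)]] for k in spec.u2_free_dests(j)]
        )  # (2, p2)
        new = M @ old
        for i, k in enumerate(new_spec.u2_free_dests(j)):
            theta_new[dummy_new.u2[(j, k)]] = new[i]
    return MarkovParams(new_spec, theta_new)


class _slices_only:
    """Parameter slice layout for a spec, independent of any panel."""

    def __init__(self, spec: MarkovSpec):
        p1 = len(spec.x1_columns)
        p2 = len(spec.x2_columns)
        pos = 0
        self.u1: dict[int, slice] = {}
        for m in spec.u1_free_stages:
            self.u1[m] = slice(pos, pos + p1)
            pos += p1
        self.u2: dict[tuple[int, int], slice] = {}
        for j in (0, 1):
            for k in spec.u2_free_dests(j):
                self.u2[(j, k)] = slice(pos, pos + p2)
                pos += p2


def implied_matrices(params: MarkovParams) -> dict[int, TransitionMatrix]:
    """Per-arm transition matrices implied by raw parameters (covariates
    at zero)."""
    spec = params.spec
    sl = _slices_only(spec)
    q = len(spec.covariates)
    out = {}
    for a in (0, 1):
        x2 = (
            np.concatenate([[1.0, float(a)], np.zeros(q)])
            if spec.mode == "multigroup"
            else np.concatenate([[1.0], np.zeros(q)])
        )
        P = np.zeros((3, 3))
        P[_ACTION, _ACTION] = 1.0
        for j in (0, 1):
            eta = np.zeros(3)
            for k in spec.u2_free_dests(j):
                eta[k] = x2 @ params.theta[sl.u2[(j, k)]]
            e = np.exp(eta - eta.max())
            P[j] = e / e.sum()
        out[a] = TransitionMatrix(P)
    return out
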