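"""Seeded synthetic trial panels with the structure of the source design.

The generator emulates a cluster-randomized parental-disclosure trial:
clinics randomized to two arms, a W2 stage drawn per participant from a
multinomial logit (with a clinic-level random intercept on the logit
scale), a W2 -> W3 transition drawn from a conditional multinomial logit
whose cell logits are ``b_jk + g_jk * arm``, an absorbing action stage,
and per-wave missingness under a configurable mechanism. Published
marginal tables are exposed as module constants and drive the default
parameter values, so an out-of-the-box panel has the study's footprint:
40 clinics of ~20 parents, roughly even stage split weighted toward
pre-intention, modest transition rates, and a few percent missingness
per wave.

``fixture_from_counts`` builds *deterministic* panels whose empirical
crosstabs and transition proportions reproduce given integer tables
exactly — the bridge between printed tables and estimator tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import StagePanel
from .markov_model import TransitionMatrix

__all__ = [
    "TrialConfig",
    "TruthManifest",
    "generate_trial",
    "fixture_from_counts",
    "largest_remainder",
    "published_table_panel",
    "W2_COUNTS",
    "W3_COUNTS",
    "CONTROL_TRANSITIONS",
    "INTERVENTION_TRANSITIONS",
]

# ---------------------------------------------------------------------------
# published marginal tables (counts / estimated probabilities), used as
# fixture targets and as the source of realistic default parameters
# ---------------------------------------------------------------------------

#: W2 stage counts, rows (control, intervention), columns ordered
#: pre-intention / intention / action.
W2_COUNTS = np.array([[179, 134, 59], [173, 133, 64]])

#: W3 stage counts, same layout.
W3_COUNTS = np.array([[200, 129, 37], [170, 127, 72]])

#: Estimated W2->W3 transition probabilities (1 dp as published; rows are
#: renormalized by TransitionMatrix).
CONTROL_TRANSITIONS = np.array(
    [[0.783, 0.194, 0.023], [0.342, 0.577, 0.081], [0.0, 0.0, 1.0]]
)
INTERVENTION_TRANSITIONS = np.array(
    [[0.741, 0.187, 0.073], [0.247, 0.588, 0.166], [0.0, 0.0, 1.0]]
)


def _u1_logits_from_counts(counts: np.ndarray) -> np.ndarray:
    """Per-arm membership logits (vs action) from a 2x3 count table."""
    p = counts / counts.sum(axis=1, keepdims=True)
    return np.log(p[:, :2] / p[:, [2]])


def _stay_ref_logits(matrix: np.ndarray) -> np.ndarray:
    """2x2 stay-reference transition logits [row j, free dest order]."""
    m = np.asarray(matrix, float)
    m = m / m.sum(axis=1, keepdims=True)
    # row pre: dests (intention, action) vs stay; row int: (pre, action) vs stay
    return np.array(
        [
            [np.log(m[0, 1] / m[0, 0]), np.log(m[0, 2] / m[0, 0])],
            [np.log(m[1, 0] / m[1, 1]), np.log(m[1, 2] / m[1, 1])],
        ]
    )


_DEFAULT_B = _stay_ref_logits(CONTROL_TRANSITIONS)
_DEFAULT_G = _stay_ref_logits(INTERVENTION_TRANSITIONS) - _DEFAULT_B
_DEFAULT_U1 = _u1_logits_from_counts(W2_COUNTS)

#: clinic_sd giving a latent-logit ICC of 0.10:
#: ICC = sd^2 / (sd^2 + pi^2/3)  =>  sd = sqrt(0.10/0.90 * pi^2/3)
_DEFAULT_CLINIC_SD = float(np.sqrt(0.10 / 0.90 * np.pi**2 / 3.0))


@dataclass
class TrialConfig:
    """Generator parameters; the defaults are the study conditions.

    ``u1_logits`` is (2 arms x 2 stages): membership logits of
    pre-intention and intention vs action, rows (control, intervention).
    ``b_logits``/``g_effects`` are 2x2 stay-reference transition slopes:
    row = origin (pre-intention, intention); columns = the two
    non-diagonal destinations in stage order. Missingness defaults match
    the observed per-wave rates (~1.2% at W2, ~2.1% at W3), MCAR.
    """

    n_clinics: int = 40
    clinic_size: int = 20
    allocation: float = 0.5
    u1_logits: np.ndarray = field(default_factory=lambda: _DEFAULT_U1.copy())
    b_logits: np.ndarray = field(default_factory=lambda: _DEFAULT_B.copy())
    g_effects: np.ndarray = field(default_factory=lambda: _DEFAULT_G.copy())
    clinic_sd: float = _DEFAULT_CLINIC_SD
    miss_w2: float = 9 / 751
    miss_w3: float = 16 / 751
    miss_mechanism: str = "MCAR"  # MCAR | MAR-on-arm | MNAR-on-stage
    mar_logit_shift: float = 1.0
    mnar_logit_shift: float = 1.0
    seed: int = 0

    def __post_init__(self):
        self.u1_logits = np.asarray(self.u1_logits, float).reshape(2, 2)
        self.b_logits = np.asarray(self.b_logits, float).reshape(2, 2)
        self.g_effects = np.asarray(self.g_effects, float).reshape(2, 2)
        if self.n_clinics < 2:
            raise ValueError("need at least 2 clinics")
        if self.clinic_sd < 0:
            raise ValueError("clinic_sd must be >= 0")
        for p in (self.allocation, self.miss_w2, self.miss_w3):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.miss_mechanism not in ("MCAR", "MAR-on-arm", "MNAR-on-stage"):
            raise ValueError(f"unknown missingness mechanism {self.miss_mechanism!r}")
        n_int = round(self.allocation * self.n_clinics)
        if n_int == 0 or n_int == self.n_clinics:
            raise ValueError("allocation leaves an arm without clinics")

    @property
    def icc(self) -> float:
        """Implied latent-logit intraclass correlation."""
        v = self.clinic_sd**2
        return v / (v + np.pi**2 / 3.0)

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("u1_logits", "b_logits", "g_effects"):
            d[k] = np.asarray(d[k]).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrialConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown TrialConfig fields: {sorted(unknown)}")
        return cls(**d)


@dataclass
class TruthManifest:
    """Exact generating parameters and the implied per-arm matrices."""

    config: TrialConfig
    matrices: dict[int, TransitionMatrix]
    u1_probs: dict[int, np.ndarray]
    icc: float
    arm_of_clinic: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "matrices": {str(a): m.probs.tolist() for a, m in self.matrices.items()},
            "u1_probs": {str(a): p.tolist() for a, p in self.u1_probs.items()},
            "icc": self.icc,
            "arm_of_clinic": self.arm_of_clinic,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _softmax(eta: np.ndarray) -> np.ndarray:
    e = np.exp(eta - eta.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def implied_truth(config: TrialConfig) -> tuple[dict[int, TransitionMatrix], dict[int, np.ndarray]]:
    """Marginal (clinic effect at zero) per-arm matrices and W2 probabilities."""
    matrices, u1 = {}, {}
    for a in (0, 1):
        eta1 = np.array([config.u1_logits[a, 0], config.u1_logits[a, 1], 0.0])
        u1[a] = _softmax(eta1)
        P = np.eye(3)[[2, 2, 2]] * 0.0
        P[2, 2] = 1.0
        slopes = config.b_logits + a * config.g_effects
        # row pre: logits of (int, act) vs stay; row int: (pre, act) vs stay
        eta_pre = np.array([0.0, slopes[0, 0], slopes[0, 1]])
        eta_int = np.array([slopes[1, 0], 0.0, slopes[1, 1]])
        P[0] = _softmax(eta_pre)
        P[1] = _softmax(eta_int)
        matrices[a] = TransitionMatrix(P)
    return matrices, u1


def generate_trial(config: TrialConfig) -> tuple[StagePanel, TruthManifest]:
    """Draw a complete two-wave panel; identical config => identical panel."""
    rng = np.random.default_rng(config.seed)
    nc, m = config.n_clinics, config.clinic_size
    n_int = round(config.allocation * nc)
    arm_of_clinic = np.zeros(nc, dtype=int)
    arm_of_clinic[rng.permutation(nc)[:n_int]] = 1
    clinic_effect = rng.normal(0.0, config.clinic_sd, size=nc)

    n = nc * m
    clinic = np.repeat(np.arange(nc), m)
    arm = arm_of_clinic[clinic]
    ce = clinic_effect[clinic]

    # W2 stage: multinomial logit, clinic effect on both non-reference logits
    eta1 = np.zeros((n, 3))
    eta1[:, 0] = config.u1_logits[arm, 0] + ce
    eta1[:, 1] = config.u1_logits[arm, 1] + ce
    p1 = _softmax(eta1)
    u = rng.random(n)
    w2 = (u[:, None] > p1.cumsum(axis=1)).sum(axis=1)  # 0,1,2

    # W3 stage: conditional logit with stay reference; action absorbing
    slopes = config.b_logits[None, :, :] + arm[:, None, None] * config.g_effects[None, :, :]
    eta2 = np.zeros((n, 3))
    is_pre = w2 == 0
    is_int = w2 == 1
    eta2[is_pre, 1] = slopes[is_pre, 0, 0] + ce[is_pre]
    eta2[is_pre, 2] = slopes[is_pre, 0, 1] + ce[is_pre]
    eta2[is_int, 0] = slopes[is_int, 1, 0] + ce[is_int]
    eta2[is_int, 2] = slopes[is_int, 1, 1] + ce[is_int]
    p2 = _softmax(eta2)
    u = rng.random(n)
    w3 = (u[:, None] > p2.cumsum(axis=1)).sum(axis=1)
    w3[w2 == 2] = 2  # absorbing

    miss2, miss3 = _draw_missingness(config, rng, arm, w2, w3)

    df = pd.DataFrame(
        {
            "pid": [f"P{i:05d}" for i in range(n)],
            "clinic": [f"C{c:03d}" for c in clinic],
            "arm": arm,
            "stage_w2": pd.array(np.where(miss2, pd.NA, w2 + 1), dtype="Int64"),
            "stage_w3": pd.array(np.where(miss3, pd.NA, w3 + 1), dtype="Int64"),
        }
    )
    panel = StagePanel(df)
    matrices, u1 = implied_truth(config)
    manifest = TruthManifest(
        config=config,
        matrices=matrices,
        u1_probs=u1,
        icc=config.icc,
        arm_of_clinic={f"C{c:03d}": int(arm_of_clinic[c]) for c in range(nc)},
    )
    return panel, manifest


def _draw_missingness(config, rng, arm, w2, w3):
    """Per-wave missingness indicators; both-missing draws are retried so
    no generated record loses both waves."""

    def probs(base, stage):
        if config.miss_mechanism == "MCAR" or base in (0.0, 1.0):
            return np.full(len(stage), base)
        logit = np.log(base / (1.0 - base))
        if config.miss_mechanism == "MAR-on-arm":
            eta = logit + config.mar_logit_shift * arm
        else:  # MNAR-on-stage: shift by the centered true current-wave stage
            eta = logit + config.mnar_logit_shift * (stage - 1.0)
        return 1.0 / (1.0 + np.exp(-eta))

    pm2 = probs(config.miss_w2, w2)
    pm3 = probs(config.miss_w3, w3)
    n = len(arm)
    miss2 = rng.random(n) < pm2
    miss3 = rng.random(n) < pm3
    both = miss2 & miss3
    while both.any():
        miss2[both] = rng.random(both.sum()) < pm2[both]
        miss3[both] = rng.random(both.sum()) < pm3[both]
        both = miss2 & miss3
    return miss2, miss3


# ---------------------------------------------------------------------------
# deterministic fixtures
# ---------------------------------------------------------------------------


def largest_remainder(total: int, probs) -> np.ndarray:
    """Apportion ``total`` into integer counts proportional to ``probs``,
    by the largest-remainder rule, so the counts sum exactly to ``total``."""
    p = np.asarray(probs, float)
    p = p / p.sum()
    raw = p * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:short]] += 1
    return base


def fixture_from_counts(
    w2_counts,
    transition_counts,
    clinics_per_arm: int = 20,
) -> StagePanel:
    """Deterministic complete-data panel reproducing given integer tables.

    ``w2_counts``: 2x3 (arm x stage) W2 counts, control row first.
    ``transition_counts``: 2x3x3 (arm x from x to); each row must sum to
    the matching W2 count and the action row may only feed action.
    Clinics are assigned round-robin within each arm.
    """
    w2c = np.asarray(w2_counts, int)
    trc = np.asarray(transition_counts, int)
    if w2c.shape != (2, 3) or trc.shape != (2, 3, 3):
        raise ValueError("expected w2_counts (2,3) and transition_counts (2,3,3)")
    if (w2c < 0).any() or (trc < 0).any():
        raise ValueError("counts must be non-negative")
    if not (trc.sum(axis=2) == w2c).all():
        raise ValueError("transition rows must sum to the W2 counts")
    if trc[:, 2, :2].any():
        raise ValueError("the action stage is absorbing: action row may only feed action")

    rows = []
    pid = 0
    for a in (0, 1):
        counter = 0
        for j in range(3):
            for k in range(3):
                for _ in range(int(trc[a, j, k])):
                    clinic = f"A{a}C{counter % clinics_per_arm:02d}"
                    rows.append((f"F{pid:05d}", clinic, a, j + 1, k + 1))
                    pid += 1
                    counter += 1
    df = pd.DataFrame(rows, columns=["pid", "clinic", "arm", "stage_w2", "stage_w3"])
    return StagePanel(df)


def published_table_panel(clinics_per_arm: int = 20) -> StagePanel:
    """Fixture panel matching the published W2 margins with transition
    counts apportioned (largest remainder) from the published per-arm
    transition probabilities."""
    mats = {0: CONTROL_TRANSITIONS, 1: INTERVENTION_TRANSITIONS}
    trc = np.zeros((2, 3, 3), dtype=int)
    for a in (0, 1):
        for j in range(3):
            trc[a, j] = largest_remainder(int(W2_COUNTS[a, j]), mats[a][j] + 1e-300)
    return fixture_from_counts(W2_COUNTS, trc, clinics_per_arm=clinics_per_arm)
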