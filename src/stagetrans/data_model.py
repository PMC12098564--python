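"""Domain types, stage coding, panel validation and CSV round-tripping.

The unit of analysis is a two-wave stage panel from a cluster-randomized
trial: one row per participant carrying a clinic (cluster) id, the trial
arm, the HAPA disclosure stage at each follow-up wave (W2 at 6 months, W3
at 12 months; either may be missing, never both), and an open set of
baseline covariates.

Stages follow the Health Action Process Approach ordering
pre-intention < intention < action. The six-category survey response is
collapsed deterministically: response 1 -> pre-intention, 2-3 -> intention,
4-6 -> action.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Stage",
    "collapse_stage",
    "StagePanel",
    "ValidationReport",
    "validate_panel",
    "crosstab",
    "PanelError",
]

#: Core columns every panel CSV must carry, in canonical order.
CORE_COLUMNS = ["pid", "clinic", "arm", "stage_w2", "stage_w3"]

#: Optional six-category response columns accepted alongside the stages.
RESPONSE_COLUMNS = ["response_w2", "response_w3"]

WAVES = ("W2", "W3")


class PanelError(ValueError):
    """Raised for structurally invalid panel input."""


class Stage(enum.IntEnum):
    """Ordered HAPA stage of disclosure readiness."""

    PRE_INTENTION = 1
    INTENTION = 2
    ACTION = 3


def collapse_stage(response: int) -> Stage:
    """Collapse a six-category disclosure response into its HAPA stage.

    Response 1 maps to pre-intention, responses 2-3 to intention and
    responses 4-6 to action.

    Raises
    ------
    PanelError
        If ``response`` is outside 1..6.
    """
    r = int(response)
    if r < 1 or r > 6:
        raise PanelError(f"disclosure response {response!r} outside the 1..6 scale")
    if r == 1:
        return Stage.PRE_INTENTION
    if r <= 3:
        return Stage.INTENTION
    return Stage.ACTION


def _as_nullable_stage(series: pd.Series, name: str) -> pd.Series:
    s = pd.to_numeric(series, errors="raise").astype("Int64")
    bad = s.dropna()[~s.dropna().isin([1, 2, 3])]
    if len(bad):
        raise PanelError(f"column {name}: stage codes outside 1..3 at rows {list(bad.index[:5])}")
    return s


@dataclass
class StagePanel:
    """Two-wave stage panel backed by a :class:`pandas.DataFrame`.

    The frame always carries the core columns ``pid, clinic, arm,
    stage_w2, stage_w3`` (stages as nullable ``Int64``, missing = NA) and
    any number of covariate columns after them.
    """

    data: pd.DataFrame
    waves: tuple[str, str] = WAVES

    def __post_init__(self) -> None:
        missing = [c for c in CORE_COLUMNS if c not in self.data.columns]
        if missing:
            raise PanelError(f"panel is missing required columns: {missing}")
        df = self.data.copy()
        df["stage_w2"] = _as_nullable_stage(df["stage_w2"], "stage_w2")
        df["stage_w3"] = _as_nullable_stage(df["stage_w3"], "stage_w3")
        df["arm"] = pd.to_numeric(df["arm"]).astype(int)
        if not df["arm"].isin([0, 1]).all():
            raise PanelError("arm must be coded control=0 / intervention=1")
        order = CORE_COLUMNS + [c for c in df.columns if c not in CORE_COLUMNS]
        self.data = df[order].reset_index(drop=True)

    # -- basic accessors ---------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def covariate_columns(self) -> list[str]:
        skip = set(CORE_COLUMNS) | set(RESPONSE_COLUMNS)
        return [c for c in self.data.columns if c not in skip]

    def stages(self, wave: str) -> pd.Series:
        if wave not in self.waves:
            raise PanelError(f"unknown wave {wave!r}; expected one of {self.waves}")
        return self.data["stage_w2" if wave == self.waves[0] else "stage_w3"]

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_csv(cls, path_or_buf) -> "StagePanel":
        """Read a panel CSV (``pid,clinic,arm,...``; empty field = missing).

        If six-category ``response_w2``/``response_w3`` columns are present,
        absent stage columns are derived by collapsing them; if both forms
        are present they must agree (checked in :func:`validate_panel`).
        """
        df = pd.read_csv(path_or_buf, dtype={"pid": str, "clinic": str})
        for wave in ("w2", "w3"):
            resp, stage = f"response_{wave}", f"stage_{wave}"
            if resp in df.columns and stage not in df.columns:
                r = pd.to_numeric(df[resp], errors="raise").astype("Int64")
                df[stage] = r.map(lambda v: int(collapse_stage(v)) if pd.notna(v) else pd.NA)
        return cls(df)

    def to_csv(self, path_or_buf=None):
        """Write the panel; missing stages become empty fields."""
        return self.data.to_csv(path_or_buf, index=False)

    def to_csv_bytes(self) -> bytes:
        buf = io.StringIO()
        self.to_csv(buf)
        return buf.getvalue().encode("utf-8")


@dataclass
class ValidationReport:
    """Structured findings from :func:`validate_panel`; never raises."""

    violations: list[str] = field(default_factory=list)
    excluded_pids: list[str] = field(default_factory=list)
    flagged_pids: list[str] = field(default_factory=list)

    @property
    def is_clean(self) -> bool:
        return not self.violations and not self.excluded_pids

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.is_clean and not self.flagged_pids:
            return "panel clean: no violations"
        lines = [f"- {v}" for v in self.violations]
        if self.excluded_pids:
            lines.append(f"- {len(self.excluded_pids)} record(s) missing both waves (exclude)")
        if self.flagged_pids:
            lines.append(f"- {len(self.flagged_pids)} record(s) flagged (inconsistent coding)")
        return "\n".join(lines)


def validate_panel(panel: StagePanel) -> ValidationReport:
    """Check panel invariants and flag records for exclusion.

    Rules checked:

    * participant ids unique;
    * every clinic maps to exactly one arm (cluster randomization);
    * no record missing the stage at both waves (such records are listed
      in ``excluded_pids``, mirroring the trial's CONSORT exclusion);
    * where six-category responses accompany three-stage codes, the stage
      equals the collapse of the response;
    * no backward move out of the absorbing action stage on the collapsed
      scale (flagged, not corrected).
    """
    report = ValidationReport()
    df = panel.data

    dup = df["pid"][df["pid"].duplicated()].unique()
    if len(dup):
        report.violations.append(f"duplicate pids: {list(dup[:5])}")

    arms_per_clinic = df.groupby("clinic")["arm"].nunique()
    mixed = arms_per_clinic[arms_per_clinic > 1]
    if len(mixed):
        report.violations.append(
            f"clinics containing both arms (cluster randomization broken): {list(mixed.index[:5])}"
        )

    both_missing = df["stage_w2"].isna() & df["stage_w3"].isna()
    report.excluded_pids = df.loc[both_missing, "pid"].tolist()

    for wave in ("w2", "w3"):
        resp, stage = f"response_{wave}", f"stage_{wave}"
        if resp in df.columns:
            r = pd.to_numeric(df[resp], errors="coerce")
            both = r.notna() & df[stage].notna()
            expect = r[both].map(lambda v: int(collapse_stage(v)))
            bad = df.loc[both, "pid"][df.loc[both, stage].astype(int) != expect]
            if len(bad):
                report.violations.append(
                    f"{stage} disagrees with collapsed {resp} for pids {list(bad[:5])}"
                )

    regress = (df["stage_w2"] == int(Stage.ACTION)) & df["stage_w3"].notna() & (
        df["stage_w3"] != int(Stage.ACTION)
    )
    report.flagged_pids = df.loc[regress, "pid"].tolist()
    if len(report.flagged_pids):
        report.violations.append(
            f"records regress out of the absorbing action stage: pids {report.flagged_pids[:5]}"
        )
    return report


def exclude_both_missing(panel: StagePanel) -> StagePanel:
    """Return a panel without the records missing the stage at both waves."""
    keep = ~(panel.data["stage_w2"].isna() & panel.data["stage_w3"].isna())
    return StagePanel(panel.data.loc[keep].reset_index(drop=True))


def crosstab(panel: StagePanel, wave: str) -> pd.DataFrame:
    """Arm-by-stage counts of non-missing stages at ``wave``.

    Returns a 2x3 integer frame indexed by arm (0 = control,
    1 = intervention) with one column per stage; absent combinations are
    zero-filled. Row sums equal the per-arm observed n at that wave.
    """
    s = panel.stages(wave)
    ok = s.notna()
    tab = pd.crosstab(panel.data.loc[ok, "arm"], s[ok].astype(int))
    tab = tab.reindex(index=[0, 1], columns=[1, 2, 3], fill_value=0)
    tab.index.name = "arm"
    tab.columns = [Stage(c).name for c in tab.columns]
    return tab.astype(int)
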