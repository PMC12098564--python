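import numpy as np
import pandas as pd
import pytest

import stagetrans as st


@pytest.fixture(scope="session")
def published_panel() -> st.StagePanel:
    """Deterministic complete-data panel with the published W2 margins and
    transition proportions apportioned from the published matrices."""
    return st.published_table_panel()


@pytest.fixture(scope="session")
def published_fit(published_panel) -> st.MarkovFit:
    return st.fit(published_panel, st.MarkovSpec(mode="multigroup"), n_starts=3, seed=11)


@pytest.fixture(scope="session")
def published_fit_restrained(published_panel) -> st.MarkovFit:
    return st.fit(published_panel, st.MarkovSpec(mode="covariate"), n_starts=3, seed=11)


@pytest.fixture()
def mixed_missing_panel() -> st.StagePanel:
    """Tiny panel with every missingness pattern except both-missing."""
    df = pd.DataFrame(
        {
            "pid": [f"x{i}" for i in range(8)],
            "clinic": ["c1", "c1", "c2", "c2", "c3", "c3", "c4", "c4"],
            "arm": [0, 0, 0, 0, 1, 1, 1, 1],
            "stage_w2": pd.array([1, 2, None, 3, 1, None, 2, 1], dtype="Int64"),
            "stage_w3": pd.array([2, None, 3, 3, 1, 2, 2, 3], dtype="Int64"),
        }
    )
    return st.StagePanel(df)


@pytest.fixture(scope="session")
def empirical_matrices(published_panel):
    """Complete-case empirical per-arm transition matrices of the fixture."""
    df = published_panel.data
    out = {}
    for a in (0, 1):
        sub = df[df["arm"] == a]
        tab = pd.crosstab(sub["stage_w2"], sub["stage_w3"], normalize="index")
        out[a] = st.TransitionMatrix(tab.to_numpy())
    return out


def empirical_transition_matrix(panel: st.StagePanel, arm: int) -> np.ndarray:
    df = panel.data
    sub = df[(df["arm"] == arm) & df["stage_w2"].notna() & df["stage_w3"].notna()]
    return pd.crosstab(sub["stage_w2"], sub["stage_w3"], normalize="index").reindex(
        index=[1, 2, 3], columns=[1, 2, 3], fill_value=0.0
    ).to_numpy()
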