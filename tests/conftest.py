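"""Shared fixtures: synthetic cohorts and a trained model, built once."""

import numpy as np
import pandas as pd
import pytest

import stromatype as st


@pytest.fixture(scope="session")
def std_cfg():
    """Standard study conditions: 400 samples, 2-SD loadings, unit noise."""
    return st.SimConfig(n_samples=400, seed=7)


@pytest.fixture(scope="session")
def std_cohort(std_cfg):
    return st.simulate_cohort(std_cfg)


@pytest.fixture(scope="session")
def std_panel(std_cfg):
    return std_cfg.panel()


@pytest.fixture(scope="session")
def std_model(std_cohort, std_panel):
    expr, _, _ = std_cohort
    model, labels = st.train_from_raw(expr, std_panel, st.TrainConfig(seed=7))
    return model, labels


@pytest.fixture(scope="session")
def std_calls(std_model, std_cohort):
    model, _ = std_model
    expr, _, _ = std_cohort
    return st.classify_raw(model, expr)


def make_calls(probs: list[tuple[float, float, float, float]],
               sample_ids=None) -> st.SubtypeCalls:
    """Build SubtypeCalls directly from probability rows (A, IA, ID, IS)."""
    p = np.asarray(probs, dtype=float)
    ids = sample_ids or [f"s{i}" for i in range(len(p))]
    table = pd.DataFrame(
        {f"P_{c}": p[:, k] for k, c in enumerate(st.SUBTYPES)},
        index=pd.Index(ids, name="sample_id"),
    )
    idx = p.argmax(axis=1)
    table["subtype"] = [st.SUBTYPES[k] for k in idx]
    table["neuron1"] = 0.0
    table["neuron2"] = 0.0
    table["max_probability"] = p.max(axis=1)
    return st.SubtypeCalls(table)


def make_clinical(rows: dict[str, str], **extra_cols) -> st.CohortClinical:
    """Clinical table from {sample_id: bor} plus optional extra columns."""
    df = pd.DataFrame({"bor": pd.Series(rows)})
    df.index.name = "sample_id"
    for k, v in extra_cols.items():
        df[k] = pd.Series(v)
    return st.CohortClinical(df)
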