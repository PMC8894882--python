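"""Shared fixtures: tiny hand-built tables and a small synthetic cohort."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from morbinet.etl import build_event_stream
from morbinet.networks import BipartiteNetwork
from morbinet.synthetic import (
    GeneratorConfig,
    generate_cohort,
    generate_episodes,
    make_disease_model,
)


def make_patients(rows: list[dict]) -> pd.DataFrame:
    """Patient table from partial dicts; sensible defaults filled in."""
    defaults = {
        "gender": "F",
        "ethnicity": "White",
        "dob": "1970-06-15",
        "first_smi_code": "F20",
        "first_smi_date": "2010-01-01",
        "death_date": pd.NaT,
    }
    frame = pd.DataFrame([{**defaults, **r} for r in rows])
    for col in ("dob", "first_smi_date", "death_date"):
        frame[col] = pd.to_datetime(frame[col])
    return frame


def make_events(rows: list[tuple], patients: pd.DataFrame) -> pd.DataFrame:
    """Event stream from (patient_id, code3, date) triples."""
    smi = patients.set_index("patient_id")["first_smi_date"]
    frame = pd.DataFrame(rows, columns=["patient_id", "code3", "timestamp"])
    frame["timestamp"] = pd.to_datetime(frame["timestamp"])
    frame = frame.sort_values("timestamp", kind="stable").reset_index(drop=True)
    frame["episode_id"] = [f"E{i:03d}" for i in range(len(frame))]
    frame["within_episode_rank"] = 0
    frame["years_to_smi"] = (
        frame["timestamp"] - frame["patient_id"].map(smi)
    ).dt.days / 365.25
    return frame


def net_from_edges(
    edges: list[tuple], patient_attrs: dict | None = None
) -> BipartiteNetwork:
    """Bipartite network straight from (patient, disease) pairs."""
    g = nx.Graph()
    patient_attrs = patient_attrs or {}
    for p, d in edges:
        if p not in g:
            g.add_node(p, kind="patient", bipartite=0,
                       **patient_attrs.get(p, {}))
        if d not in g:
            g.add_node(d, kind="disease", bipartite=1)
        if g.has_edge(p, d):
            g[p][d]["weight"] += 1
        else:
            g.add_edge(p, d, weight=1, first_age=40)
    return BipartiteNetwork(graph=g, window=(None, None), label="TEST")


def random_bipartite(rng: np.random.Generator, n_p=8, n_d=8, p=0.3):
    """Random simple bipartite network with no isolated nodes."""
    edges = [
        (f"p{i}", f"d{j}")
        for i in range(n_p)
        for j in range(n_d)
        if rng.random() < p
    ]
    if not edges:
        edges = [("p0", "d0"), ("p1", "d1")]
    return net_from_edges(edges)


@pytest.fixture(scope="session")
def small_cohort():
    """200-patient default-condition cohort shared by read-only tests."""
    config = GeneratorConfig(n_patients=200, seed=11)
    patients = generate_cohort(config)
    model = make_disease_model(config)
    episodes = generate_episodes(patients, config, model)
    events = build_event_stream(episodes, patients)
    return config, patients, model, episodes, events
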