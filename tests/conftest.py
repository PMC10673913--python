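import dataclasses

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import ccnet

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-participant cohort from the default generative law (fast)."""
    spec = ccnet.default_cohort_spec(n_participants=400, seed=11)
    return ccnet.generate_cohort(spec)


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size (1500 × 40) cohort for integration-level checks."""
    spec = ccnet.default_cohort_spec(seed=5)
    return ccnet.generate_cohort(spec)


@pytest.fixture()
def fast_config():
    return ccnet.RunConfig(n_repeats=25, seed=7)


@pytest.fixture()
def fast_edge_config():
    return ccnet.EdgeValidationConfig(n_repeats=25, seed=7)


def random_graph(n_nodes: int, p: float, seed: int) -> nx.Graph:
    """Erdős–Rényi graph with string node names (deterministic)."""
    rng = np.random.default_rng(seed)
    nodes = [f"n{i}" for i in range(n_nodes)]
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p:
                graph.add_edge(nodes[i], nodes[j])
    return graph


def intake_frame(values, columns=None) -> pd.DataFrame:
    arr = np.asarray(values, dtype=float)
    columns = columns or [f"g{i}" for i in range(arr.shape[1])]
    index = pd.Index([f"p{i}" for i in range(arr.shape[0])], name="id")
    return pd.DataFrame(arr, index=index, columns=columns)


def replace_config(cfg, **kw):
    return dataclasses.replace(cfg, **kw)
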