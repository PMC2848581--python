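import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from cardionet import ExpressionDataset, SynthConfig, generate_expression, generate_interactions


def make_dataset(values, flags, platform="A", reference="baseline"):
    """Small ExpressionDataset from dicts gene -> list of per-sample values.

    Samples are named progenitor_r1..r{n} then baseline_r1..r{n}.
    """
    genes = list(values)
    n = len(next(iter(values.values())))
    half = n // 2
    samples = [f"progenitor_r{i+1}" for i in range(half)] + [
        f"baseline_r{i+1}" for i in range(n - half)
    ]
    conditions = {s: ("progenitor" if s.startswith("progenitor") else "baseline") for s in samples}
    return ExpressionDataset(
        platform=platform,
        values=pd.DataFrame([values[g] for g in genes], index=genes, columns=samples, dtype=float),
        flags=pd.DataFrame([flags[g] for g in genes], index=genes, columns=samples),
        conditions=conditions,
        reference=reference,
    )


@pytest.fixture(scope="session")
def small_config():
    """A compact planted configuration used across the suite."""
    return SynthConfig(
        n_conserved_up=20,
        n_conserved_down=30,
        n_platform_specific=15,
        n_background=200,
        n_network_nodes=120,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    ds_a, ds_b, truth = generate_expression(small_config)
    db = generate_interactions(small_config, truth)
    return ds_a, ds_b, db, truth


def random_graph(rng, n_max=25, p=0.3):
    """Random simple undirected graph as (nodes, edges) with string labels."""
    n = int(rng.integers(2, n_max + 1))
    nodes = [f"v{i}" for i in range(n)]
    edges = [
        (nodes[i], nodes[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    return nodes, edges
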