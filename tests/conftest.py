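import warnings

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import menconserve as mc


@pytest.fixture(scope="session")
def metadata():
    return mc.generate_metadata(n_samples=40, ph_min=1.86, ph_max=4.10, seed=7)


@pytest.fixture(scope="session")
def grouping(metadata):
    return mc.assign_ph_groups(metadata, n_groups=6)


@pytest.fixture(scope="session")
def trait_table(metadata):
    return mc.generate_layer(
        metadata,
        n_features=80,
        archetype_weights=mc.TRAIT_PRESET,
        layer="trait",
        seed=7,
    )


def net_from_edges(edges, layer="test", group="G1"):
    """Build a CorrelationNetwork from a plain edge list (weight 1)."""
    g = nx.Graph()
    for a, b in edges:
        g.add_edge(a, b, weight=1.0)
    return mc.CorrelationNetwork(layer=layer, group=group, graph=g, threshold=0.5)


@pytest.fixture
def quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield
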