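import numpy as np
import pandas as pd
import pytest

from riverscape import (CrossSection, FuzzySystem, Hydrograph,
                        MembershipFunction, RiverNetworkGraph, Rule)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def rect_section():
    """Rectangular channel: B=10 m, banks 1 m high, n=0.05, S=0.001."""
    return CrossSection(stations=[0.0, 0.0, 10.0, 10.0],
                        elevations=[1.0, 0.0, 0.0, 1.0],
                        n_manning=0.05, slope=0.001)


@pytest.fixture
def simple_system():
    """Single-rule system: any flow -> output triangle (0.5, 1, 1)."""
    anywhere = MembershipFunction(0, 0, 10, 10)
    return FuzzySystem(
        variables={"velocity": {"any": anywhere}, "depth": {"any": anywhere}},
        output={"high": MembershipFunction(0.5, 1.0, 1.0, 1.0)},
        rules=[Rule({"velocity": "any", "depth": "any"}, "high")],
    )


def make_hydrograph(q, start="2020-01-01"):
    q = np.asarray(q, dtype=float)
    return Hydrograph(pd.date_range(start, periods=len(q), freq="D"), q)


def line_network(length=1000.0, dx=10.0, barriers=()):
    """Single straight reach oriented downstream from node 1 to node 0."""
    return RiverNetworkGraph([(1, 0, length)], dx=dx, barriers=list(barriers))


def random_tree_network(rng, n_reaches=8, dx=25.0, barriers=()):
    """Random dendritic network; node 0 is the outlet."""
    edges = []
    for i in range(1, n_reaches + 1):
        parent = int(rng.integers(0, i))
        length = float(rng.uniform(200, 800))
        edges.append((i, parent, length))
    return RiverNetworkGraph(edges, dx=dx, barriers=list(barriers))
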