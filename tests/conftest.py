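import datetime as dt

import numpy as np
import pytest

from phenonet import InteractionRecord, FloweringCensusRecord, WeightedBipartiteNetwork


def rec(day, plant, visitor, visits, site="NEV", fg="Bees"):
    return InteractionRecord(
        census_date=dt.date(2017, 6, day) if day <= 30 else dt.date(2017, 7, day - 30),
        site=site,
        plant=plant,
        visitor=visitor,
        functional_group=fg,
        visits=visits,
    )


def flow(day, plant, n, site="NEV"):
    return FloweringCensusRecord(
        census_date=dt.date(2017, 6, day) if day <= 30 else dt.date(2017, 7, day - 30),
        site=site,
        plant=plant,
        n_flowering=n,
    )


@pytest.fixture
def small_records():
    """Three census days, partial species turnover between days."""
    return [
        rec(14, "p1", "v1", 2),
        rec(14, "p1", "v1", 3),
        rec(14, "p2", "v2", 1),
        rec(18, "p1", "v2", 4),
        rec(18, "p2", "v2", 2),
        rec(25, "p3", "v3", 1),
    ]


@pytest.fixture
def two_block_network():
    """2 plants + 2 visitors per block, within-block weight 3, between 0."""
    A = np.array(
        [
            [3, 3, 0, 0],
            [3, 3, 0, 0],
            [0, 0, 3, 3],
            [0, 0, 3, 3],
        ],
        dtype=np.int64,
    )
    return WeightedBipartiteNetwork(
        ("p1", "p2", "p3", "p4"), ("v1", "v2", "v3", "v4"), A, label="two-block"
    )


def make_net(A, label="net", date=None):
    A = np.asarray(A, dtype=np.int64)
    plants = tuple(f"p{i}" for i in range(A.shape[0]))
    visitors = tuple(f"v{j}" for j in range(A.shape[1]))
    return WeightedBipartiteNetwork(plants, visitors, A, label=label, date=date)


def random_net(rng, n_plants=4, n_visitors=4, max_w=5):
    """Random weighted bipartite network with no empty rows/columns."""
    while True:
        A = rng.integers(0, max_w + 1, size=(n_plants, n_visitors))
        if (A.sum(axis=1) > 0).all() and (A.sum(axis=0) > 0).all():
            return make_net(A)
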