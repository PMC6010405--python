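import numpy as np
import pytest
from scipy import stats

from phenonet import (
    BipartiteModularity,
    NullModelResult,
    maximize_modularity,
    modularity_q,
    modularity_significance,
    null_networks,
)

from conftest import make_net, random_net


# ---------------------------------------------------------------------------
# independent oracle: exhaustive enumeration over all set partitions

def set_partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + [first]] + part[i + 1 :]
        yield part + [[first]]


def brute_force_q(net):
    best = -np.inf
    for part in set_partitions(list(net.species)):
        assignment = {s: g for g, block in enumerate(part) for s in block}
        best = max(best, modularity_q(net, assignment))
    return best


# ---------------------------------------------------------------------------
# objective

def test_single_module_q_is_zero_exactly():
    rng = np.random.default_rng(0)
    for _ in range(25):
        net = random_net(rng, 3, 4)
        assignment = {s: 0 for s in net.species}
        assert modularity_q(net, assignment) == 0.0


def test_two_by_two_hand_values():
    net = make_net([[1, 0], [0, 1]])
    aligned = {"p0": 0, "v0": 0, "p1": 1, "v1": 1}
    crossed = {"p0": 0, "v0": 1, "p1": 1, "v1": 0}
    assert modularity_q(net, aligned) == pytest.approx(0.5)
    assert modularity_q(net, crossed) == pytest.approx(-0.5)


def test_missing_species_is_error():
    net = make_net([[1, 0], [0, 1]])
    with pytest.raises(KeyError):
        modularity_q(net, {"p0": 0, "v0": 0, "p1": 0})


def test_q_at_most_one():
    rng = np.random.default_rng(5)
    for _ in range(10):
        net = random_net(rng, 3, 3)
        for _ in range(20):
            assignment = {s: int(rng.integers(0, 4)) for s in net.species}
            assert modularity_q(net, assignment) <= 1.0


# ---------------------------------------------------------------------------
# maximizer

def test_two_block_network_recovers_blocks(two_block_network):
    part = maximize_modularity(two_block_network, n_runs=20, seed=0)
    assert part.n_modules == 2
    a = part.assignment
    assert a["p1"] == a["p2"] == a["v1"] == a["v2"]
    assert a["p3"] == a["p4"] == a["v3"] == a["v4"]
    assert a["p1"] != a["p3"]
    assert part.q == pytest.approx(brute_force_q(two_block_network), abs=1e-12)
    assert part.q == max(part.run_scores)


def test_uniform_network_has_near_zero_optimum():
    net = make_net(np.ones((3, 3), dtype=np.int64))
    assert brute_force_q(net) <= 0.05
    part = maximize_modularity(net, n_runs=20, seed=1)
    assert part.q <= brute_force_q(net) + 1e-12


def test_maximizer_is_deterministic_given_seed():
    rng = np.random.default_rng(11)
    net = random_net(rng, 5, 5, max_w=4)
    a = maximize_modularity(net, n_runs=10, seed=123)
    b = maximize_modularity(net, n_runs=10, seed=123)
    assert a == b
    assert a.q >= 0  # search includes single-module-equivalent candidates


def test_degenerate_one_by_one_network():
    net = make_net([[4]])
    part = maximize_modularity(net, n_runs=3, seed=0)
    assert part.n_modules == 1 and part.q == 0.0


def test_maximizer_attains_enumeration_optimum_on_random_nets():
    rng = np.random.default_rng(99)
    for _ in range(5):
        net = random_net(rng, 3, 3, max_w=4)
        opt = brute_force_q(net)
        part = maximize_modularity(net, n_runs=30, seed=int(rng.integers(2**31)))
        assert part.q == pytest.approx(opt, abs=1e-10)


# ---------------------------------------------------------------------------
# null models

def test_marginal_nulls_preserve_margins_exactly(two_block_network):
    net = two_block_network
    for null in null_networks(net, n=50, seed=0):
        assert np.array_equal(null.k, net.k)
        assert np.array_equal(null.d, net.d)
        assert null.F == net.F


def test_one_by_one_nulls_identical_to_observation():
    net = make_net([[4]])
    for null in null_networks(net, n=5, seed=0):
        assert np.array_equal(null.weights, net.weights)


def test_two_by_two_nulls_lie_in_margin_fiber():
    # margins k=(2,2), d=(2,2): enumerable fiber A = [[x, 2-x], [2-x, x]]
    net = make_net([[2, 0], [0, 2]])
    fiber = {(x, 2 - x, 2 - x, x) for x in range(3)}
    seen = set()
    for null in null_networks(net, n=200, seed=1):
        flat = tuple(int(v) for v in null.weights.ravel())
        assert flat in fiber
        seen.add(flat)
    assert len(seen) == 3  # sampler reaches the whole fiber


def test_binary_degree_null_preserves_binary_degrees_and_weights():
    rng = np.random.default_rng(2)
    net = random_net(rng, 5, 6, max_w=4)
    B = net.weights > 0
    for null in null_networks(net, n=20, seed=3, model="binary-degree"):
        Bn = null.weights > 0
        assert np.array_equal(Bn.sum(axis=1), B.sum(axis=1))
        assert np.array_equal(Bn.sum(axis=0), B.sum(axis=0))
        assert sorted(null.weights[Bn].tolist()) == sorted(net.weights[B].tolist())


# ---------------------------------------------------------------------------
# significance

def test_z_and_p_hand_arithmetic():
    # null Qs {0.15, 0.20, 0.25}: mean 0.20, sd 0.05 -> z = 2.8
    res = NullModelResult(q_obs=0.34, null_qs=(0.15, 0.20, 0.25), n_null=3)
    assert res.z == pytest.approx(2.8)
    assert res.p_value == pytest.approx(2 * stats.norm.sf(2.8))
    assert res.p_value == pytest.approx(0.0051, abs=5e-4)


def test_zero_null_variance_is_error():
    with pytest.raises(ValueError, match="variance"):
        NullModelResult(q_obs=0.3, null_qs=(0.2, 0.2, 0.2), n_null=3)


def test_two_block_structure_is_significant(two_block_network):
    n_sig = 0
    n_reps = 20
    for seed in range(n_reps):
        _, null = modularity_significance(
            two_block_network, n_runs=8, n_null=20, seed=seed, sweeps=20
        )
        if null.p_value < 0.05:
            n_sig += 1
    assert n_sig >= 0.95 * n_reps


def test_results_object_summary_and_frame(two_block_network):
    res = BipartiteModularity(two_block_network).fit_significance(
        n_runs=8, n_null=10, seed=4, sweeps=20
    )
    text = res.summary()
    assert "Q =" in text and "Z =" in text
    df = res.to_frame()
    assert set(df.columns) == {"species", "guild", "module", "module_rank"}
    assert len(df) == 8
    assert df["module"].nunique() == res.n_modules
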