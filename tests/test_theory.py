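import numpy as np
import pytest

from singlefile import (
    ParameterError,
    Partition,
    SimulationParams,
    empirical_between_weight,
    expected_between_weight,
    generate_population,
    merge_modularity_delta,
    modularity,
    run_single_simulation,
    serialize,
    sufficient_condition_bound,
)
from singlefile.network import AggregateGraph, aggregate_movements
from conftest import random_partition_labels, random_weighted_graph


def graph_from_edges(n, edges):
    w = np.zeros((n, n), dtype=np.int64)
    for i, j, wt in edges:
        w[i - 1, j - 1] += wt
        w[j - 1, i - 1] += wt
    return AggregateGraph(weights=w)


def merged(partition, p, q):
    labels = partition.labels.copy()
    labels[labels == q] = p
    return Partition.from_labels(labels)


def test_merge_delta_two_triangles():
    g = graph_from_edges(
        6, [(1, 2, 1), (2, 3, 1), (1, 3, 1), (4, 5, 1), (5, 6, 1), (4, 6, 1)]
    )
    part = Partition.from_labels([1, 1, 1, 2, 2, 2])
    d = merge_modularity_delta(g, part, 1, 2)
    assert (d.m, d.K_p, d.K_q, d.M) == (0.0, 6.0, 6.0, 6.0)
    assert d.delta == pytest.approx(-0.5)


def test_merge_delta_two_node_pair():
    g = graph_from_edges(2, [(1, 2, 1)])
    part = Partition.from_labels([1, 2])
    d = merge_modularity_delta(g, part, 1, 2)
    assert d.delta == pytest.approx(0.5)  # 1/1 - 1/(2*1)


def test_merge_delta_errors():
    g = graph_from_edges(2, [(1, 2, 1)])
    part = Partition.from_labels([1, 2])
    with pytest.raises(ParameterError):
        merge_modularity_delta(g, part, 1, 1)
    with pytest.raises(ParameterError):
        merge_modularity_delta(g, part, 1, 5)


def test_merge_delta_equals_direct_difference(rng):
    # closed form vs direct modularity differencing on random graphs
    for _ in range(30):
        n = int(rng.integers(4, 21))
        g = random_weighted_graph(rng, n)
        k = int(rng.integers(2, min(n, 5) + 1))
        part = Partition.from_labels(random_partition_labels(rng, n, k))
        labs = np.unique(part.labels)
        for p in labs:
            for q in labs:
                if p >= q:
                    continue
                d = merge_modularity_delta(g, part, int(p), int(q))
                direct = modularity(g, merged(part, p, q)) - modularity(g, part)
                assert abs(d.delta - direct) < 1e-12


def test_expected_between_weight_values():
    e = expected_between_weight(10, 30)
    assert e.as_printed == pytest.approx(3.0)
    assert e.enumeration == pytest.approx(6.0)
    # n_I=2: the unique pair of blocks is adjacent in every movement
    e2 = expected_between_weight(2, 10)
    assert e2.enumeration == pytest.approx(10.0)
    assert e2.as_printed == pytest.approx(5.0)
    with pytest.raises(ParameterError):
        expected_between_weight(1, 10)


@pytest.mark.parametrize("n_I", [2, 3, 4, 5, 6])
def test_enumeration_matches_symmetry_closed_form(n_I):
    # P(two given blocks adjacent in a uniform ordering) = 2/n_I
    e = expected_between_weight(n_I, 7)
    assert e.enumeration == pytest.approx(2 * 7 / n_I)


def test_sufficient_condition_bound_values():
    rep = sufficient_condition_bound(
        SimulationParams(n_I=10, n_D=5, sigma_I=10.0, n_exp=30)
    )
    assert rep.M == 1770
    assert rep.bound == pytest.approx(22500 / 3540)
    assert rep.prefactor == pytest.approx(2.5 * 5 / 5.9)
    assert rep.holds_as_printed and rep.holds_enumeration
    zero = sufficient_condition_bound(
        SimulationParams(n_I=3, n_D=0, sigma_I=1.0, n_exp=5)
    )
    assert zero.bound == 0.0 and zero.prefactor == 0.0


def test_empirical_between_weight_hand_graph():
    # two 2-agent subgroups with one unit crossing edge
    params = SimulationParams(n_I=2, n_D=1, sigma_I=1.0)
    pop = generate_population(params, np.random.default_rng(0))
    # IDs: 1,2 independenters; 3 dep of 1; 4 dep of 2 -> subgroups {1,3},{2,4}
    g = graph_from_edges(4, [(1, 3, 2), (2, 4, 3), (1, 2, 1)])
    m, K_p, K_q = empirical_between_weight(g, pop, 1, 2)
    assert m == 1.0
    assert K_p == 2 * 2 + 1 and K_q == 2 * 3 + 1
    no_cross = graph_from_edges(4, [(1, 3, 2), (2, 4, 3)])
    assert empirical_between_weight(no_cross, pop, 1, 2)[0] == 0.0
    with pytest.raises(ParameterError):
        empirical_between_weight(g, pop, 1, 1)


def test_mean_between_weight_matches_enumeration():
    # separated regime: measured m averaged over simulated runs matches the
    # exhaustive block-ordering expectation 2 n_exp / n_I
    params = SimulationParams(n_I=3, n_D=3, sigma_I=1e6, n_exp=10)
    rng = np.random.default_rng(8)
    expect = expected_between_weight(3, 10).enumeration
    ms = []
    for _ in range(1500):
        pop = generate_population(params, rng)
        movements = [serialize(generate_population(params, rng), rng) for _ in range(10)]
        g = aggregate_movements(movements)
        ms.append(empirical_between_weight(g, pop, 1, 2)[0])
    # per-movement pair adjacency is Bernoulli(2/3): SE ~ sqrt(10*2/9)/sqrt(1500)
    assert abs(np.mean(ms) - expect) < 0.15


def test_true_partition_beats_single_merges_in_separated_regime():
    params = SimulationParams(n_I=4, n_D=4, sigma_I=1e6, n_exp=20)
    rec = run_single_simulation(params, np.random.default_rng(2), keep_artifacts=True)
    pop = rec.populations[0]
    true_part = Partition.from_labels(pop.subgroup)
    for p in range(1, 5):
        for q in range(p + 1, 5):
            m, K_p, K_q = empirical_between_weight(rec.graph, pop, p, q)
            if m < K_p * K_q / (2 * rec.graph.M):
                d = merge_modularity_delta(rec.graph, true_part, p, q)
                assert d.delta < 0
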