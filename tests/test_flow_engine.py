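import math

import networkx as nx
import numpy as np
import pytest

from wardflow import (
    ArrivalProfile,
    AugmentingPath,
    RunConfig,
    augment,
    dfs_find_path,
    make_constant_service,
    path_bottleneck,
    run_simulation,
    run_time_step,
)
from wardflow.capacity_adjust import StaticResidualGraph, build_static_residual, compute_vertex_loads
from wardflow.flow_engine import DynamicResidualGraph, POSITIVE_EPS, write_result
from wardflow.synthetic_hospital import fitted_toy_distributions


def srg(residuals):
    return StaticResidualGraph(dict(residuals))


def random_residual_graph(rng, n=8):
    """A random digraph on Source, W1..Wn-2, Sink with signed residuals."""
    names = ["Source"] + [f"W{i}" for i in range(1, n - 1)] + ["Sink"]
    residuals = {}
    for i, u in enumerate(names):
        for v in names[i + 1 :]:
            if rng.random() < 0.35:
                residuals[(u, v)] = float(rng.uniform(-5, 5))
    return names, residuals


class TestDfsFindPath:
    def test_positive_chain_found(self):
        res = srg({("Source", "A", ): 3.0, ("A", "Sink"): 2.0})
        path = dfs_find_path(res, "Source", "Sink")
        assert path is not None
        assert path.wards == ("Source", "A", "Sink")
        assert path.bottleneck == 2.0

    def test_blocked_middle_edge_none(self):
        res = srg({("Source", "A"): 3.0, ("A", "Sink"): 0.0})
        assert dfs_find_path(res, "Source", "Sink") is None

    def test_negative_residual_blocks(self):
        res = srg({("Source", "A"): 3.0, ("A", "Sink"): -2.0})
        assert dfs_find_path(res, "Source", "Sink") is None

    def test_detour_found_when_direct_blocked(self):
        res = srg({
            ("Source", "A"): 3.0,
            ("A", "Sink"): -1.0,
            ("A", "B"): 2.0,
            ("B", "Sink"): 4.0,
        })
        path = dfs_find_path(res, "Source", "Sink")
        assert path.wards == ("Source", "A", "B", "Sink")

    def test_simple_paths_terminate_on_cycles(self):
        res = srg({
            ("Source", "A"): 1.0,
            ("A", "B"): 1.0,
            ("B", "A"): 1.0,   # cycle
            ("B", "Sink"): -1.0,
        })
        assert dfs_find_path(res, "Source", "Sink") is None

    def test_unknown_source_raises(self):
        res = srg({("A", "Sink"): 1.0})
        with pytest.raises(KeyError):
            dfs_find_path(res, "Nope", "Sink", adjacency={"A": [("A", "Sink")]})

    def test_source_without_out_edges_unreachable(self):
        res = srg({("A", "Sink"): 1.0})
        assert dfs_find_path(res, "Source", "Sink") is None

    def test_reachability_oracle_small_graphs(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            _, residuals = random_residual_graph(rng, n=8)
            res = srg(residuals)
            found = dfs_find_path(res, "Source", "Sink")
            g = nx.DiGraph(
                (u, v) for (u, v), c in residuals.items() if c > POSITIVE_EPS
            )
            reachable = (
                g.has_node("Source") and g.has_node("Sink")
                and nx.has_path(g, "Source", "Sink")
            )
            assert (found is not None) == reachable


class TestBottleneckAndAugment:
    def test_bottleneck_is_min(self):
        res = srg({("S", "A"): 3.0, ("A", "B"): 7.0, ("B", "T"): 2.0})
        path = AugmentingPath(("S", "A", "B", "T"), 2.0)
        assert path_bottleneck(res, path) == 2.0

    def test_single_edge(self):
        res = srg({("S", "T"): 5.0})
        assert path_bottleneck(res, AugmentingPath(("S", "T"), 5.0)) == 5.0

    def test_empty_path_rejected(self):
        res = srg({("S", "T"): 5.0})
        with pytest.raises(ValueError):
            path_bottleneck(res, AugmentingPath(("S",), 0.0))

    def test_augment_elementwise_subtraction(self):
        res = srg({("S", "A"): 3.0, ("A", "B"): 7.0, ("B", "T"): 2.0})
        path = AugmentingPath(("S", "A", "B", "T"), 2.0)
        augment(res, path, 2.0)
        assert res.residuals[("S", "A")] == 1.0
        assert res.residuals[("A", "B")] == 5.0
        assert res.residuals[("B", "T")] == 0.0

    def test_no_backward_edges_created(self):
        res = srg({("S", "A"): 3.0, ("A", "T"): 3.0})
        augment(res, AugmentingPath(("S", "A", "T"), 3.0), 3.0)
        assert set(res.residuals) == {("S", "A"), ("A", "T")}

    def test_zero_amount_rejected(self):
        res = srg({("S", "T"): 5.0})
        with pytest.raises(ValueError):
            augment(res, AugmentingPath(("S", "T"), 5.0), 0.0)

    def test_amount_above_bottleneck_rejected(self):
        res = srg({("S", "T"): 5.0})
        with pytest.raises(ValueError):
            augment(res, AugmentingPath(("S", "T"), 5.0), 6.0)

    def test_random_paths_against_brute_min(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            k = rng.integers(2, 7)
            wards = tuple(f"N{i}" for i in range(k))
            values = rng.uniform(0.1, 9.0, k - 1)
            res = srg({e: float(v) for e, v in zip(zip(wards, wards[1:]), values)})
            path = AugmentingPath(wards, float(values.min()))
            assert path_bottleneck(res, path) == pytest.approx(float(values.min()))


class TestRunTimeStep:
    def test_unloaded_chain_pushes_min_capacity(self, chain_network):
        # r=0: residuals Source->A = 5+10 = 15, A->Sink = 5; one path of 5,
        # then A->Sink is exhausted
        loads = compute_vertex_loads(chain_network, 0.0, {"A": 1.0})
        res = build_static_residual(chain_network, 0.0, loads)
        step = run_time_step(chain_network, res, 0.0, {"A": 1.0})
        assert step.total_flow == pytest.approx(5.0)
        assert len(step.paths) == 1
        assert res.residuals[("A", "Sink")] == pytest.approx(0.0)

    def test_blocked_source_edges_zero_flow(self, chain_network):
        res = srg({("Source", "A"): -3.0, ("A", "Sink"): 5.0})
        step = run_time_step(chain_network, res, 1.0, {"A": 1.0})
        assert step.paths == []
        assert step.total_flow == 0.0

    def test_total_flow_is_sum_of_bottlenecks(self, toy_hospital):
        s_times = {w.name: 5.01 for w in toy_hospital.interior_wards}
        loads = compute_vertex_loads(toy_hospital, 1.0, s_times)
        res = build_static_residual(toy_hospital, 1.0, loads)
        step = run_time_step(toy_hospital, res, 1.0, s_times)
        assert step.total_flow == pytest.approx(sum(p.bottleneck for p in step.paths))
        assert all(p.bottleneck > 0 for p in step.paths)

    def test_augmentation_cap_respected(self, toy_hospital):
        s_times = {w.name: 5.01 for w in toy_hospital.interior_wards}
        loads = compute_vertex_loads(toy_hospital, 1.0, s_times)
        res = build_static_residual(toy_hospital, 1.0, loads)
        config = RunConfig(max_augmentations_per_step=2)
        step = run_time_step(toy_hospital, res, 1.0, s_times, config)
        assert len(step.paths) <= 2

    def test_forward_only_bounded_by_classical_max_flow(self):
        # on random small DAGs, forward-only pushed flow never exceeds the
        # classical max-flow (which also exploits backward residuals)
        from conftest import sentinel_ward
        from wardflow import build_network
        from wardflow.network_model import Ward, CarePathway

        rng = np.random.default_rng(21)
        for _ in range(100):
            names, residuals = random_residual_graph(rng, n=7)
            residuals = {e: abs(c) for e, c in residuals.items()}
            g = nx.DiGraph()
            g.add_nodes_from(names)
            for (u, v), c in residuals.items():
                g.add_edge(u, v, capacity=c)
            if not (nx.has_path(g, "Source", "Sink") if "Sink" in g and "Source" in g else False):
                continue
            maxflow = nx.maximum_flow_value(g, "Source", "Sink")
            wards = [sentinel_ward(n) if n in ("Source", "Sink") else Ward(n, 5, 5)
                     for n in names]
            edges = [CarePathway(u, v, 5.0, 0.5) for (u, v) in residuals]
            net = build_network(wards, edges, "Source", "Sink", validate=False)
            res = srg(residuals)
            step = run_time_step(net, res, 0.0, {})
            assert step.total_flow <= maxflow + 1e-9

    def test_single_path_network_equals_max_flow(self, three_chain_network):
        residuals = {("Source", "A"): 5.0, ("A", "B"): 3.0, ("B", "Sink"): 7.0}
        res = srg(residuals)
        step = run_time_step(three_chain_network, res, 0.0, {})
        g = nx.DiGraph()
        for (u, v), c in residuals.items():
            g.add_edge(u, v, capacity=c)
        assert step.total_flow == pytest.approx(
            nx.maximum_flow_value(g, "Source", "Sink")
        )


class TestDynamicRecords:
    def test_dynrg_initialized_at_infinities(self):
        dynrg = DynamicResidualGraph.empty([("a", "b")])
        assert dynrg.min_cap[("a", "b")] == math.inf
        assert dynrg.max_cap[("a", "b")] == -math.inf

    def test_running_extrema_match_brute_force(self):
        rng = np.random.default_rng(3)
        edges = [("a", "b"), ("b", "c")]
        dynrg = DynamicResidualGraph.empty(edges)
        history = {e: [] for e in edges}
        for _ in range(50):
            obs = {e: float(rng.uniform(-10, 10)) for e in edges}
            for e, v in obs.items():
                history[e].append(v)
            dynrg.observe(obs)
        for e in edges:
            assert dynrg.min_cap[e] == min(history[e])
            assert dynrg.max_cap[e] == max(history[e])
            assert dynrg.mean_cap()[e] == pytest.approx(np.mean(history[e]))

    def test_two_step_example(self):
        dynrg = DynamicResidualGraph.empty([("u", "v")])
        dynrg.observe({("u", "v"): 4.0})
        dynrg.observe({("u", "v"): 1.0})
        assert dynrg.min_cap[("u", "v")] == 1.0
        assert dynrg.max_cap[("u", "v")] == 4.0


class TestRunSimulation:
    def test_deterministic_with_seed(self, toy_hospital, spike_profile):
        dists = fitted_toy_distributions(toy_hospital)
        a = run_simulation(toy_hospital, spike_profile, dists, seed=3)
        b = run_simulation(toy_hospital, spike_profile, dists, seed=3)
        assert a.dynv == b.dynv
        assert a.dynrg.min_cap == b.dynrg.min_cap
        assert a.dynrg.max_cap == b.dynrg.max_cap
        assert a.path_log == b.path_log

    def test_constant_service_deterministic_anyway(self, toy_hospital, spike_profile,
                                                   constant_5_01):
        a = run_simulation(toy_hospital, spike_profile, constant_5_01, seed=1)
        b = run_simulation(toy_hospital, spike_profile, constant_5_01, seed=99)
        assert a.dynv == b.dynv  # constant distributions ignore the stream

    def test_single_step_equals_run_time_step(self, chain_network):
        dists = make_constant_service(chain_network, 1.0)
        result = run_simulation(
            chain_network, ArrivalProfile((0.0,)), dists, seed=0
        )
        loads = compute_vertex_loads(chain_network, 0.0, {"A": 1.0})
        res = build_static_residual(chain_network, 0.0, loads)
        step = run_time_step(chain_network, res, 0.0, {"A": 1.0})
        assert result.total_flow == pytest.approx(step.total_flow)
        assert result.dynv["A"][0] == pytest.approx(
            res.residuals[("Source", "A")]
        )

    def test_dynrg_brackets_every_dynv_observation(self, toy_hospital, spike_profile):
        dists = fitted_toy_distributions(toy_hospital)
        result = run_simulation(toy_hospital, spike_profile, dists, seed=2)
        for (u, v) in result.dynrg.edges:
            assert result.dynrg.min_cap[(u, v)] <= result.dynrg.max_cap[(u, v)]

    def test_dynv_length_equals_steps(self, toy_hospital, spike_profile, constant_5_01):
        result = run_simulation(toy_hospital, spike_profile, constant_5_01, seed=0)
        assert all(len(s) == spike_profile.t_max for s in result.dynv.values())

    def test_missing_distribution_rejected(self, toy_hospital, spike_profile):
        with pytest.raises(ValueError, match="distribution"):
            run_simulation(toy_hospital, spike_profile, {}, seed=0)

    def test_path_log_disabled(self, toy_hospital, spike_profile, constant_5_01):
        config = RunConfig(keep_path_log=False)
        result = run_simulation(
            toy_hospital, spike_profile, constant_5_01, config, seed=0
        )
        assert result.path_log == []
        assert result.total_flow > 0

    def test_year_horizon_smoke(self, toy_hospital, constant_5_01, spike_profile):
        # 365 repeats of the daily profile, path log off: bounded runtime
        profile = spike_profile.repeat(365)
        config = RunConfig(keep_path_log=False)
        result = run_simulation(
            toy_hospital, profile, constant_5_01, config, seed=0
        )
        assert result.steps == 24 * 365

    def test_write_result_files(self, toy_hospital, spike_profile, constant_5_01, tmp_path):
        result = run_simulation(toy_hospital, spike_profile, constant_5_01, seed=0)
        write_result(result, tmp_path)
        for name in ("dynrg.csv", "dynv.csv", "paths.jsonl", "manifest.json",
                     "edge_means.csv"):
            assert (tmp_path / name).exists()
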