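"""Forward polymer assembly: pool steps, joint assembly spaces, experiments."""

import numpy as np
import pytest

from assemblykit.simulate import (
    AssemblyPool,
    SimulationConfig,
    exploration_ratio,
    joint_assembly_space,
    run_experiment,
    run_single,
    step_directed,
    step_undirected,
)


class TestSteps:
    def test_monomer_pool_must_double(self, rng):
        pool = AssemblyPool()
        step_undirected(pool, rng)
        assert pool.members == {1, 2}

    def test_undirected_growth_is_bounded(self, rng):
        pool = AssemblyPool()
        pool.add(2)
        before = set(pool.members)
        step_undirected(pool, rng)
        assert before <= pool.members <= {1, 2, 3, 4}
        assert len(pool.members) <= len(before) + 1

    def test_pool_size_bound_after_steps(self, rng):
        pool = AssemblyPool()
        for _ in range(300):
            step_undirected(pool, rng)
        assert len(pool.members) <= 301
        assert max(pool.members) <= 2**300

    def test_directed_first_step(self, rng):
        pool = AssemblyPool()
        step_directed(pool, rng)
        assert pool.members == {1, 2} and pool.most_recent == 2

    def test_directed_second_step_adds_3_or_4(self, rng):
        pool = AssemblyPool()
        step_directed(pool, rng)
        step_directed(pool, rng)
        assert pool.members - {1, 2} <= {3, 4} and len(pool.members) == 3

    def test_directed_doubling_bound(self, rng):
        pool = AssemblyPool()
        for _ in range(50):
            step_directed(pool, rng)
        novel = len(pool.order) - 1
        assert max(pool.members) <= 2**novel

    def test_members_are_sums_of_prior_members(self, rng):
        pool = AssemblyPool()
        for _ in range(100):
            step_undirected(pool, rng)
        for k, value in enumerate(pool.order[1:], start=1):
            prior = set(pool.order[:k])
            # created from members present at creation time (a superset check:
            # every non-monomer is a sum of two earlier-discovered lengths)
            assert any(value - a in prior for a in prior)


class TestJointAssemblySpace:
    def test_observed_1_and_8(self):
        dag = joint_assembly_space({1, 8})
        assert set(dag.graph.nodes) == {1, 2, 4, 8}
        assert dag.observed == {1, 8} and dag.contingent == {2, 4}
        assert exploration_ratio(dag) == 0.5

    def test_monomer_only(self):
        dag = joint_assembly_space({1})
        assert set(dag.graph.nodes) == {1} and not dag.contingent
        assert exploration_ratio(dag) == 1.0

    def test_fully_observed_doubling_chain(self):
        dag = joint_assembly_space({1, 2, 4, 8})
        assert set(dag.graph.nodes) == {1, 2, 4, 8} and not dag.contingent
        assert exploration_ratio(dag) == 1.0

    def test_huge_power_of_two(self):
        dag = joint_assembly_space({1, 2**20}, over_limit="binary")
        assert dag.graph.number_of_nodes() == 21
        assert exploration_ratio(dag) == pytest.approx(2 / 21)

    def test_node_count_bounds(self):
        observed = {1, 5, 9, 13}
        dag = joint_assembly_space(observed)
        total = dag.graph.number_of_nodes()
        from assemblykit.chains import addition_chain_min

        chain_lens = {n: addition_chain_min(n).index for n in observed}
        assert total <= sum(chain_lens.values()) + 1
        assert total >= chain_lens[max(observed)] + 1

    def test_refuses_over_limit_by_default(self):
        with pytest.raises(ValueError, match="exceeds"):
            joint_assembly_space({1, 2**20})

    def test_empty_and_invalid(self):
        with pytest.raises(ValueError, match="non-empty"):
            joint_assembly_space(set())
        with pytest.raises(ValueError, match=">= 1"):
            joint_assembly_space({0, 4})

    def test_dag_is_acyclic_with_parents_in_graph(self):
        import networkx as nx

        dag = joint_assembly_space({1, 11, 23})
        assert nx.is_directed_acyclic_graph(dag.graph)
        for n, d in dag.graph.nodes(data=True):
            if n == 1:
                continue
            left, right = d["parents"]
            assert left + right == n
            assert left in dag.graph and right in dag.graph


class TestExperiments:
    def test_single_step_run(self):
        cfg = SimulationConfig(mode="directed", steps=1, runs=1, seed=0)
        pool, stats = run_single(cfg, 0)
        assert pool.members == {1, 2}
        assert stats["exploration_ratio"] == 1.0

    def test_same_seed_identical_outputs(self):
        cfg = SimulationConfig(mode="undirected", steps=200, runs=3, seed=7)
        r1 = run_experiment(cfg).per_run
        r2 = run_experiment(cfg).per_run
        assert r1.equals(r2)

    def test_directed_more_selective_than_undirected(self):
        steps, runs, seed = 300, 10, 11
        ru = run_experiment(SimulationConfig(mode="undirected", steps=steps, runs=runs, seed=seed)).per_run
        rd = run_experiment(SimulationConfig(mode="directed", steps=steps, runs=runs, seed=seed)).per_run
        assert rd.exploration_ratio.mean() < ru.exploration_ratio.mean()
        assert rd.max_assembly_index.mean() > ru.max_assembly_index.mean()

    def test_max_index_within_log2_band(self):
        cfg = SimulationConfig(mode="undirected", steps=400, runs=4, seed=3)
        per_run = run_experiment(cfg).per_run
        for _, row in per_run.iterrows():
            log2n = row["log2_max_length"]
            assert log2n <= row["max_assembly_index"] <= 2 * log2n + 1e-9

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(mode="sideways", steps=1, runs=1, seed=0)
        with pytest.raises(ValueError):
            SimulationConfig(mode="directed", steps=0, runs=1, seed=0)
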