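"""Pearson networks, threshold sweep, components, bait-prey construction."""

import math
import random

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from roothair import coexpression as cx
from roothair.model import CompendiumMatrix
from roothair.synthetic_data import SyntheticConfig, gen_compendium, gen_go


def _pearson_oracle(x, y):
    """Two-pass textbook formula, independent of the numpy path."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


class TestPearson:
    def test_perfect_linearity_and_reflection(self):
        assert cx.pearson([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
        assert cx.pearson([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        assert cx.pearson([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_matches_two_pass_oracle_on_random_vectors(self):
        rng = random.Random(5)
        for _ in range(50):
            n = rng.randint(3, 40)
            x = [rng.gauss(0, 1) for _ in range(n)]
            y = [rng.gauss(0, 1) for _ in range(n)]
            assert cx.pearson(x, y) == pytest.approx(_pearson_oracle(x, y), abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            cx.pearson([1, 1, 1], [1, 2, 3])

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            cx.pearson([1, 2], [3, 4])


def _matrix_from_rows(rows):
    return CompendiumMatrix(
        pd.DataFrame(
            rows, index=[f"g{i}" for i in range(len(rows))],
            columns=[f"a{j}" for j in range(len(rows[0]))],
        )
    )


class TestBuildNetwork:
    def test_threshold_one_on_noise_gives_empty_network(self):
        rng = np.random.default_rng(1)
        mat = _matrix_from_rows(rng.normal(size=(6, 30)))
        net = cx.build_network(mat, mat.genes, 1.0)
        assert net.nodes == set() and net.edges == set()

    def test_duplicated_rows_always_connected(self):
        rng = np.random.default_rng(2)
        row = rng.normal(size=20)
        mat = _matrix_from_rows([row, row.copy(), rng.normal(size=20)])
        net = cx.build_network(mat, mat.genes, 0.9999)
        assert ("g0", "g1") in {(u, v) for u, v, _ in net.edges}

    def test_isolated_genes_are_not_nodes(self):
        rng = np.random.default_rng(3)
        row = rng.normal(size=50)
        mat = _matrix_from_rows([row, row + rng.normal(0, 0.05, 50), rng.normal(size=50)])
        net = cx.build_network(mat, mat.genes, 0.9)
        assert net.nodes == {"g0", "g1"}

    def test_planted_module_edge_recall(self):
        cfg = SyntheticConfig(seed=7, n_genes=60, module_specs=((20, 0.95),), n_arrays=300)
        mat, truth = gen_compendium(cfg)
        net = cx.build_network(mat, mat.genes, 0.83)
        members = sorted(truth.true_modules[0])
        possible = len(members) * (len(members) - 1) // 2
        within = sum(
            1 for u, v, _ in net.edges if u in truth.true_modules[0] and v in truth.true_modules[0]
        )
        assert within / possible >= 0.9

    def test_edge_count_non_increasing_in_threshold(self):
        cfg = SyntheticConfig(seed=8, n_genes=40, module_specs=((15, 0.9),), n_arrays=100)
        mat, _ = gen_compendium(cfg)
        counts = [len(cx.build_network(mat, mat.genes, t).edges) for t in cx.DEFAULT_GRID]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestSelectThreshold:
    def _setup(self, seed=10):
        cfg = SyntheticConfig(seed=seed, n_genes=80, module_specs=((20, 0.9),), n_arrays=150)
        mat, truth = gen_compendium(cfg)
        study = sorted(truth.true_modules[0])
        dag, _ = gen_go(
            SyntheticConfig(seed=seed, dag_terms=30, enriched_term_fold=3.5, enriched_term_size=12),
            study,
            mat.genes,
        )
        return mat, dag

    def test_single_value_grid_is_chosen(self):
        mat, dag = self._setup()
        res = cx.select_threshold(mat, mat.genes, dag, grid=[0.75])
        assert res.chosen == 0.75

    def test_flat_noise_ties_break_to_largest_threshold(self):
        rng = np.random.default_rng(11)
        mat = _matrix_from_rows(rng.normal(size=(12, 20)))
        dag, _ = gen_go(
            SyntheticConfig(seed=11, dag_terms=10, enriched_term_fold=1.0, enriched_term_size=4),
            mat.genes[:4],
            mat.genes,
        )
        # low grid so chance edges keep the networks non-empty; no term can
        # reach the sweep alpha, so all scores tie at 0
        res = cx.select_threshold(mat, mat.genes, dag, grid=[0.3, 0.4, 0.5])
        assert res.scores == (0, 0, 0)
        assert res.chosen == 0.5

    def test_all_empty_networks_error(self):
        rng = np.random.default_rng(12)
        mat = _matrix_from_rows(rng.normal(size=(8, 60)))
        dag, _ = gen_go(
            SyntheticConfig(seed=12, dag_terms=10, enriched_term_fold=1.0, enriched_term_size=4),
            mat.genes[:3],
            mat.genes,
        )
        with pytest.raises(ValueError, match="lower threshold"):
            cx.select_threshold(mat, mat.genes, dag, grid=[0.999])

    def test_enriched_module_drives_choice_below_disconnection(self):
        mat, dag = self._setup(seed=13)
        res = cx.select_threshold(mat, mat.genes, dag, grid=cx.DEFAULT_GRID)
        # latent strength 0.9 -> expected r ~ 0.81; above that the module
        # disconnects and its enrichment disappears
        assert res.chosen <= 0.88
        assert max(res.scores) > 0


class TestComponents:
    def test_two_planted_modules_give_two_components(self):
        cfg = SyntheticConfig(
            seed=14, n_genes=60, module_specs=((10, 0.97), (7, 0.97)), n_arrays=300
        )
        mat, truth = gen_compendium(cfg)
        net = cx.build_network(mat, mat.genes, 0.85)
        comps = cx.connected_components(net)
        assert [set(c) for c in comps[:2]] == sorted(
            truth.true_modules, key=lambda m: (-len(m), min(m))
        )

    def test_empty_and_single_edge(self):
        empty = cx.CoexpressionNetwork(nx.Graph(), 0.8)
        assert cx.connected_components(empty) == []
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.9)
        assert cx.connected_components(cx.CoexpressionNetwork(g, 0.8)) == [{"a", "b"}]

    def test_components_partition_nodes(self):
        cfg = SyntheticConfig(seed=15, n_genes=50, module_specs=((8, 0.9),), n_arrays=100)
        mat, _ = gen_compendium(cfg)
        net = cx.build_network(mat, mat.genes, 0.7)
        comps = cx.connected_components(net)
        union = set().union(*comps) if comps else set()
        assert union == net.nodes
        assert sum(len(c) for c in comps) == len(net.nodes)


class TestBaitPrey:
    def test_prey_pair_without_bait_link_removed(self):
        rng = np.random.default_rng(16)
        shared = rng.normal(size=60)
        rows = [shared + rng.normal(0, 0.05, 60) for _ in range(2)]  # correlated preys
        rows.append(rng.normal(size=60))  # unrelated bait
        mat = _matrix_from_rows(rows)
        net = cx.bait_prey_network(mat, baits={"g2"}, preys={"g0", "g1"}, threshold=0.8)
        assert net.nodes == set()

    def test_bait_prey_edge_retained(self):
        rng = np.random.default_rng(17)
        shared = rng.normal(size=60)
        mat = _matrix_from_rows([shared + rng.normal(0, 0.05, 60), shared + rng.normal(0, 0.05, 60)])
        net = cx.bait_prey_network(mat, baits={"g0"}, preys={"g1"}, threshold=0.8)
        assert net.nodes == {"g0", "g1"}

    def test_overlapping_sets_rejected(self):
        rng = np.random.default_rng(18)
        mat = _matrix_from_rows(rng.normal(size=(3, 30)))
        with pytest.raises(ValueError, match="overlap"):
            cx.bait_prey_network(mat, {"g0", "g1"}, {"g1", "g2"}, 0.8)

    def test_every_prey_adjacent_to_a_bait(self):
        cfg = SyntheticConfig(seed=19, n_genes=50, module_specs=((15, 0.9),), n_arrays=200)
        mat, truth = gen_compendium(cfg)
        members = sorted(truth.true_modules[0])
        baits = set(members[:5])
        preys = set(mat.genes) - baits
        net = cx.bait_prey_network(mat, baits, preys, 0.75)
        for node in net.nodes & preys:
            assert any(nb in baits for nb in net.graph.neighbors(node))
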