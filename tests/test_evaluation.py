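import dataclasses
import json
import math

import numpy as np
import pytest

from wmilink import (
    IndexConfig,
    WeightedGraph,
    alpha_sweep,
    evaluate,
    precision_at,
    random_split,
    rank_candidates,
    rmsd,
    select_alpha_validated,
)
from wmilink.evaluation import (
    SweepResult,
    candidate_non_edges,
    run_seeds,
    score_candidates,
)
from wmilink.synth_networks import SynthSpec, generate

from conftest import random_graph


def small_synth(seed=0, mode="iid", n=60):
    return generate(SynthSpec(n=n, mean_degree=6, weight_mode=mode,
                              seed=seed))


class TestRandomSplit:
    def test_sizes(self):
        g = random_graph(2, n_min=8)
        split = random_split(g, 0.1, rng_seed=5)
        n_probe = int(round(0.1 * g.number_of_edges))
        assert len(split.probe) == max(n_probe, 1)
        assert (split.train.number_of_edges + len(split.probe)
                == g.number_of_edges)

    def test_ten_edges_fraction_tenth(self):
        g = WeightedGraph([(f"n{i}", f"n{i+1}", 1.0) for i in range(10)])
        split = random_split(g, 0.1, rng_seed=0)
        assert len(split.probe) == 1
        assert split.train.number_of_edges == 9

    def test_deterministic(self):
        g = random_graph(4)
        s1 = random_split(g, 0.2, rng_seed=42)
        s2 = random_split(g, 0.2, rng_seed=42)
        assert s1.probe == s2.probe
        assert s1.train == s2.train

    @pytest.mark.parametrize("seed", range(25))
    def test_partition_invariants(self, seed):
        g = random_graph(seed, n_min=6)
        split = random_split(g, 0.25, rng_seed=seed)
        train_edges = split.train.edge_pairs()
        assert train_edges | split.probe == g.edge_pairs()
        assert not train_edges & split.probe
        assert split.train.nodes == g.nodes  # node set preserved

    def test_weights_preserved_in_train(self):
        g = random_graph(9)
        split = random_split(g, 0.2, rng_seed=1)
        for x, y in split.train.edge_pairs():
            assert split.train.weight(x, y) == g.weight(x, y)

    @pytest.mark.parametrize("frac", [0.0, 1.0, -0.1])
    def test_degenerate_fraction_rejected(self, frac):
        g = random_graph(0)
        with pytest.raises(ValueError):
            random_split(g, frac, rng_seed=0)


class TestPrecisionAt:
    def test_all_hits(self):
        ranked = [("a", "b"), ("c", "d")]
        assert precision_at(ranked, {("a", "b"), ("c", "d")}, 2) == 1.0

    def test_no_hits(self):
        assert precision_at([("a", "b")], {("x", "y")}, 1) == 0.0

    def test_ratio(self):
        ranked = [(f"u{i}", f"v{i}") for i in range(100)]
        probe = {(f"u{i}", f"v{i}") for i in range(37)}
        assert precision_at(ranked, probe, 100) == 0.37

    def test_orientation_insensitive(self):
        assert precision_at([("b", "a")], {("a", "b")}, 1) == 1.0

    def test_too_few_candidates(self):
        with pytest.raises(ValueError):
            precision_at([("a", "b")], set(), 2)


class TestRankCandidates:
    def test_distinct_scores_deterministic(self):
        scores = {("a", "b"): 3.0, ("c", "d"): 1.0, ("e", "f"): 2.0}
        rng = np.random.default_rng(0)
        assert rank_candidates(scores, 1, rng) == [
            ("a", "b"), ("e", "f"), ("c", "d")]

    def test_tied_block_stays_above_gap(self):
        scores = {("a", "b"): 5.0, ("c", "d"): 5.0, ("e", "f"): 0.0}
        for seed in range(20):
            ranked = rank_candidates(scores, 3,
                                     np.random.default_rng(seed))
            assert set(ranked[:2]) == {("a", "b"), ("c", "d")}

    def test_all_tied_mean_rank_uniform(self):
        pairs = [(f"u{i}", f"v{i}") for i in range(8)]
        scores = {p: 1.0 for p in pairs}
        ranks = {p: [] for p in pairs}
        for seed in range(3000):
            ranked = rank_candidates(scores, 8, np.random.default_rng(seed))
            for r, p in enumerate(ranked, start=1):
                ranks[p].append(r)
        expected = (len(pairs) + 1) / 2  # 4.5
        for p in pairs:
            assert np.mean(ranks[p]) == pytest.approx(expected, abs=0.15)


class TestEvaluate:
    def test_single_run_equals_manual_composition(self):
        g = small_synth(seed=3, mode="positive")
        cfg = IndexConfig("cn", mi_fused=True, alpha=0.8)
        L = 20
        res = evaluate(g, cfg, runs=1, L=L, probe_fraction=0.1, seed=7)
        split_seed, tie_seed = run_seeds(7, 1)[0]
        split = random_split(g, 0.1, split_seed)
        cands = candidate_non_edges(split.train)
        scores = score_candidates(split.train, cands, cfg)
        ranked = rank_candidates(scores, L, np.random.default_rng(tie_seed))
        manual = precision_at(ranked, split.probe, L)
        assert res.precision_per_run == [manual]

    def test_identical_seed_identical_result(self):
        g = small_synth(seed=1)
        cfg = IndexConfig("ra")
        r1 = evaluate(g, cfg, runs=3, L=10, seed=11)
        r2 = evaluate(g, cfg, runs=3, L=10, seed=11)
        assert dataclasses.asdict(r1) == dataclasses.asdict(r2)
        assert (json.dumps(dataclasses.asdict(r1))
                == json.dumps(dataclasses.asdict(r2)))

    def test_precision_in_unit_interval_and_probe_bound(self):
        g = small_synth(seed=2)
        L = 40
        with pytest.warns(UserWarning, match="bounded"):
            res = evaluate(g, IndexConfig("cn"), runs=4, L=L,
                           probe_fraction=0.1, seed=3)
        bound = int(round(0.1 * g.number_of_edges)) / L
        for p in res.precision_per_run:
            assert 0.0 <= p <= min(1.0, bound)

    def test_planted_ranking_gives_perfect_precision(self, fixtures):
        # train = K5 minus one edge (plus K3): the missing clique edge has
        # three common neighbors, every other candidate at most zero.
        g = fixtures["cliques53"]
        probe = {("p", "q")}
        train = g.subgraph_with_edges(e for e in g.edge_pairs()
                                      if e not in probe)
        cands = candidate_non_edges(train)
        scores = score_candidates(train, cands, IndexConfig("cn"))
        ranked = rank_candidates(scores, 1, np.random.default_rng(0))
        assert precision_at(ranked, probe, 1) == 1.0

    def test_pure_mi_config(self):
        g = small_synth(seed=5)
        res = evaluate(g, "mi", runs=2, L=10, seed=2)
        assert 0.0 <= res.mean_precision <= 1.0


class TestAlphaSweep:
    def test_singleton_grid(self):
        g = small_synth(seed=4)
        res = alpha_sweep(g, IndexConfig("cn"), [0.7], runs=2, L=10, seed=1)
        assert res.alpha_star == 0.7

    def test_uniform_weights_flat_in_alpha(self):
        base = generate(SynthSpec(n=60, mean_degree=6, weight_mode="iid",
                                  noise_sd=0.0, seed=8))
        res = alpha_sweep(base, IndexConfig("cn"), [-1.0, 0.0, 1.0, 2.0],
                          runs=3, L=10, seed=5)
        vals = set(res.mean_precision_at.values())
        assert len(vals) == 1

    def test_alpha_zero_column_equals_unweighted(self):
        g = small_synth(seed=6, mode="positive")
        sweep = alpha_sweep(g, IndexConfig("aa"), [0.0], runs=3, L=10,
                            seed=9)
        unweighted = evaluate(g, IndexConfig("aa", weighted=False), runs=3,
                              L=10, seed=9)
        assert sweep.mean_precision_at[0.0] == pytest.approx(
            unweighted.mean_precision)

    def test_tie_break_toward_smallest_abs_alpha(self):
        res = SweepResult(grid=[-1.0, 0.5, 1.0],
                          mean_precision_at={-1.0: 0.3, 0.5: 0.3, 1.0: 0.3})
        assert res.alpha_star == 0.5


class TestSelectAlphaValidated:
    def test_singleton_grid(self):
        g = small_synth(seed=3)
        a_hat, p = select_alpha_validated(g, IndexConfig("cn"), [1.3],
                                          seed=2, L=10)
        assert a_hat == 1.3
        assert 0.0 <= p <= 1.0

    def test_deterministic(self):
        g = small_synth(seed=3, mode="positive")
        grid = [-0.5, 0.0, 0.5, 1.0, 1.5]
        out1 = select_alpha_validated(g, IndexConfig("cn"), grid, seed=4,
                                      L=10)
        out2 = select_alpha_validated(g, IndexConfig("cn"), grid, seed=4,
                                      L=10)
        assert out1 == out2

    def test_bad_proportions(self):
        g = small_synth(seed=0)
        with pytest.raises(ValueError):
            select_alpha_validated(g, IndexConfig("cn"), [1.0],
                                   proportions=(0.5, 0.2, 0.2), seed=0)


class TestRmsd:
    def test_identical_pairs_zero(self):
        assert rmsd([(0.3, 0.3), (0.7, 0.7)]) == 0.0

    def test_single_unit_pair(self):
        assert rmsd([(0.0, 1.0)]) == 1.0

    def test_hand_value(self):
        assert rmsd([(0.1, 0.2), (0.3, 0.3)]) == pytest.approx(
            math.sqrt(0.005))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rmsd([])
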