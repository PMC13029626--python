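import numpy as np
import pytest
from scipy.stats import spearmanr

from krdqn.errors import UndefinedMetricError
from krdqn.evaluate import score_pair
from krdqn.interpret import (
    _cosine_condensed,
    fidelity,
    similarity_concordance,
    top_k_paths,
)
from krdqn.network import QNetwork
from krdqn.search import beam_complete_paths, enumerate_paths_to_adr, score_paths

from conftest import chain_edges, make_graph


def fan_graph(n_targets=4, n_pathways=5, n_genes=5, adrs=("A1", "A2")):
    """Dense layered toy with n_t * n_p * n_g * len(adrs) template paths."""
    edges = []
    for t in range(n_targets):
        edges.append(("D1", f"T{t}"))
        for p in range(n_pathways):
            edges.append((f"T{t}", f"P{p}"))
    for p in range(n_pathways):
        for g in range(n_genes):
            edges.append((f"P{p}", f"G{g}"))
    for g in range(n_genes):
        for a in adrs:
            edges.append((f"G{g}", a))
    return make_graph(edges)


class TestTopKPaths:
    def test_k_exceeding_supply_returns_all(self, rng):
        g = make_graph(
            chain_edges("D1", "T1", "P1", "G1", "A1")
            + chain_edges("D1", "T2", "P2", "G2", "A1")
            + chain_edges("D1", "T3", "P3", "G3", "A1")
        )
        net = QNetwork(sorted(g.nodes), rng=rng)
        paths = top_k_paths(net, g, "D1", "A1", k=10)
        assert len(paths) == 3
        assert [p.rank for p in paths] == [1, 2, 3]
        qs = [p.q_value for p in paths]
        assert qs == sorted(qs, reverse=True)

    def test_exhaustive_equals_wide_beam(self, rng):
        g = fan_graph()  # 4*5*5*2 = 200 template paths
        net = QNetwork(sorted(g.nodes), rng=rng)
        exhaustive = score_paths(net, g, enumerate_paths_to_adr(g, "D1", "A1"), "A1")
        exhaustive.sort(key=lambda p: (-p.total_q, p.nodes))
        beam = [
            p for p in beam_complete_paths(net, g, "D1", "A1", beam_width=500)
            if p.adr == "A1"
        ]
        beam.sort(key=lambda p: (-p.total_q, p.nodes))
        assert [p.nodes for p in beam[:10]] == [p.nodes for p in exhaustive[:10]]

    def test_k1_is_argmax_path(self, rng):
        g = fan_graph(2, 2, 2)
        net = QNetwork(sorted(g.nodes), rng=rng)
        all_scored = score_paths(net, g, enumerate_paths_to_adr(g, "D1", "A1"), "A1")
        best = max(all_scored, key=lambda p: (p.total_q, p.nodes))
        assert top_k_paths(net, g, "D1", "A1", k=1)[0].node_ids == best.nodes

    def test_no_path_gives_empty_list(self, rng):
        g = make_graph(chain_edges("D1", "T1", "P1", "G1", "A1"), extra_nodes=["A9"])
        net = QNetwork(sorted(g.nodes), rng=rng)
        assert top_k_paths(net, g, "D1", "A9") == []

    def test_paths_are_sound(self, rng):
        g = fan_graph(3, 3, 3)
        net = QNetwork(sorted(g.nodes), rng=rng)
        edge_set = {(e.source, e.target) for e in g.edges}
        for p in top_k_paths(net, g, "D1", "A2", k=10):
            assert p.node_ids[0] == "D1" and p.node_ids[-1] == "A2"
            assert all(
                (p.node_ids[i], p.node_ids[i + 1]) in edge_set for i in range(4)
            )


class TestCosine:
    def test_identities(self, rng):
        v = rng.normal(size=8)
        sims = _cosine_condensed(np.vstack([v, v, -v]))
        assert sims[0] == pytest.approx(1.0)   # cos(v, v)
        assert sims[1] == pytest.approx(-1.0)  # cos(v, -v)


class TestSimilarityConcordance:
    def _monotone_setup(self, n_drugs=8):
        # drugs on a circle at uneven angles (no tied similarities); path
        # vectors sit at half the angle, so path-path cosine is a strictly
        # monotone transform of drug-drug cosine: identical rankings
        feats = {}
        paths = {}
        for i in range(n_drugs):
            angle = 0.12 * i ** 1.5
            feats[f"D{i}"] = np.array([np.cos(angle), np.sin(angle), 0.0])
            mech = np.array([np.cos(angle / 2), np.sin(angle / 2), 0.0])
            feats[f"T{i}"] = mech
            feats[f"P{i}"] = mech
            feats[f"G{i}"] = mech
            paths[f"D{i}"] = (f"D{i}", f"T{i}", f"P{i}", f"G{i}", "A1")
        return feats, {"A1": paths}

    def test_perfect_monotone_toy(self):
        feats, by_adr = self._monotone_setup()
        res = similarity_concordance(feats, by_adr, min_drugs=8)
        assert len(res) == 1
        assert res[0].spearman_rho == pytest.approx(1.0)
        assert res[0].n_drugs == 8

    def test_below_min_drugs_excluded(self):
        feats, by_adr = self._monotone_setup(n_drugs=5)
        assert similarity_concordance(feats, by_adr, min_drugs=8) == []

    def test_degenerate_flagged_and_outside_bh_family(self):
        feats = {f"D{i}": np.ones(3) for i in range(8)}
        feats.update({"T0": np.ones(3), "P0": np.ones(3), "G0": np.ones(3)})
        by_adr = {"A1": {f"D{i}": (f"D{i}", "T0", "P0", "G0", "A1") for i in range(8)}}
        res = similarity_concordance(feats, by_adr, min_drugs=8)
        assert res[0].degenerate
        assert res[0].adjusted_p is None

    def test_bh_stepup_hand_example(self):
        # p = [0.01, 0.02, 0.03] with m=3 -> adjusted all 0.03
        from scipy.stats import false_discovery_control

        adj = false_discovery_control([0.01, 0.02, 0.03], method="bh")
        assert np.allclose(adj, [0.03, 0.03, 0.03])

    def test_bh_matches_hand_oracle_on_random_vectors(self, rng):
        from scipy.stats import false_discovery_control

        for _ in range(20):
            p = rng.random(int(rng.integers(2, 30)))
            m = len(p)
            order = np.argsort(p)
            hand = np.empty(m)
            running = 1.0
            for rank_from_top in range(m - 1, -1, -1):
                idx = order[rank_from_top]
                running = min(running, p[idx] * m / (rank_from_top + 1))
                hand[idx] = running
            adj = false_discovery_control(p, method="bh")
            assert np.allclose(adj, hand)
            # monotone in the raw p-values, bounded by 1
            assert np.all(adj[order] == np.sort(adj)) and np.all(adj <= 1)


class TestFidelity:
    def test_single_chain_direct_recomputation(self, chain_graph, rng):
        net = QNetwork(sorted(chain_graph.nodes), rng=rng)
        score_orig, best = score_pair(net, chain_graph, "D1", "A1")
        masked = chain_graph.without_node(best[3])  # the gene
        score_masked, _ = score_pair(net, masked, "D1", "A1")
        f = fidelity(net, chain_graph, [("D1", "A1")], level="gene")
        assert f == pytest.approx(score_orig - score_masked)

    def test_target_removal_disconnects_and_skips(self, chain_graph, rng):
        net = QNetwork(sorted(chain_graph.nodes), rng=rng)
        # removing T1 leaves D1 with no out-edges -> pair skipped -> empty mean
        with pytest.raises(UndefinedMetricError):
            fidelity(net, chain_graph, [("D1", "A1")], level="target")

    def test_empty_pair_set_raises(self, chain_graph, rng):
        net = QNetwork(sorted(chain_graph.nodes), rng=rng)
        with pytest.raises(UndefinedMetricError):
            fidelity(net, chain_graph, [], level="gene")

    def test_invalid_level_rejected(self, chain_graph, rng):
        net = QNetwork(sorted(chain_graph.nodes), rng=rng)
        with pytest.raises(ValueError):
            fidelity(net, chain_graph, [("D1", "A1")], level="drug")

    def test_alternative_route_can_give_negative_fidelity(self, rng):
        # two chains to A1; masking the best path's gene reroutes the beam,
        # so per-pair fidelity is score difference of the two routes and may
        # legitimately be negative
        g = make_graph(
            chain_edges("D1", "T1", "P1", "G1", "A1")
            + chain_edges("D1", "T2", "P2", "G2", "A1")
        )
        net = QNetwork(sorted(g.nodes), rng=rng)
        f = fidelity(net, g, [("D1", "A1")], level="gene")
        assert np.isfinite(f)
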