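import numpy as np
import pytest
from scipy.stats import chisquare

from krdqn.agent import (
    EpisodeRecord,
    Experience,
    ReplayBuffer,
    TrainingConfig,
    anneal_epsilon,
    demonstrations_to_experiences,
    encode_state_action,
    select_action,
    td_target,
    train,
    train_step,
)
from krdqn.env import State, reset, rollout
from krdqn.errors import TrainingError
from krdqn.graph import extract_demonstration_paths
from krdqn.network import QNetwork

from conftest import chain_edges, make_graph


def small_config(**kw):
    defaults = dict(
        episodes=50, batch_size=8, dropout=0.0, learning_rate=0.01,
        target_sync_interval=10, seed=0,
    )
    defaults.update(kw)
    return TrainingConfig(**defaults)


class TestReplayBuffer:
    def _exp(self, i):
        return Experience(State(f"D{i}", 0, "A1"), "T1", 1.0, None, True, "A1")

    def test_fifo_eviction(self):
        buf = ReplayBuffer(capacity=10)
        for i in range(13):
            buf.push(self._exp(i))
        assert len(buf) == 10
        assert buf[0].state.current_node == "D3"  # first 3 evicted

    def test_sample_without_replacement(self, rng):
        buf = ReplayBuffer()
        for i in range(20):
            buf.push(self._exp(i))
        batch = buf.sample(20, rng)
        assert len({e.state.current_node for e in batch}) == 20

    def test_underfull_sample_raises(self, rng):
        buf = ReplayBuffer()
        buf.push(self._exp(0))
        with pytest.raises(ValueError):
            buf.sample(2, rng)


class TestEpsilonAnnealing:
    def test_one_application(self):
        assert anneal_epsilon(1.0, TrainingConfig()) == pytest.approx(0.987)

    def test_floor(self):
        assert anneal_epsilon(0.066, TrainingConfig()) == 0.066

    def test_floor_reached_at_episode_208(self):
        cfg = TrainingConfig()
        eps, n = 1.0, 0
        while eps > cfg.epsilon_min:
            eps = anneal_epsilon(eps, cfg)
            n += 1
        assert n == 208
        assert 0.987 ** 208 < 0.066 <= 0.987 ** 207

    def test_sequence_non_increasing(self):
        cfg = TrainingConfig()
        eps = 1.0
        seq = []
        for _ in range(300):
            eps = anneal_epsilon(eps, cfg)
            seq.append(eps)
        assert all(a >= b for a, b in zip(seq, seq[1:]))
        assert min(seq) == 0.066


class TestTdTarget:
    def test_terminal_is_reward(self, chain_graph, rng):
        net = QNetwork(sorted(chain_graph.nodes), rng=rng)
        exp = Experience(State("G1", 3, "A1"), "A1", 5.0, None, True, "A1")
        assert td_target(net, chain_graph, exp, 0.946) == 5.0

    def test_bootstrap_from_max_next_q(self, chain_graph, rng):
        net = QNetwork(sorted(chain_graph.nodes), rng=rng)
        exp = Experience(
            State("P1", 2, "A1"), "G1", 1.0, State("G1", 3, "A1"), False, "A1"
        )
        max_q = net.q_value("A1", 3, "A1")  # only admissible next action
        assert td_target(net, chain_graph, exp, 0.946) == pytest.approx(1 + 0.946 * max_q)

    def test_hand_arithmetic(self, chain_graph, rng):
        net = QNetwork(sorted(chain_graph.nodes), rng=rng)

        class Fixed:
            def q_values(self, *a, **kw):
                return np.array([5.73])

        exp = Experience(
            State("P1", 2, "A1"), "G1", 1.0, State("G1", 3, "A1"), False, "A1"
        )
        assert td_target(Fixed(), chain_graph, exp, 0.946) == pytest.approx(6.42058)

    def test_gamma_zero_is_myopic(self, chain_graph, rng):
        net = QNetwork(sorted(chain_graph.nodes), rng=rng)
        exp = Experience(
            State("D1", 0, "A1"), "T1", 1.0, State("T1", 1, "A1"), False, "A1"
        )
        assert td_target(net, chain_graph, exp, 0.0) == 1.0


class TestSelectAction:
    def test_fully_random_is_uniform(self, rng):
        g = make_graph([("D1", f"T{i}") for i in range(1, 5)])
        net = QNetwork(sorted(g.nodes), rng=rng)
        counts = {f"T{i}": 0 for i in range(1, 5)}
        s = State("D1", 0, "T1")  # target unused at epsilon=1
        for _ in range(10_000):
            counts[select_action(net, g, State("D1", 0, "T1"), 1.0, rng)] += 1
        _, p = chisquare(list(counts.values()))
        assert p > 1e-4

    def test_greedy_argmax(self, chain_graph, rng):
        g = make_graph([("D1", "T1"), ("D1", "T2")])
        net = QNetwork(sorted(g.nodes), rng=rng)

        class Stub:
            def q_values(self, actions, *a, **kw):
                return np.array([{"T1": 2.0, "T2": 1.0}[x] for x in actions])

        assert select_action(Stub(), g, State("D1", 0, "T1"), 0.0, rng) == "T1"

    def test_tie_breaks_lexicographically(self, rng):
        g = make_graph([("D1", "T2"), ("D1", "T1")])

        class Stub:
            def q_values(self, actions, *a, **kw):
                return np.zeros(len(actions))

        assert select_action(Stub(), g, State("D1", 0, "T1"), 0.0, rng) == "T1"

    def test_dead_end_returns_none(self, chain_graph, rng):
        net = QNetwork(sorted(chain_graph.nodes), rng=rng)
        assert select_action(net, chain_graph, State("A1", 4, "A1"), 0.0, rng) is None


class TestTrainStep:
    def test_underfull_buffer_skips(self, chain_graph, rng):
        net = QNetwork(sorted(chain_graph.nodes), rng=rng)
        target = net.clone()
        before = net.params["W0"].copy()
        loss = train_step(net, target, ReplayBuffer(), chain_graph, small_config(), rng)
        assert loss is None
        assert np.array_equal(net.params["W0"], before)

    def test_zero_network_fixed_point(self, chain_graph, rng):
        # Q == 0 everywhere and reward 0 => every TD error is 0: loss 0,
        # no parameter movement
        net = QNetwork(sorted(chain_graph.nodes), dropout=0.0, rng=rng)
        for k in net.params:
            net.params[k][:] = 0.0
        target = net.clone()
        buf = ReplayBuffer()
        for _ in range(8):
            buf.push(Experience(State("D1", 0, "A1"), "T1", 0.0,
                                State("T1", 1, "A1"), False, "A1"))
        loss = train_step(net, target, buf, chain_graph, small_config(), rng)
        assert loss == 0.0
        assert all(np.all(v == 0) for v in net.params.values())

    def test_single_experience_loss_is_squared_td_error(self, chain_graph, rng):
        net = QNetwork(sorted(chain_graph.nodes), dropout=0.0, rng=rng)
        target = net.clone()
        exp = Experience(State("G1", 3, "A1"), "A1", 5.0, None, True, "A1")
        buf = ReplayBuffer()
        buf.push(exp)
        q = encode_state_action(net, exp.state, exp.action)
        loss = train_step(net, target, buf, chain_graph, small_config(batch_size=1), rng)
        assert loss == pytest.approx((q - 5.0) ** 2)

    def test_loss_decreases_on_frozen_buffer(self, chain_graph, rng):
        net = QNetwork(sorted(chain_graph.nodes), dropout=0.0, rng=rng)
        target = net.clone()
        buf = ReplayBuffer()
        buf.extend(
            demonstrations_to_experiences(
                chain_graph, extract_demonstration_paths(chain_graph)
            )
        )
        cfg = small_config(batch_size=4)
        losses = [train_step(net, target, buf, chain_graph, cfg, rng) for _ in range(200)]
        assert np.mean(losses[-20:]) < 0.05 * np.mean(losses[:20])


class TestDemonstrationDecomposition:
    def test_rewards_and_transitions(self, chain_graph):
        exps = demonstrations_to_experiences(
            chain_graph, extract_demonstration_paths(chain_graph)
        )
        assert len(exps) == 4
        assert [e.reward for e in exps] == [1.0, 1.0, 1.0, 5.0]
        assert exps[-1].done and exps[-1].next_state is None
        assert all(e.target_adr == "A1" for e in exps)
        assert [e.state.hop_count for e in exps] == [0, 1, 2, 3]


class TestTrain:
    def test_single_chain_recovery(self, chain_graph):
        paths = extract_demonstration_paths(chain_graph)
        cfg = small_config(episodes=300, batch_size=16, seed=1)
        net, log = train(chain_graph, paths, [("D1", "A1")], cfg)
        greedy = lambda s: select_action(net, chain_graph, s, 0.0, np.random.default_rng(0))
        path, total, reached = rollout(chain_graph, reset(chain_graph, "D1", "A1"), greedy)
        assert reached and total == 8
        assert len(log) == 300

    def test_two_chain_preference(self, two_chain_graph):
        # only the T1 chain ends at A1; after training the greedy policy
        # must pick it when A1 is the goal
        paths = extract_demonstration_paths(two_chain_graph)
        cfg = small_config(episodes=400, batch_size=16, seed=2)
        net, _ = train(two_chain_graph, paths, [("D1", "A1")], cfg)
        greedy = lambda s: select_action(net, two_chain_graph, s, 0.0, np.random.default_rng(0))
        path, total, reached = rollout(
            two_chain_graph, reset(two_chain_graph, "D1", "A1"), greedy
        )
        assert path == ["D1", "T1", "P1", "G1", "A1"] and reached

    def test_zero_episodes_leaves_network_at_init(self, chain_graph):
        paths = extract_demonstration_paths(chain_graph)
        cfg = small_config(episodes=0, seed=3)
        net, log = train(chain_graph, paths, [("D1", "A1")], cfg)
        fresh = QNetwork(
            sorted(chain_graph.nodes), embed_dim=cfg.embed_dim,
            hidden_sizes=cfg.hidden_sizes, dropout=cfg.dropout,
            rng=np.random.default_rng(cfg.seed),
        )
        assert log == []
        for k in net.params:
            assert np.array_equal(net.params[k], fresh.params[k])

    def test_seed_determinism(self, chain_graph):
        paths = extract_demonstration_paths(chain_graph)
        logs = []
        for _ in range(2):
            _, log = train(chain_graph, paths, [("D1", "A1")], small_config(seed=7))
            logs.append([(r.episode, r.total_reward, r.epsilon, r.loss, r.lr) for r in log])
        assert logs[0] == logs[1]

    def test_gradient_reaches_embeddings(self, chain_graph):
        paths = extract_demonstration_paths(chain_graph)
        cfg = small_config(episodes=40, batch_size=4, seed=4)
        net, _ = train(chain_graph, paths, [("D1", "A1")], cfg)
        fresh = QNetwork(
            sorted(chain_graph.nodes), embed_dim=cfg.embed_dim,
            hidden_sizes=cfg.hidden_sizes, dropout=cfg.dropout,
            rng=np.random.default_rng(cfg.seed),
        )
        assert not np.array_equal(net.params["node_emb"], fresh.params["node_emb"])
        assert not np.array_equal(net.params["step_emb"], fresh.params["step_emb"])

    def test_degenerate_task_raises(self, chain_graph):
        with pytest.raises(TrainingError):
            train(chain_graph, [], [("D1", "A1")], small_config())


class TestTrainingConfig:
    @pytest.mark.parametrize(
        "kw",
        [
            {"gamma": 0.0},
            {"gamma": 1.0},
            {"epsilon_min": 0.0},
            {"epsilon_start": 1.5},
            {"learning_rate": -1.0},
            {"episodes": -1},
        ],
    )
    def test_invalid_values_rejected(self, kw):
        with pytest.raises(ValueError):
            TrainingConfig(**kw)
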