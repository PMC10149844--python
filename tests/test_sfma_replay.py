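"""Sequential replay sampler: score factors, sampling distribution,
event generation and the random-replay comparator."""

import numpy as np
import pytest
from scipy.stats import chisquare, spearmanr

from emrl.maze_env import TopologyMaze, build_tunnel_maze
from emrl.sfma_replay import (
    ExperienceStore,
    eq10_probabilities,
    generate_replay_event,
    random_replay_event,
    sample_next,
    sequence_lengths,
)


N_LINE = 9


@pytest.fixture()
def line_maze():
    return TopologyMaze(
        [(i, 0) for i in range(N_LINE)],
        [(i, i + 1) for i in range(N_LINE - 1)],
        0,
        N_LINE - 1,
        timeout=50,
    )


def track_store(maze, rewarded=True, **kw):
    """One traversal of the line, heading E (action 0 throughout)."""
    store = ExperienceStore(maze, **kw)
    for i in range(N_LINE - 1):
        s, s2 = i * 4 + 1, (i + 1) * 4 + 1
        last = i == N_LINE - 2
        store.add(s, 0, s2, 1.0 if (last and rewarded) else 0.0, last and rewarded)
    return store


class TestStrength:
    def test_unstored_is_zero(self, line_maze):
        store = track_store(line_maze)
        assert store.strength(99, 0, 100) == 0.0

    def test_visit_count_no_reward_linear(self, line_maze):
        store = ExperienceStore(line_maze, count_weighting="linear")
        for _ in range(3):
            store.add(1, 0, 5, 0.0, False)
        assert store.strength(1, 0, 5) == pytest.approx(3.0)

    def test_visit_count_saturating_default(self, line_maze):
        store = ExperienceStore(line_maze)
        for _ in range(3):
            store.add(1, 0, 5, 0.0, False)
        assert store.strength(1, 0, 5) == pytest.approx(1.0 + np.log(3.0))

    def test_reward_weighting(self, line_maze):
        # single visit: both count responses give 1, reward doubles it
        store = ExperienceStore(line_maze, lambda_r=1.0)
        store.add(1, 0, 5, 1.0, True)
        assert store.strength(1, 0, 5) == pytest.approx(2.0)


class TestSimilarity:
    def test_coincident_anchors_give_one(self, line_maze):
        store = track_store(line_maze)
        # reverse mode: candidate whose next state is prev's current state
        sims = store.similarities(prev_idx=1, mode="reverse")
        assert sims[0] == pytest.approx(1.0)  # e0.next == e1.current

    def test_exponential_decay_with_distance_on_line(self, line_maze):
        # D = exp(-d_G / sigma) exactly, evaluated over all stored pairs
        store = track_store(line_maze, sigma=1.0)
        prev = 3  # e3: current node 3
        sims = store.similarities(prev_idx=prev, mode="reverse")
        next_nodes = np.arange(1, N_LINE)
        expected = np.exp(-np.abs(next_nodes - 3).astype(float))
        np.testing.assert_allclose(sims, expected)

    def test_unreachable_anchor_gives_zero(self):
        # d_G = inf convention: similarity exactly 0
        from types import SimpleNamespace

        fake_maze = SimpleNamespace(
            node_distances=np.array([[0.0, np.inf], [np.inf, 0.0]])
        )
        store = ExperienceStore(fake_maze, anchor="node")
        store.add(0 * 4, 0, 0 * 4 + 1, 0.0, False)  # stays on node 0
        store.add(1 * 4, 0, 1 * 4 + 1, 0.0, False)  # stays on node 1
        sims = store.similarities(prev_idx=0, mode="reverse")
        assert sims[1] == 0.0 and sims[0] == 1.0

    def test_event_start_similarity_is_one(self, line_maze):
        store = track_store(line_maze)
        np.testing.assert_allclose(store.similarities(None, "reverse"), 1.0)


class TestReactivationScores:
    def test_product_form(self, line_maze):
        store = ExperienceStore(line_maze)
        store.add(1, 0, 5, 1.0, False)  # C = 1 * (1 + 1) = 2
        store._consolidate()
        scores = store.reactivation_scores(None, "reverse")
        assert scores[0] == pytest.approx(2.0)  # D = 1 at event start, I = 0

    def test_full_inhibition_zeroes_score(self, line_maze):
        store = track_store(line_maze)
        store._consolidate()
        store.inhibition[2] = 1.0
        scores = store.reactivation_scores(None, "reverse")
        assert scores[2] == 0.0
        assert (scores >= 0).all()

    def test_empty_store(self, line_maze):
        store = ExperienceStore(line_maze)
        store._consolidate()
        assert store.reactivation_scores(None, "reverse").size == 0


class TestSamplingDistribution:
    def test_probabilities_normalize(self, rng):
        scores = rng.random(20)
        p = eq10_probabilities(scores, beta=2.0)
        assert p.sum() == pytest.approx(1.0)
        assert (p >= 0).all()

    def test_zero_score_zero_probability(self):
        p = eq10_probabilities(np.array([0.0, 1.0, 2.0]), beta=1.0)
        assert p[0] == 0.0

    def test_equal_scores_equal_probability(self):
        p = eq10_probabilities(np.array([0.7, 0.7]), beta=3.0)
        np.testing.assert_allclose(p, 0.5)

    def test_log_scores_closed_form(self):
        # scores (ln 3, ln 2) at beta = 1: weights (2, 1) -> (2/3, 1/3)
        p = eq10_probabilities(np.array([np.log(3), np.log(2)]), beta=1.0)
        np.testing.assert_allclose(p, [2 / 3, 1 / 3])

    def test_large_beta_stable(self):
        p = eq10_probabilities(np.array([0.0, 200.0, 199.0]), beta=10.0)
        assert p[0] == 0.0
        assert p.sum() == pytest.approx(1.0)
        assert p[1] > p[2]

    def test_empirical_frequencies_match_analytic(self, rng):
        # goodness of fit at 1e5 draws on a fixed 5-experience score set
        scores = np.array([0.1, 0.4, 0.8, 1.2, 0.0])
        p = eq10_probabilities(scores, beta=2.0)
        draws = np.array(
            [sample_next(scores, 2.0, rng) for _ in range(100_000)]
        )
        counts = np.bincount(draws, minlength=5)
        assert counts[4] == 0
        stat = chisquare(counts[:4], 100_000 * p[:4] / p[:4].sum())
        assert stat.pvalue > 1e-3

    def test_beta_zero_uniform_over_eligible(self, rng):
        # unequal strengths, beta = 0: uniform over eligible experiences
        scores = np.array([5.0, 1.0, 0.5, 2.0])
        eligible = np.array([True, True, True, True])
        draws = np.array(
            [sample_next(scores, 0.0, rng, eligible) for _ in range(40_000)]
        )
        freqs = np.bincount(draws, minlength=4) / 40_000
        np.testing.assert_allclose(freqs, 0.25, atol=0.012)

    def test_all_zero_scores_terminate(self, rng):
        assert sample_next(np.zeros(4), 2.0, rng) is None
        assert sample_next(np.zeros(0), 0.0, rng, np.zeros(0, dtype=bool)) is None

    def test_negative_beta_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_next(np.ones(3), -1.0, rng)


class TestReplayEvents:
    def test_event_geometry(self, line_maze, rng):
        store = track_store(line_maze)
        event = generate_replay_event(store, 10, 32, beta=2.0, rng=rng)
        assert event.n_batches == 10
        assert all(len(b) == 32 for b in event.batches)
        assert event.stream.size == 320
        assert all(int(i) < len(store) for i in event.stream)

    def test_empty_store_rejected(self, line_maze, rng):
        with pytest.raises(ValueError):
            generate_replay_event(ExperienceStore(line_maze), 1, rng=rng)

    def test_reverse_chain_property(self, line_maze, rng):
        # after one rewarded traversal, high beta: the modal successor of a
        # reactivated experience is its behavioural predecessor, verified
        # against exhaustive score computation at each step
        store = track_store(line_maze)
        event = generate_replay_event(store, 4, 32, beta=10.0, mode="reverse", rng=rng)
        store._consolidate()
        stream = event.stream
        is_pred = store.s[stream[:-1]] == store.s2[stream[1:]]
        assert is_pred.mean() > 0.5

    def test_sequence_length_increases_with_beta(self, line_maze):
        store = track_store(line_maze)
        means = []
        for beta in (0.0, 1.0, 2.0, 5.0, 10.0):
            lens = []
            for seed in range(10):
                ev = generate_replay_event(
                    store, 2, 32, beta=beta, rng=np.random.default_rng(seed)
                )
                lens.append(sequence_lengths(ev, store).mean())
            means.append(np.mean(lens))
        rho = spearmanr([0, 1, 2, 5, 10], means).statistic
        assert rho > 0.8

    def test_random_event_uniform_for_equal_counts(self, line_maze, rng):
        store = track_store(line_maze, rewarded=False)
        event = random_replay_event(store, 100, 32, rng)
        m = N_LINE - 1
        freqs = np.bincount(event.stream, minlength=m) / event.stream.size
        np.testing.assert_allclose(freqs, 1.0 / m, atol=0.02)

    def test_random_event_frequency_proportional(self, line_maze, rng):
        # one experience visited 9 times among singletons: expect ~9/18
        store = ExperienceStore(line_maze)
        for _ in range(9):
            store.add(1, 0, 5, 0.0, False)
        for i in range(1, 10):
            store.add(1, i % 5, 5 + i, 0.0, False)  # distinct singleton keys
        event = random_replay_event(store, 200, 32, rng)
        share = (event.stream == 0).mean()
        assert share == pytest.approx(0.5, abs=0.03)

    def test_random_event_shape_matches_sequential(self, line_maze, rng):
        store = track_store(line_maze)
        ev_r = random_replay_event(store, 5, 8, rng)
        ev_s = generate_replay_event(store, 5, 8, beta=1.0, rng=rng)
        assert ev_r.n_batches == ev_s.n_batches
        assert all(len(a) == len(b) for a, b in zip(ev_r.batches, ev_s.batches))

    def test_beta_zero_sequential_differs_from_random(self, line_maze):
        # unequal visit counts: beta = 0 samples unique transitions
        # uniformly; random replay oversamples the frequent one
        store = ExperienceStore(line_maze)
        for _ in range(20):
            store.add(1, 0, 5, 0.0, False)
        for i in range(1, 5):
            store.add(1, i, 5 + i, 0.0, False)
        rng = np.random.default_rng(0)
        seq = generate_replay_event(store, 20, 32, beta=0.0, rng=rng)
        rand = random_replay_event(store, 20, 32, rng)
        seq_share = (seq.stream == 0).mean()
        rand_share = (rand.stream == 0).mean()
        assert rand_share > 2 * seq_share

    def test_reverse_replay_accelerates_per_sample_q_learning(self):
        # the canonical regime for sequential replay: tabular Q-learning
        # with one update per reactivated experience and live bootstrap;
        # goal-anchored reverse replay must clearly outperform
        # frequency-weighted random replay
        from emrl.maze_env import build_tunnel_maze

        maze = build_tunnel_maze(2)
        nxt, rew, term = maze.transition_tables
        S, gamma, alpha, eps = maze.n_states, 0.9, 0.5, 0.1

        def run(mode, beta, seed, trials=25, n_batches=10):
            rng = np.random.default_rng(seed)
            Q = np.zeros((S, 6))
            store = ExperienceStore(maze)
            latencies = []
            start = maze.state_index(maze.start_state)
            for _ in range(trials):
                s = start
                for t in range(maze.timeout):
                    if rng.random() < eps:
                        a = rng.integers(0, 6)
                    else:
                        best = np.flatnonzero(Q[s] == Q[s].max())
                        a = best[rng.integers(0, best.size)]
                    s2, r, d = int(nxt[s, a]), float(rew[s, a]), bool(term[s, a])
                    store.add(s, int(a), s2, r, d)
                    s = s2
                    if d:
                        break
                latencies.append(t + 1)
                if mode == "seq":
                    ev = generate_replay_event(
                        store, n_batches, 32, beta=beta, rng=rng, start_state=s
                    )
                else:
                    ev = random_replay_event(store, n_batches, 32, rng=rng)
                store._consolidate()
                for i in ev.stream:
                    tgt = store.reward_sums[i] / store.counts[i]
                    if not store.terminal[i]:
                        tgt += gamma * Q[store.s2[i]].max()
                    Q[store.s[i], store.a[i]] += alpha * (
                        tgt - Q[store.s[i], store.a[i]]
                    )
            return np.mean(latencies)

        rand = np.mean([run("rand", 0.0, seed) for seed in range(5)])
        seq = np.mean([run("seq", 2.0, seed) for seed in range(5)])
        assert rand / seq > 1.3  # reverse replay clearly faster

    def test_inhibition_blocks_immediate_repeat(self, line_maze, rng):
        # within a sequence (= one batch) no experience follows itself
        store = track_store(line_maze)
        event = generate_replay_event(store, 3, 32, beta=5.0, rng=rng)
        for batch in event.batches:
            assert not np.any(batch[:-1] == batch[1:])
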