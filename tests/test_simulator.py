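import math

import numpy as np
import pytest

import trapline as tl
from trapline.simulator import init_agent, reinforce, run_trial


class TestInitAgent:
    def test_equilateral_triangle_uniform(self):
        arr = tl.build_array(
            "tri", {"A": (0, 0), "B": (1, 0), "C": (0.5, math.sqrt(3) / 2)}
        )
        agent = init_agent(arr, 1.0)
        w = agent.W[0]
        p = w[1:] / w[1:].sum()
        assert np.allclose(p, [0.5, 0.5])

    def test_collinear_weights(self, collinear):
        # from A: weights 1/1 and 1/2 toward B and C -> probs 2/3, 1/3
        agent = init_agent(collinear, 1.0)
        w = agent.W[0]
        assert w[1] / (w[1] + w[2]) == pytest.approx(2 / 3)
        # from the middle platform both neighbours are equidistant
        w = agent.W[1]
        assert w[0] == pytest.approx(w[2])

    def test_rejects_factor_below_one(self, collinear):
        with pytest.raises(ValueError, match="factor"):
            init_agent(collinear, 0.5)

    def test_rejects_bad_start_probs(self, collinear):
        with pytest.raises(ValueError):
            init_agent(collinear, 1.0, [0.5, 0.6, 0.2])


class TestRunTrial:
    def test_two_platform_trial(self, rng):
        arr = tl.build_array("pair", {"A": (0, 0), "B": (1, 0)})
        agent = init_agent(arr, 1.0)
        seq = run_trial(agent, rng)
        assert len(seq) == 2 and set(seq) == {"A", "B"}

    def test_visits_all_and_never_backtracks(self, double_trapezoid, rng):
        agent = init_agent(double_trapezoid, 1.0)
        for _ in range(200):
            seq = run_trial(agent, rng)
            assert set(seq) == set(double_trapezoid.labels)
            # no transition returns to the just-left platform
            for a, b, c in zip(seq, seq[1:], seq[2:]):
                assert a != c or a == b  # a==c only legal if not a backtrack
            for a, b in zip(seq, seq[1:]):
                assert a != b

    def test_first_transition_frequencies(self, collinear, rng):
        # from a fixed start at A: P(B)=2/3, P(C)=1/3
        agent = init_agent(collinear, 1.0, start_probs={"A": 1.0})
        n = 10_000
        count_b = sum(run_trial(agent, rng)[1] == "B" for _ in range(n))
        p = 2 / 3
        se = math.sqrt(p * (1 - p) / n)
        assert abs(count_b / n - p) < 3 * se


class TestReinforce:
    def test_factor_one_never_changes_weights(self, collinear, rng):
        agent = init_agent(collinear, 1.0)
        before = agent.W.copy()
        for _ in range(20):
            seq = run_trial(agent, rng)
            reinforce(agent, seq)
        assert np.array_equal(agent.W, before)

    def test_worse_trial_leaves_weights(self, collinear):
        agent = init_agent(collinear, 2.0)
        agent.best_distance = 1.0
        before = agent.W.copy()
        reinforce(agent, ["A", "B", "A", "C"], trial_distance=4.0)
        assert np.array_equal(agent.W, before)
        assert agent.best_distance == 1.0

    def test_improving_trial_doubles_used_transitions(self, collinear):
        agent = init_agent(collinear, 2.0)
        before = agent.W.copy()
        reinforce(agent, ["A", "B", "C"], trial_distance=2.0)
        i, j, k = 0, 1, 2
        assert agent.W[i, j] == pytest.approx(2 * before[i, j])
        assert agent.W[j, k] == pytest.approx(2 * before[j, k])
        untouched = np.ones_like(before, dtype=bool)
        untouched[i, j] = untouched[j, k] = False
        assert np.array_equal(agent.W[untouched], before[untouched])
        assert agent.best_distance == 2.0

    def test_duplicate_transition_reinforced_once(self, double_trapezoid):
        agent = init_agent(double_trapezoid, 2.0)
        before = agent.W.copy()
        # transition 1->2 traversed twice in one trial
        seq = ["1", "2", "3", "1", "2", "4", "5", "6"]
        reinforce(agent, seq)
        i, j = 0, 1
        assert agent.W[i, j] == pytest.approx(2 * before[i, j])

    def test_strict_mode_ignores_ties(self, collinear):
        agent = init_agent(collinear, 2.0, reinforce_ties=False)
        reinforce(agent, ["A", "B", "C"], trial_distance=2.0)
        before = agent.W.copy()
        reinforce(agent, ["A", "B", "C"], trial_distance=2.0)
        assert np.array_equal(agent.W, before)


class TestRunAgent:
    def test_deterministic_under_seed(self, pentagon):
        a = tl.run_agent(pentagon, 2.0, 30, seed=(5, 1))
        b = tl.run_agent(pentagon, 2.0, 30, seed=(5, 1))
        assert [r.sequence for r in a] == [r.sequence for r in b]

    def test_best_distance_bounded_by_optimum(self, pentagon):
        opt = tl.optimal_open_path(pentagon).length
        recs = tl.run_agent(pentagon, 2.0, 60, seed=3)
        best = min(r.distance for r in recs)
        assert best >= opt - 1e-9

    def test_weights_stay_positive(self, double_trapezoid, rng):
        agent = init_agent(double_trapezoid, 2.0)
        for _ in range(100):
            seq = run_trial(agent, rng)
            reinforce(agent, seq)
        off = agent.W[~np.eye(agent.array.n, dtype=bool)]
        assert np.all(off > 0)

    def test_no_trend_without_reinforcement(self, double_trapezoid):
        # F=1: slope of log distance on log trial ~ 0 across agents
        slopes = []
        for a in range(40):
            recs = tl.run_agent(double_trapezoid, 1.0, 40, seed=(11, a))
            y = np.log([r.distance for r in recs])
            x = np.log(np.arange(1, len(recs) + 1))
            slopes.append(np.polyfit(x, y, 1)[0])
        se = np.std(slopes, ddof=1) / math.sqrt(len(slopes))
        assert abs(np.mean(slopes)) < 3 * se + 0.01

    def test_strong_reinforcement_shortens_late_trials(self, double_trapezoid):
        # late-trial (101-120) mean distance: strong reinforcement < none
        late = {F: [] for F in (1.0, 2.0)}
        for F in late:
            for a in range(60):
                recs = tl.run_agent(double_trapezoid, F, 120, seed=(13, a))
                late[F].append(np.mean([r.distance for r in recs[100:]]))
        from scipy.stats import mannwhitneyu

        stat = mannwhitneyu(late[2.0], late[1.0], alternative="less")
        assert stat.pvalue < 0.01


class TestRunCohort:
    def test_row_count_and_round_trip(self, pentagon, tmp_path):
        df = tl.run_cohort(pentagon, [1.0, 2.0], 3, 4, seed=0)
        assert len(df) == 2 * 3 * 4
        path = tl.write_trials_csv(df, tmp_path / "trials.csv")
        loaded = tl.read_trials_csv(path)
        assert list(loaded["sequence"]) == list(df["sequence"])
        assert np.allclose(loaded["distance"], df["distance"])

    def test_uniform_starts(self, pentagon):
        df = tl.run_cohort(pentagon, [1.0], 40, 10, seed=2)
        starts = df["sequence"].str.split("-").str[0].value_counts()
        from scipy.stats import chisquare

        assert chisquare(starts.to_numpy()).pvalue > 0.001

    def test_empirical_start_mode_requires_table(self, pentagon):
        with pytest.raises(ValueError, match="start"):
            tl.run_cohort(pentagon, [1.0], 2, 2, start_mode="empirical")

    def test_empirical_start_mode_uses_species_probs(self, pentagon):
        probs = {"vervet": {"1": 1.0}}
        df = tl.run_cohort(
            pentagon, [1.0], 5, 4, start_mode="empirical",
            species_start_probs=probs, seed=4,
        )
        assert (df["sequence"].str.split("-").str[0] == "1").all()
        assert set(df["species"]) == {"vervet"}


class TestConvergence:
    def test_pentagon_strong_reinforcement_locks(self, pentagon):
        opt = tl.optimal_open_path(pentagon).length
        locks = []
        for a in range(20):
            recs = tl.run_agent(pentagon, 2.0, 120, seed=(42, a))
            locks.append(tl.convergence_trial(recs, opt))
        assert np.median(locks) <= 100
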