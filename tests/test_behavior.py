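import numpy as np
import pytest

from emobook import ModelParams, init_population
from emobook.behavior import (action_distribution, check_grouping,
                              counter_attack_probability,
                              execute_movement_step, maybe_scan,
                              perceive_candidates, win_probability)
from emobook.core import NONE, Activity, MoveKind, torus_distance


def empty_pop(n=20, **kwargs):
    """Population with everyone parked far away from agent 0."""
    params = ModelParams(n_agents=n, **kwargs)
    pop = init_population(params, np.random.default_rng(0))
    pop.pos[:] = np.linspace(120, 260, n)[:, None]  # spread along diagonal
    pop.pos[0] = (10.0, 10.0)
    pop.heading[:] = 0.0
    return pop


def place(pop, i, x, y):
    pop.pos[i] = (x % pop.params.world_size, y % pop.params.world_size)


class TestPerception:
    def test_ten_nearest_of_twelve_in_view(self):
        pop = empty_pop()
        for k in range(1, 13):
            place(pop, k, 10.0 + 2.0 * k, 10.0)  # straight ahead
        cands = perceive_candidates(pop, 0)
        assert len(cands) == 10
        assert set(cands.ids) == set(range(1, 11))
        assert np.all(np.diff(cands.dists) >= 0)

    def test_close_agent_behind_is_percieved(self):
        pop = empty_pop()
        place(pop, 1, 9.5, 10.0)  # 0.5 m directly behind (heading +x)
        cands = perceive_candidates(pop, 0)
        assert 1 in cands.ids

    def test_agent_beyond_max_dist_excluded(self):
        pop = empty_pop()
        place(pop, 1, 70.0, 10.0)  # 60 m dead ahead
        cands = perceive_candidates(pop, 0)
        assert 1 not in cands.ids

    def test_agent_outside_view_angle_excluded(self):
        pop = empty_pop()
        place(pop, 1, 10.0, 20.0)   # 10 m away at 90 degrees off heading
        assert 1 not in perceive_candidates(pop, 0).ids
        pop.view[0] = 360.0          # scanning widens the view
        assert 1 in perceive_candidates(pop, 0).ids


class TestGrouping:
    def test_triggered_when_fewer_than_three_near(self, rng):
        pop = empty_pop()
        place(pop, 1, 15.0, 10.0)
        place(pop, 2, 10.0, 15.0)
        # remaining agents sit 120+ m away -> also "too far" criterion
        assert check_grouping(pop, 0, rng) is not None

    def test_triggered_when_any_member_beyond_far_dist(self, rng):
        pop = empty_pop(n=5)
        for k in (1, 2, 3):
            place(pop, k, 10.0 + 3 * k, 10.0)
        place(pop, 4, 10.0 + 120.0, 10.0)  # 120 m away
        assert check_grouping(pop, 0, rng) is not None

    def test_not_triggered_for_cohesive_group(self, rng):
        pop = empty_pop(n=7)
        for k in range(1, 6):
            place(pop, k, 10.0 + 2 * k, 10.0)
        place(pop, 6, 90.0, 10.0)  # 80 m: inside FAR_DIST
        assert check_grouping(pop, 0, rng) is None


class TestActionSelection:
    def _pair_setup(self, lps, like_a=0.9, like_b=0.1):
        """Ego with two equidistant equal-rank partners at 0.8 m."""
        pop = empty_pop(n=20, lps=lps)
        place(pop, 9, 10.8, 10.0)
        place(pop, 10, 9.2, 10.0)
        pop.dom[9] = pop.dom[10] = 0.5
        pop.like[0, 9] = like_a
        pop.like[0, 10] = like_b
        pop.like_time[0, :] = pop.last_update[0]
        return pop

    def test_probabilities_sum_to_one(self):
        pop = self._pair_setup(0.5)
        dist = action_distribution(pop, 0, perceive_candidates(pop, 0),
                                   pop.params)
        assert dist.probs.sum() == pytest.approx(1.0)
        assert np.all(dist.probs >= 0)

    def test_null_model_ignores_like(self):
        ref = None
        for like_a, like_b in [(0.9, 0.1), (0.0, 0.0), (1.0, 1.0)]:
            pop = self._pair_setup(0.0, like_a, like_b)
            dist = action_distribution(pop, 0, perceive_candidates(pop, 0),
                                       pop.params)
            probs = dict(zip(zip(dist.behaviors, dist.targets), dist.probs))
            if ref is None:
                ref = probs
            else:
                assert probs.keys() == ref.keys()
                for key in ref:
                    assert probs[key] == pytest.approx(ref[key])
        pop = self._pair_setup(0.0)
        pop.like_reads = 0
        action_distribution(pop, 0, perceive_candidates(pop, 0), pop.params)
        assert pop.like_reads == 0

    def test_selectivity_sharpens_partner_choice(self):
        def groom_odds(lps):
            pop = self._pair_setup(lps)
            dist = action_distribution(pop, 0, perceive_candidates(pop, 0),
                                       pop.params)
            p = dict(zip(zip(dist.behaviors, dist.targets), dist.probs))
            return p[("groom", 9)] / p[("groom", 10)]

        assert groom_odds(0.99) > groom_odds(0.5) > groom_odds(0.0)
        assert groom_odds(0.0) == pytest.approx(1.0)

    def test_sampling_matches_analytic_distribution(self, rng):
        # Monte-Carlo oracle: empirical frequencies over 1e5 draws agree
        # with the analytic distribution within 3 standard errors
        pop = self._pair_setup(0.9)
        pop.arousal[0] = 0.6
        dist = action_distribution(pop, 0, perceive_candidates(pop, 0),
                                   pop.params)
        n_draws = 100_000
        counts = np.bincount(
            rng.choice(len(dist.probs), size=n_draws, p=dist.probs),
            minlength=len(dist.probs))
        freq = counts / n_draws
        se = np.sqrt(dist.probs * (1 - dist.probs) / n_draws)
        assert np.all(np.abs(freq - dist.probs) <= 3 * se + 1e-9)

    def test_distance_gates_respected(self):
        pop = empty_pop(n=20)
        place(pop, 1, 13.0, 10.0)    # 3 m: signal range, not interact
        place(pop, 2, 40.0, 10.0)    # 30 m: approach range only
        dist = action_distribution(pop, 0, perceive_candidates(pop, 0),
                                   pop.params)
        pairs = set(zip(dist.behaviors, dist.targets))
        assert ("groom", 1) not in pairs
        assert ("affil_signal", 1) in pairs
        assert ("approach", 2) in pairs
        assert ("affil_signal", 2) not in pairs
        assert ("attack", 2) not in pairs

    def test_rest_probability_falls_with_arousal(self):
        pop = self._pair_setup(0.5)
        def p_rest(arousal):
            pop.arousal[0] = arousal
            d = action_distribution(pop, 0, perceive_candidates(pop, 0),
                                    pop.params)
            return d.probs[d.behaviors.index("rest")]
        assert p_rest(0.09) > p_rest(0.5) > p_rest(1.0)


class TestMovement:
    def test_step_displacement(self, rng):
        pop = empty_pop(n=3)
        place(pop, 1, 40.0, 10.0)
        pop.activity[0] = Activity.MOVE
        pop.move_kind[0] = MoveKind.APPROACH
        pop.move_target[0] = 1
        start = pop.pos[0].copy()
        execute_movement_step(pop, 0, 3.0, rng)
        moved = torus_distance(start, pop.pos[0], 300.0)
        assert moved == pytest.approx(1.8)   # 0.6 m/s x 3 s

    def test_approach_stops_at_interaction_distance(self, rng):
        pop = empty_pop(n=3)
        place(pop, 1, 12.0, 10.0)   # 2 m ahead
        pop.activity[0] = Activity.MOVE
        pop.move_kind[0] = MoveKind.APPROACH
        pop.move_target[0] = 1
        arrived = execute_movement_step(pop, 0, 3.0, rng)
        assert arrived
        assert torus_distance(pop.pos[0], pop.pos[1], 300.0) <= 1.0 + 1e-9

    def test_avoid_ends_beyond_personal_distance(self, rng):
        pop = empty_pop(n=3)
        place(pop, 1, 11.0, 10.0)
        pop.activity[0] = Activity.MOVE
        pop.move_kind[0] = MoveKind.AVOID
        pop.move_target[0] = 1
        for _ in range(10):
            if execute_movement_step(pop, 0, 3.0, rng):
                break
        assert torus_distance(pop.pos[0], pop.pos[1], 300.0) > 5.0

    def test_random_walk_is_not_straight(self, rng):
        pop = empty_pop(n=3)
        pop.activity[0] = Activity.MOVE
        pop.move_kind[0] = MoveKind.RANDOM_WALK
        start = pop.pos[0].copy()
        steps = 200
        for _ in range(steps):
            execute_movement_step(pop, 0, 3.0, rng)
        displacement = torus_distance(start, pop.pos[0], 300.0)
        assert displacement < steps * 1.8   # shorter than the path length


class TestAggression:
    def test_equal_rank_is_a_coin_flip(self):
        assert win_probability(0.5, 0.5, 4.0) == pytest.approx(0.5)
        assert counter_attack_probability(0.5, 0.5, 4.0) == pytest.approx(0.5)

    def test_sigmoid_value(self):
        assert win_probability(0.8, 0.3, 4.0) == pytest.approx(
            1.0 / (1.0 + np.exp(-2.0)))

    def test_win_chances_are_complementary(self, rng):
        for _ in range(50):
            di, dj = rng.uniform(0.05, 1.0, size=2)
            assert win_probability(di, dj, 4.0) + win_probability(
                dj, di, 4.0) == pytest.approx(1.0)

    def test_counter_attack_more_likely_against_lower_ranking(self):
        # victim dominance 0.8; attacker below vs above
        assert (counter_attack_probability(0.8, 0.2, 4.0)
                > counter_attack_probability(0.8, 0.8, 4.0)
                > counter_attack_probability(0.8, 1.0, 4.0))


class TestScanning:
    def test_refused_unless_resting(self, rng):
        pop = empty_pop(n=3)
        pop.activity[0] = Activity.MOVE
        with pytest.raises(ValueError):
            maybe_scan(pop, 0, rng)

    def test_probability_increases_with_arousal(self):
        pop = empty_pop(n=3)
        pop.activity[0] = Activity.REST
        def scan_rate(arousal, n=2000):
            rng = np.random.default_rng(99)
            hits = 0
            for _ in range(n):
                pop.arousal[0] = arousal
                pop.view[0] = 120.0
                hits += maybe_scan(pop, 0, rng)
            return hits / n
        assert scan_rate(1.0) > scan_rate(0.09)
        pop.arousal[0] = 1.0
        pop.view[0] = 120.0
        rng = np.random.default_rng(1)
        assert maybe_scan(pop, 0, rng)   # arousal 1.0 always scans
        assert pop.view[0] == 360.0
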