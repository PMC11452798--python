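"""Synthetic experiment sessions: protocol invariants, bots, payoffs, I/O."""

import numpy as np
import pandas as pd
import pytest

from innodiff.sessions import (
    Behavior,
    SettingSpec,
    assign_displays,
    bot_decision,
    compute_payoffs,
    curve_from_records,
    default_settings,
    frame_to_records,
    generate_session,
    initialize_session,
    read_session_csv,
    records_to_frame,
    simulate_setting,
    write_session_csv,
)

SETTINGS = default_settings()


class TestInitialize:
    def test_minority_count(self, net31):
        state = initialize_session(net31, 4, seed=7)
        assert state.sum() == 4 and len(state) == 31
        assert set(np.unique(state)) == {0, 1}

    def test_deterministic(self, net31):
        assert np.array_equal(initialize_session(net31, 4, 7), initialize_session(net31, 4, 7))

    @pytest.mark.parametrize("bad", [0, 31, 40])
    def test_degenerate_minority_rejected(self, net31, bad):
        with pytest.raises(ValueError):
            initialize_session(net31, bad, 7)


class TestDisplays:
    def test_setting_one_shows_no_distant_peers(self, net31, dist31):
        displays = assign_displays(net31, dist31, SETTINGS[0], seed=3)
        assert all(len(direct) == 2 and distant == () for direct, distant in displays.values())

    @pytest.mark.parametrize("spec", SETTINGS[1:], ids=lambda s: f"setting_{s.index}")
    def test_distant_peers_at_exact_distance(self, net31, dist31, spec):
        displays = assign_displays(net31, dist31, spec, seed=3)
        for node, (direct, distant) in displays.items():
            assert all(dist31.distance(node, p) == 1 for p in direct)
            assert len(distant) == 2
            assert all(dist31.distance(node, p) == spec.display_distance for p in distant)

    def test_deterministic(self, net31, dist31):
        a = assign_displays(net31, dist31, SETTINGS[2], seed=9)
        b = assign_displays(net31, dist31, SETTINGS[2], seed=9)
        assert a == b

    def test_insufficient_circle_reported(self):
        from innodiff.network import SocialNetwork, distance_matrix

        # 4-cycle: distance-2 circle has a single node
        cyc = SocialNetwork(
            nodes=(0, 1, 2, 3),
            edges=frozenset(frozenset((i, (i + 1) % 4)) for i in range(4)),
        )
        with pytest.raises(ValueError, match="distance 2"):
            assign_displays(cyc, distance_matrix(cyc), SETTINGS[1], seed=0)


class TestBotPolicy:
    def test_majority_branch_forced_mode(self):
        class Forced:
            def random(self):
                return 0.9  # majority branch

            def integers(self, *a, **k):  # pragma: no cover - tie path unused
                raise AssertionError

        assert bot_decision([1, 1, 1, 0], Forced()) == 1
        assert bot_decision([0, 0, 1], Forced()) == 0

    def test_all_innovation_display_frequency(self):
        # 0.5·1 (follow unanimous display) + 0.5·0.5 (random) = 0.75
        rng = np.random.default_rng(123)
        freq = np.mean([bot_decision([1, 1, 1, 1], rng) for _ in range(10_000)])
        assert freq == pytest.approx(0.75, abs=0.02)

    def test_empty_display_rejected(self):
        with pytest.raises(ValueError):
            bot_decision([], np.random.default_rng(0))


class TestSimulate:
    def test_deterministic_per_seed(self, net31, dist31):
        init = initialize_session(net31, 4, 5)
        a = simulate_setting(net31, SETTINGS[1], init, 77, dist=dist31)
        b = simulate_setting(net31, SETTINGS[1], init, 77, dist=dist31)
        assert a.records == b.records
        assert np.array_equal(a.curve.proportion, b.curve.proportion)

    def test_display_invariants_in_records(self, net31, dist31):
        init = initialize_session(net31, 4, 5)
        res = simulate_setting(net31, SETTINGS[2], init, 77, dist=dist31)
        for rec in res.records:
            assert len(rec.displayed_direct) == 2
            assert all(dist31.distance(rec.node, p) == 1 for p, _ in rec.displayed_direct)
            assert all(dist31.distance(rec.node, p) == 3 for p, _ in rec.displayed_distant)

    def test_curve_starts_at_minority_fraction_and_is_cumulative(self, net31, dist31):
        init = initialize_session(net31, 4, 5)
        res = simulate_setting(net31, SETTINGS[1], init, 77, dist=dist31)
        assert res.curve.proportion[0] == pytest.approx(4 / 31)
        assert (np.diff(res.curve.proportion) >= 0).all()

    def test_stubborn_agent_blocks_consensus(self, net31, dist31):
        init = initialize_session(net31, 4, 5)
        stub = int(net31.nodes[np.flatnonzero(init == 0)[0]])
        res = simulate_setting(
            net31, SETTINGS[1], init, 77,
            behavior=Behavior(theta=-5.0),  # everyone else adopts immediately
            roles={stub: "stubborn"}, dist=dist31,
        )
        assert res.consensus_round is None
        assert res.curve.proportion[-1] == pytest.approx(30 / 31)

    def test_eager_humans_reach_consensus_by_round_two(self, net31, dist31):
        init = initialize_session(net31, 4, 5)
        res = simulate_setting(net31, SETTINGS[0], init, 77,
                               behavior=Behavior(theta=-8.0), dist=dist31)
        assert res.consensus_round == 2

    def test_distant_information_accelerates_consensus(self, net31, dist31):
        """More responsiveness to the distant display (larger beta) never
        slows consensus on average — the qualitative acceleration effect."""
        def mean_rounds(beta, n=30):
            tot = 0
            for s in range(n):
                init = initialize_session(net31, 4, 400 + s)
                res = simulate_setting(net31, SETTINGS[1], init, 800 + s,
                                       behavior=Behavior(beta=beta), dist=dist31)
                tot += res.consensus_round or SETTINGS[1].max_rounds + 1
            return tot / n

        assert mean_rounds(6.0) <= mean_rounds(0.0)

    def test_default_sessions_reach_consensus(self, net31, dist31):
        """Stubborn-free sessions under the default behaviour reach
        consensus within the round cap in ≥ 90% of seeded runs (the
        indirect-information settings are the generator's home regime)."""
        hits = 0
        n = 100
        for s in range(n):
            init = initialize_session(net31, 4, 10_000 + s)
            res = simulate_setting(net31, SETTINGS[1], init, 20_000 + s, dist=dist31)
            hits += res.consensus_round is not None
        assert hits >= 0.9 * n


class TestPayoffs:
    def test_consensus_bonus(self, net31, dist31):
        init = initialize_session(net31, 4, 5)
        res = simulate_setting(net31, SETTINGS[0], init, 77,
                               behavior=Behavior(theta=-8.0), dist=dist31)
        assert res.consensus_round == 2
        pay = compute_payoffs(res)
        # 2 active rounds + 5·(15−2) bonus
        assert all(p == 2 + 5 * 13 for p in pay.values())

    def test_no_consensus_no_bonus(self, net31, dist31):
        init = initialize_session(net31, 4, 5)
        stub = int(net31.nodes[np.flatnonzero(init == 0)[0]])
        spec = SettingSpec("I", None, max_rounds=13)
        res = simulate_setting(net31, spec, init, 77,
                               behavior=Behavior(theta=-5.0),
                               roles={stub: "stubborn"}, dist=dist31)
        assert res.consensus_round is None
        assert all(p == 13 for p in compute_payoffs(res).values())

    def test_consensus_at_cap_gives_zero_bonus(self):
        from innodiff.sessions import SettingResult
        from innodiff.diffusion import AdoptionCurve
        from innodiff.sessions import RoundRecord

        recs = [
            RoundRecord("S", "I", rnd, 0, "human", 1, ((1, 1), (2, 1)), ())
            for rnd in range(1, 16)
        ]
        res = SettingResult(
            spec=SettingSpec("I", None), records=recs,
            curve=AdoptionCurve(np.arange(1, 16), np.ones(15)),
            consensus_round=15, initial=np.array([1]), roles={0: "human"},
        )
        assert compute_payoffs(res)[0] == 15


class TestSessionIO:
    def test_round_trip(self, net31, dist31, tmp_path):
        sess = generate_session(net31, 99, dist=dist31)
        path = tmp_path / "sessions.csv"
        write_session_csv([sess], path)
        df = read_session_csv(path)
        back = frame_to_records(df[df["setting"] == "II"])
        orig = next(r.records for r in sess.settings if r.spec.index == "II")
        assert back == orig

    def test_full_generation_deterministic(self, net31, dist31, tmp_path):
        a = records_to_frame(
            [r for s in generate_session(net31, 99, dist=dist31).settings for r in s.records]
        )
        b = records_to_frame(
            [r for s in generate_session(net31, 99, dist=dist31).settings for r in s.records]
        )
        pd.testing.assert_frame_equal(a, b)

    def test_curve_from_records_matches_simulated_curve(self, net31, dist31):
        sess = generate_session(net31, 99, dist=dist31)
        res = sess.settings[1]
        df = records_to_frame(res.records)
        curve = curve_from_records(df)
        assert np.allclose(curve.proportion, res.curve.proportion)
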