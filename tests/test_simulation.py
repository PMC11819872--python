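"""Field simulation: movement, alert-only traffic, buffering, determinism."""

import numpy as np
import pytest

from vitalfield.classify import load_model
from vitalfield.cohort import EpisodeSpec
from vitalfield.secure import KeyConfig, encrypt_message
from vitalfield.simulation import (
    BaseStation,
    SimConfig,
    SoldierNode,
    move,
    run_simulation,
)
from vitalfield.features import FEATURE_COLUMNS

from .conftest import make_constant_series


class _FixedStep:
    """Stub RNG yielding a prescribed step, for reflection arithmetic."""

    def __init__(self, dx, dy):
        self.step = np.array([dx, dy])

    def normal(self, loc, scale, size):
        return self.step


class TestMove:
    def test_zero_sd_keeps_position(self):
        rng = np.random.default_rng(0)
        assert move((12.0, 34.0), 0.0, rng) == (12.0, 34.0)

    def test_reflection_arithmetic(self):
        x, y = move((50.0, 50.0), 2.0, _FixedStep(53.0, 0.0))
        assert x == pytest.approx(97.0)  # 103 reflects to 97
        assert y == pytest.approx(50.0)
        x, _ = move((5.0, 50.0), 2.0, _FixedStep(-8.0, 0.0))
        assert x == pytest.approx(3.0)  # -3 reflects to 3

    def test_long_walk_stays_in_bounds(self):
        rng = np.random.default_rng(1)
        pos = (50.0, 50.0)
        for _ in range(100_000):
            pos = move(pos, 50.0, rng)
            assert 0.0 <= pos[0] <= 100.0 and 0.0 <= pos[1] <= 100.0


class TestStepNode:
    def test_constant_safe_vitals_emit_nothing(self, tiny_model_path, squad_key):
        model, _ = load_model(tiny_model_path, expected_features=list(FEATURE_COLUMNS))
        config = SimConfig(n_soldiers=1, n_ticks=100, seed=1)
        node = SoldierNode("N00", make_constant_series(n=100), model, config, squad_key, seed=1)
        for tick in range(1, 101):
            state, envelope = node.step(tick)
            assert state == "normal"
            assert envelope is None
        assert node.seq == 0

    def test_forced_desaturation_raises_an_alert(self, tiny_model_path, squad_key):
        config = SimConfig(
            n_soldiers=2, n_ticks=60, seed=5,
            forced_episodes={"N01": [EpisodeSpec("desaturation", 20, 25, 12.0)]},
        )
        result = run_simulation(config, tiny_model_path, squad_key)
        alert_ticks = [
            e["tick"] for e in result.events if e["node"] == "N01" and e["emitted"]
        ]
        assert alert_ticks, "desaturation episode produced no alert"
        assert any(21 <= t <= 45 for t in alert_ticks)
        assert result.base.roster["N01"]["state"] == "abnormal"

    def test_traffic_only_on_abnormal_predictions(self, tiny_model_path, squad_key):
        config = SimConfig(n_soldiers=4, n_ticks=80, episode_rate=2.0, seed=6)
        result = run_simulation(config, tiny_model_path, squad_key)
        for event in result.events:
            assert event["emitted"] == (1 if event["state"] == "abnormal" else 0)


class TestDelivery:
    def outage_config(self):
        return SimConfig(
            n_soldiers=2, n_ticks=60, seed=8,
            forced_episodes={"N00": [EpisodeSpec("desaturation", 9, 30, 12.0)]},
            outages={"N00": [(15, 34)]},
        )

    def test_outage_buffers_then_flushes_in_order(self, tiny_model_path, squad_key):
        result = run_simulation(self.outage_config(), tiny_model_path, squad_key)
        events = [e for e in result.events if e["node"] == "N00"]
        during = [e for e in events if 15 <= e["tick"] <= 34]
        assert all(e["delivered"] == [] for e in during)
        emitted_during = sum(e["emitted"] for e in during)
        assert emitted_during > 0, "scenario produced no alerts during the outage"
        flush = next(e for e in events if e["tick"] == 35)
        assert len(flush["delivered"]) >= emitted_during
        assert flush["delivered"] == sorted(flush["delivered"])
        seqs = [s for e in events for s in e["delivered"]]
        assert seqs == sorted(seqs), "per-sender delivery order was not preserved"

    def test_alert_conservation(self, tiny_model_path, squad_key):
        result = run_simulation(self.outage_config(), tiny_model_path, squad_key)
        emitted = sum(e["emitted"] for e in result.events)
        delivered = sum(len(e["delivered"]) for e in result.events)
        final_buffered = sum(len(n.outbox) for n in result.nodes.values())
        assert emitted == delivered + final_buffered + result.base.dropped

    def test_replayed_envelope_is_flagged_and_roster_unchanged(self, squad_key):
        base = BaseStation(key=squad_key)
        base.register("N00")
        from vitalfield.simulation import AlertMessage

        alert = AlertMessage("N00", 5.0, 130.0, 85.0, 30.0, 128.0, "abnormal", 10.0, 20.0)
        env = encrypt_message(alert.to_json(), squad_key, "N00", seq=1)
        assert base.receive(env, tick=1) is not None
        roster_before = dict(base.roster["N00"])
        assert base.receive(env, tick=2) is None
        assert base.replays == [("N00", 1, 2)]
        assert base.roster["N00"] == roster_before

    def test_tampered_envelope_is_dropped_and_counted(self, squad_key):
        base = BaseStation(key=squad_key)
        base.register("N00")
        env = encrypt_message(b'{"x": 1}', squad_key, "N00", seq=1)
        broken = type(env)(env.sender_id, env.seq, env.nonce, env.ciphertext, bytes(16))
        assert base.receive(broken, tick=1) is None
        assert base.dropped == 1


class TestRunSimulation:
    def test_roster_tracks_liveness_for_all_nodes(self, tiny_model_path, squad_key):
        config = SimConfig(n_soldiers=8, n_ticks=50, seed=2)
        result = run_simulation(config, tiny_model_path, squad_key)
        assert len(result.base.roster) == 8
        assert all(entry["last_tick"] == 50 for entry in result.base.roster.values())

    def test_event_logs_are_seed_deterministic(self, tiny_model_path, squad_key):
        config = SimConfig(n_soldiers=3, n_ticks=40, episode_rate=1.0, seed=12)
        r1 = run_simulation(config, tiny_model_path, squad_key)
        r2 = run_simulation(config, tiny_model_path, squad_key)
        assert r1.events == r2.events
        assert r1.base.roster == r2.base.roster

    def test_logical_duration(self, tiny_model_path, squad_key):
        config = SimConfig(n_soldiers=1, n_ticks=30, seed=3)
        result = run_simulation(config, tiny_model_path, squad_key)
        assert result.events[-1]["tick"] * config.tick_seconds == 150.0

    def test_peers_learn_about_an_abnormal_teammate(self, tiny_model_path, squad_key):
        config = SimConfig(
            n_soldiers=3, n_ticks=60, seed=4,
            forced_episodes={"N02": [EpisodeSpec("desaturation", 10, 30, 12.0)]},
        )
        result = run_simulation(config, tiny_model_path, squad_key)
        assert result.nodes["N00"].peer_view.get("N02") == "abnormal"
        assert result.nodes["N01"].peer_view.get("N02") == "abnormal"
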