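"""Multi-node field-monitoring simulation on a logical 5-second clock.

Each soldier node owns a synthetic vitals stream (same generator and
noise models as the offline pipeline), a ring buffer of recent noisy
samples, and the persisted classifier.  Per tick a node ingests the next
sample, assembles its feature row from trailing windows over the buffer,
predicts its state, moves by a reflected Gaussian random walk on the
0-100 map, and — only when the prediction is abnormal — seals one alert
envelope addressed to the base station and all peers.  Link outages
buffer outgoing envelopes in FIFO order; on reconnection the backlog is
flushed before new traffic.  The base station verifies per-sender
sequence monotonicity (flagging replays and gaps) and maintains a squad
roster.

Execution is single-threaded on a logical clock with a deterministic
per-tick node order: node state is owned by its node and inter-node
effects travel only as messages, so the run is a pure function of
(config, seed, key).  Roster liveness (`last_tick`) is updated by the
link layer while a node's link is up; alert envelopes are the only
payload traffic, so all-normal runs generate zero messages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from collections import deque

import numpy as np
import pandas as pd

from ._seeds import child_seed
from .cohort import EpisodeSpec, GeneratorConfig, ValidationError, generate_cohort, inject_episodes
from .classify import load_model
from .features import FEATURE_COLUMNS, MIN_FFT_HISTORY, dominant_frequency
from .noise import NoiseConfig, apply_noise_profile
from .secure import KeyConfig, SecureEnvelope, TamperError, decrypt_message, encrypt_message

__all__ = ["SimConfig", "SoldierNode", "BaseStation", "AlertMessage", "move", "run_simulation", "SimResult"]

MAP_LO, MAP_HI = 0.0, 100.0


@dataclass(frozen=True)
class AlertMessage:
    """Abnormal-state notification: vitals snapshot plus position."""

    node_id: str
    tick_time: float          # seconds on the logical clock
    hr: float
    spo2: float
    resp: float
    pulse: float
    state: str
    x: float
    y: float

    def to_json(self) -> bytes:
        return json.dumps(self.__dict__, sort_keys=True).encode()

    @classmethod
    def from_json(cls, raw: bytes) -> "AlertMessage":
        return cls(**json.loads(raw))


@dataclass(frozen=True)
class SimConfig:
    """Scenario parameters of one simulation run."""

    n_soldiers: int = 8
    tick_seconds: float = 5.0
    n_ticks: int = 100
    movement_step_sd: float = 2.0    # map units per tick
    buffer_capacity: int = 64
    smoothing_window: int = 5
    episode_rate: float = 0.0        # expected abnormal events per node stream
    #: node_id -> list of (first_tick, last_tick) inclusive outage windows
    outages: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    #: node_id -> forced episode specs on the node's stream (tick units)
    forced_episodes: dict[str, list[EpisodeSpec]] = field(default_factory=dict)
    #: measurement-noise override; None applies the default noise profile
    noise: NoiseConfig | None = None
    seed: int = 42

    def validate(self) -> None:
        if self.n_soldiers < 1:
            raise ValidationError("n_soldiers must be >= 1")
        if self.tick_seconds <= 0:
            raise ValidationError("tick_seconds must be > 0")
        if self.n_ticks < 1:
            raise ValidationError("n_ticks must be >= 1")
        if self.movement_step_sd < 0:
            raise ValidationError("movement_step_sd must be >= 0")
        if self.buffer_capacity < MIN_FFT_HISTORY:
            raise ValidationError(f"buffer_capacity must be >= {MIN_FFT_HISTORY}")


def move(position: tuple[float, float], step_sd: float, rng: np.random.Generator) -> tuple[float, float]:
    """One Gaussian random-walk step, reflected at the map boundaries."""

    def reflect(v: float) -> float:
        r = v % (2 * MAP_HI)
        return 2 * MAP_HI - r if r > MAP_HI else r

    x, y = position
    if step_sd == 0:
        return x, y
    dx, dy = rng.normal(0.0, step_sd, size=2)
    return reflect(x + dx), reflect(y + dy)


class SoldierNode:
    """One soldier: vitals stream, local classifier, outbox, position."""

    def __init__(self, node_id, series, model, config: SimConfig, key: KeyConfig, seed: int):
        self.node_id = node_id
        self.series = series          # noisy stream, one sample per tick
        self.model = model
        self.config = config
        self.key = key
        self.buffer: deque = deque(maxlen=config.buffer_capacity)
        self.outbox: deque = deque()
        self.seq = 0
        self.rng = np.random.default_rng(child_seed(seed, "move", node_id))
        self._nonce_rng = np.random.default_rng(child_seed(seed, "nonce", node_id))
        start = np.random.default_rng(child_seed(seed, "pos", node_id)).uniform(MAP_LO, MAP_HI, 2)
        self.position = (float(start[0]), float(start[1]))
        self.peer_view: dict[str, str] = {}

    def link_up(self, tick: int) -> bool:
        return not any(a <= tick <= b for a, b in self.config.outages.get(self.node_id, []))

    def _feature_row(self) -> pd.DataFrame:
        buf = np.asarray(self.buffer)  # columns: hr, spo2, resp, pulse (noisy)
        w = self.config.smoothing_window
        names = ("HR", "SpO2", "RESP", "Pulse")
        row = {}
        for j, name in enumerate(names):
            x = buf[:, j]
            row[f"{name}_noisy"] = x[-1]
            row[f"{name}_smooth"] = x[-min(w, len(x)):].mean()
            row[f"{name}_fft"] = dominant_frequency(x)
        s = self.series
        row.update(
            Age=s.profile.age,
            Gender=0 if s.profile.gender == "male" else 1,
            Altitude=s.context.altitude,
            Temperature=s.context.temperature,
            Activity_level=s.context.activity_level,
        )
        return pd.DataFrame([row], columns=FEATURE_COLUMNS)

    def step(self, tick: int) -> tuple[str, SecureEnvelope | None]:
        """Advance one tick: ingest, classify, move; maybe emit an alert."""
        i = tick - 1  # stream index; tick counts from 1
        self.buffer.append(
            (self.series.noisy["hr"][i], self.series.noisy["spo2"][i],
             self.series.noisy["resp"][i], self.series.noisy["pulse"][i])
        )
        pred = int(self.model.predict(self._feature_row())[0])
        state = "abnormal" if pred == 1 else "normal"
        envelope = None
        if state == "abnormal":
            hr, spo2, resp, pulse = self.buffer[-1]
            alert = AlertMessage(
                node_id=self.node_id,
                tick_time=tick * self.config.tick_seconds,
                hr=float(hr), spo2=float(spo2), resp=float(resp), pulse=float(pulse),
                state=state, x=self.position[0], y=self.position[1],
            )
            self.seq += 1
            envelope = encrypt_message(
                alert.to_json(), self.key, self.node_id, self.seq,
                nonce_source=lambda n: self._nonce_rng.bytes(n),
            )
        self.position = move(self.position, self.config.movement_step_sd, self.rng)
        return state, envelope


@dataclass
class BaseStation:
    """Command-center view of the squad."""

    key: KeyConfig
    roster: dict = field(default_factory=dict)
    received: list = field(default_factory=list)
    replays: list = field(default_factory=list)
    gaps: list = field(default_factory=list)
    dropped: int = 0
    _last_seq: dict = field(default_factory=dict)

    def register(self, node_id: str) -> None:
        self.roster[node_id] = {"state": "normal", "position": None, "last_tick": 0, "last_alert_tick": None}

    def heartbeat(self, node_id: str, tick: int) -> None:
        """Link-layer liveness: no payload traffic involved."""
        self.roster[node_id]["last_tick"] = tick

    def receive(self, envelope: SecureEnvelope, tick: int) -> AlertMessage | None:
        try:
            raw = decrypt_message(envelope, self.key)
        except TamperError:
            self.dropped += 1
            return None
        last = self._last_seq.get(envelope.sender_id, 0)
        if envelope.seq <= last:
            self.replays.append((envelope.sender_id, envelope.seq, tick))
            return None
        if envelope.seq > last + 1:
            self.gaps.append((envelope.sender_id, last + 1, envelope.seq, tick))
        self._last_seq[envelope.sender_id] = envelope.seq
        alert = AlertMessage.from_json(raw)
        entry = self.roster[alert.node_id]
        entry.update(state=alert.state, position=(alert.x, alert.y), last_alert_tick=tick)
        self.received.append(alert)
        return alert


@dataclass
class SimResult:
    """Event log plus final base-station and node states."""

    events: list[dict]
    base: BaseStation
    nodes: dict[str, SoldierNode]
    config: SimConfig

    def summary(self) -> str:
        n_alerts = len(self.base.received)
        abnormal_nodes = sorted(
            nid for nid, entry in self.base.roster.items() if entry["state"] == "abnormal"
        )
        return (
            f"{self.config.n_ticks} ticks x {self.config.tick_seconds:g} s logical clock, "
            f"{self.config.n_soldiers} nodes\n"
            f"alerts delivered to base: {n_alerts}; replays flagged: {len(self.base.replays)}; "
            f"tamper-dropped: {self.base.dropped}\n"
            f"nodes last reported abnormal: {', '.join(abnormal_nodes) or 'none'}\n"
        )


def _build_streams(config: SimConfig, seed: int):
    """One generator stream per node, noise applied, forced episodes injected."""
    gen = GeneratorConfig(
        n_subjects=config.n_soldiers,
        samples_per_subject=config.n_ticks,
        episode_rate=config.episode_rate,
        seed=child_seed(seed, "streams"),
    )
    cohort = generate_cohort(gen)
    node_ids = [f"N{i:02d}" for i in range(config.n_soldiers)]
    series_by_node = {}
    for node_id, series in zip(node_ids, cohort):
        for spec in config.forced_episodes.get(node_id, []):
            series = inject_episodes(series, [spec])
        series_by_node[node_id] = series
    noise_cfg = config.noise or NoiseConfig(seed=child_seed(seed, "noise"))
    apply_noise_profile(list(series_by_node.values()), noise_cfg)
    return series_by_node


def run_simulation(config: SimConfig, model_path: str, key: KeyConfig) -> SimResult:
    """Run the full scenario and return the event log and final states.

    Nodes progress independently within a tick (no cross-node reads of
    same-tick state); deliveries are processed in deterministic node
    order after every node has stepped.  The logical clock advances
    ``n_ticks * tick_seconds`` seconds with no wall-clock sleeping.
    """
    config.validate()
    model, manifest = load_model(model_path, expected_features=list(FEATURE_COLUMNS))
    streams = _build_streams(config, config.seed)
    nodes = {
        nid: SoldierNode(nid, series, model, config, key, config.seed)
        for nid, series in streams.items()
    }
    base = BaseStation(key=key)
    for nid in nodes:
        base.register(nid)

    events: list[dict] = []
    for tick in range(1, config.n_ticks + 1):
        stepped = [(nid, *nodes[nid].step(tick)) for nid in sorted(nodes)]
        for nid, state, envelope in stepped:
            node = nodes[nid]
            delivered: list[int] = []
            if envelope is not None:
                node.outbox.append(envelope)
            if node.link_up(tick):
                base.heartbeat(nid, tick)
                while node.outbox:
                    env = node.outbox.popleft()
                    alert = base.receive(env, tick)
                    delivered.append(env.seq)
                    if alert is not None:
                        for peer_id, peer in nodes.items():
                            if peer_id != nid:
                                peer.peer_view[alert.node_id] = alert.state
            events.append(
                {
                    "tick": tick,
                    "node": nid,
                    "state": state,
                    "position": [round(node.position[0], 6), round(node.position[1], 6)],
                    "emitted": int(envelope is not None),
                    "delivered": delivered,
                    "buffered": len(node.outbox),
                    "link_up": node.link_up(tick),
                }
            )
    return SimResult(events=events, base=base, nodes=nodes, config=config)
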