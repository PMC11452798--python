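"""Seeded generator of experiment-like adoption sessions.

Emulates the round-based colour-consensus protocol: 31 participants seated
on a fixed friendship network, 27 starting with the majority ("tradition")
colour and 4 with the minority ("innovation") colour.  A session runs four
informational settings; in setting I each participant sees the colours of
two of their direct neighbours, and in setting k (II–IV) additionally the
colours of two participants in their k-th circle of influence.  Rounds
proceed synchronously until global consensus or the setting's round cap
(13–15).  Inactive seats are played by bots (50% random colour, 50% follow
the displayed majority); stubborn agents never join the consensus colour.

Human choice is modelled with a logistic response to the displayed
information — the probability of choosing the innovation in a round is
σ(α·f_direct + β·f_distant + γ·adopted − θ), with f_* the innovation
fractions among displayed direct/distant peers.  The experiment this
emulates measures but does not model individual choice; the rule and its
default parameters are this package's construction (see docs/methods.md).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .diffusion import AdoptionCurve
from .network import DistanceMatrix, SocialNetwork, distance_matrix

log = logging.getLogger(__name__)

INNOVATION, TRADITION = 1, 0

#: Cosmetic colour pairs per setting, (minority, majority); internal state
#: is always binary innovation/tradition.
SETTING_COLORS = {
    "I": ("blue", "yellow"),
    "II": ("magenta", "green"),
    "III": ("orange", "red"),
    "IV": ("purple", "lilac"),
}

MAX_ROUNDS_CAP = 15


@dataclass(frozen=True)
class SettingSpec:
    """One informational treatment of a session."""

    index: str                       # "I".."IV"
    display_distance: int | None     # None for I, 2/3/4 for II-IV
    colors: tuple[str, str] = ("blue", "yellow")
    max_rounds: int = 15

    def __post_init__(self) -> None:
        if self.index not in SETTING_COLORS:
            raise ValueError(f"unknown setting {self.index!r}")
        if self.display_distance is not None and self.display_distance < 2:
            raise ValueError("display distance must be ≥ 2 (direct peers are always shown)")
        if not 13 <= self.max_rounds <= MAX_ROUNDS_CAP:
            raise ValueError(f"max_rounds must be in [13, {MAX_ROUNDS_CAP}]")


def default_settings(max_rounds: int = 15) -> list[SettingSpec]:
    """The four settings: I (direct only) and II–IV (direct + distance k)."""
    return [
        SettingSpec("I", None, SETTING_COLORS["I"], max_rounds),
        SettingSpec("II", 2, SETTING_COLORS["II"], max_rounds),
        SettingSpec("III", 3, SETTING_COLORS["III"], max_rounds),
        SettingSpec("IV", 4, SETTING_COLORS["IV"], max_rounds),
    ]


@dataclass(frozen=True)
class Behavior:
    """Parameters of the logistic human choice rule.

    alpha, beta weight the innovation fraction among displayed direct and
    distant peers; gamma rewards having already adopted (only relevant when
    ``cumulative`` is off, since with it adopters never revert); theta is
    the adoption resistance.  The distant weight decays with the displayed
    circle: at distance k the effective weight is beta·beta_decay^(k−2), so
    information from farther circles moves choices less — the qualitative
    pattern the coefficient fits are meant to recover.  ``dropout_prob`` is
    the per-round chance a human is inactive and replaced by a bot for that
    round.
    """

    alpha: float = 3.4
    beta: float = 3.0
    beta_decay: float = 0.6
    gamma: float = 2.0
    theta: float = 3.0
    cumulative: bool = True
    dropout_prob: float = 0.0

    def beta_at(self, k: int | None) -> float:
        if k is None:
            return 0.0
        return self.beta * self.beta_decay ** (k - 2)


@dataclass(frozen=True)
class AgentSpec:
    node: int
    role: str = "human"  # human | bot | stubborn

    def __post_init__(self) -> None:
        if self.role not in ("human", "bot", "stubborn"):
            raise ValueError(f"unknown role {self.role!r}")


@dataclass(frozen=True)
class RoundRecord:
    """One participant's state in one round of one setting."""

    session_id: str
    setting: str
    round: int
    node: int
    role: str
    chosen_color: int  # 1 = innovation, 0 = tradition
    displayed_direct: tuple[tuple[int, int], ...]
    displayed_distant: tuple[tuple[int, int], ...]
    active: bool = True


@dataclass(frozen=True)
class SettingResult:
    spec: SettingSpec
    records: list[RoundRecord]
    curve: AdoptionCurve
    consensus_round: int | None
    initial: np.ndarray
    roles: dict[int, str]


@dataclass(frozen=True)
class Session:
    session_id: str
    network: SocialNetwork
    settings: list[SettingResult]
    seed: int


# ---------------------------------------------------------------------------

def initialize_session(net: SocialNetwork, n_minority: int, seed: int) -> np.ndarray:
    """Assign the innovation colour to ``n_minority`` uniformly random seats.

    Returns the binary state vector in network node order (1 = innovation).
    """
    if not 1 <= n_minority < net.n:
        raise ValueError(f"n_minority must be in [1, {net.n - 1}], got {n_minority}")
    rng = np.random.default_rng(seed)
    state = np.zeros(net.n, dtype=int)
    state[rng.choice(net.n, size=n_minority, replace=False)] = INNOVATION
    return state


def assign_displays(
    net: SocialNetwork,
    dist: DistanceMatrix,
    spec: SettingSpec,
    seed: int,
) -> dict[int, tuple[tuple[int, ...], tuple[int, ...]]]:
    """Sample, per node, the 2 direct peers (and 2 distance-k peers for
    settings II–IV) whose colours the node will be shown.

    The sample is drawn once per setting and held fixed across rounds; the
    colours shown are refreshed every round.
    """
    rng = np.random.default_rng(seed)
    out: dict[int, tuple[tuple[int, ...], tuple[int, ...]]] = {}
    for node in net.nodes:
        direct = dist.nodes_at_distance(node, 1)
        if len(direct) < 2:
            raise ValueError(f"node {node} has only {len(direct)} neighbours at distance 1")
        direct_pick = tuple(rng.choice(direct, size=2, replace=False).tolist())
        distant_pick: tuple[int, ...] = ()
        if spec.display_distance is not None:
            k = spec.display_distance
            distant = dist.nodes_at_distance(node, k)
            if len(distant) < 2:
                raise ValueError(f"node {node} has only {len(distant)} nodes at distance {k}")
            distant_pick = tuple(rng.choice(distant, size=2, replace=False).tolist())
        out[node] = (direct_pick, distant_pick)
    return out


def bot_decision(displayed_colors: list[int] | tuple[int, ...], rng: np.random.Generator) -> int:
    """Bot policy: 50% uniformly random colour, 50% the displayed majority
    (majority ties broken uniformly at random)."""
    if len(displayed_colors) == 0:
        raise ValueError("bot needs at least one displayed colour")
    if rng.random() < 0.5:
        return int(rng.integers(2))
    k = sum(displayed_colors)
    if 2 * k == len(displayed_colors):
        return int(rng.integers(2))
    return INNOVATION if 2 * k > len(displayed_colors) else TRADITION


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_setting(
    net: SocialNetwork,
    spec: SettingSpec,
    initial: np.ndarray,
    seed: int,
    *,
    behavior: Behavior = Behavior(),
    roles: dict[int, str] | None = None,
    dist: DistanceMatrix | None = None,
    resample_displays: bool = False,
    session_id: str = "S1",
) -> SettingResult:
    """Run one setting to consensus or the round cap.

    ``roles`` maps node → "human"/"bot"/"stubborn" (default all human).
    Stubborn agents keep their initial colour throughout; adopters never
    revert while ``behavior.cumulative`` is on.  Deterministic per seed.
    """
    if dist is None:
        dist = distance_matrix(net)
    roles = dict(roles or {})
    for v in net.nodes:
        roles.setdefault(v, "human")
    rng = np.random.default_rng(seed)
    displays = assign_displays(net, dist, spec, int(rng.integers(2**31)))

    idx = {v: i for i, v in enumerate(net.nodes)}
    state = np.asarray(initial, dtype=int).copy()
    ever = state.copy()  # cumulative adopter flags
    records: list[RoundRecord] = []
    proportions = [ever.mean()]
    consensus_round: int | None = None

    def shown(node: int, colors: np.ndarray) -> tuple[tuple, tuple]:
        d_peers, k_peers = displays[node]
        return (
            tuple((p, int(colors[idx[p]])) for p in d_peers),
            tuple((p, int(colors[idx[p]])) for p in k_peers),
        )

    for v in net.nodes:
        dd, dk = shown(v, state)
        records.append(RoundRecord(session_id, spec.index, 1, v, roles[v], int(state[idx[v]]), dd, dk))

    for rnd in range(2, spec.max_rounds + 1):
        if resample_displays:
            displays = assign_displays(net, dist, spec, int(rng.integers(2**31)))
        prev = state.copy()
        new = prev.copy()
        for v in net.nodes:
            i = idx[v]
            dd, dk = shown(v, prev)
            all_shown = [c for _, c in dd + dk]
            role = roles[v]
            active = True
            if role == "human" and behavior.dropout_prob > 0 and rng.random() < behavior.dropout_prob:
                role_now, active = "bot", False
            else:
                role_now = role
            if role_now == "stubborn":
                choice = int(initial[i])
            elif role_now == "bot":
                choice = bot_decision(all_shown, rng)
            else:
                if behavior.cumulative and ever[i]:
                    choice = INNOVATION
                else:
                    f_direct = np.mean([c for _, c in dd])
                    f_distant = np.mean([c for _, c in dk]) if dk else 0.0
                    p = _sigmoid(
                        behavior.alpha * f_direct
                        + behavior.beta_at(spec.display_distance) * f_distant
                        + behavior.gamma * float(ever[i])
                        - behavior.theta
                    )
                    choice = INNOVATION if rng.random() < p else TRADITION
            new[i] = choice
            records.append(
                RoundRecord(session_id, spec.index, rnd, v, roles[v], choice, dd, dk, active)
            )
        state = new
        ever = np.maximum(ever, state)
        proportions.append(ever.mean())
        if consensus_round is None and (state == state[0]).all():
            consensus_round = rnd
            break

    curve = AdoptionCurve(
        rounds=np.arange(1, len(proportions) + 1),
        proportion=np.asarray(proportions, dtype=float),
    )
    return SettingResult(
        spec=spec, records=records, curve=curve,
        consensus_round=consensus_round, initial=np.asarray(initial, dtype=int),
        roles=roles,
    )


def generate_session(
    net: SocialNetwork,
    seed: int,
    *,
    n_minority: int = 4,
    behavior: Behavior = Behavior(),
    n_stubborn: int = 0,
    settings: list[SettingSpec] | None = None,
    dist: DistanceMatrix | None = None,
    session_id: str | None = None,
) -> Session:
    """Run a full session: each of the four settings with a fresh random
    initialization (and, optionally, ``n_stubborn`` stubborn agents planted
    among the tradition-colour starters per setting).
    """
    if dist is None:
        dist = distance_matrix(net)
    settings = settings if settings is not None else default_settings()
    session_id = session_id if session_id is not None else f"S{seed}"
    ss = np.random.SeedSequence(seed)
    results = []
    for spec, child in zip(settings, ss.spawn(len(settings))):
        s_init, s_roles, s_run = (int(s.generate_state(1)[0] % 2**31) for s in child.spawn(3))
        initial = initialize_session(net, n_minority, s_init)
        roles: dict[int, str] = {}
        if n_stubborn > 0:
            rng = np.random.default_rng(s_roles)
            candidates = [v for i, v in enumerate(net.nodes) if initial[i] == TRADITION]
            for v in rng.choice(candidates, size=n_stubborn, replace=False):
                roles[int(v)] = "stubborn"
        results.append(
            simulate_setting(
                net, spec, initial, s_run,
                behavior=behavior, roles=roles, dist=dist, session_id=session_id,
            )
        )
    return Session(session_id=session_id, network=net, settings=results, seed=seed)


# ---------------------------------------------------------------------------
# Payoffs

def compute_payoffs(result: SettingResult, *, round_cap: int = MAX_ROUNDS_CAP) -> dict[int, int]:
    """Points per participant for one setting: 1 point per active round,
    plus — if consensus was reached — 5 points per round left until the
    cap, for participants active in at least one of the last two played
    rounds."""
    by_node: dict[int, list[RoundRecord]] = {}
    for rec in result.records:
        by_node.setdefault(rec.node, []).append(rec)
    last_round = max(rec.round for rec in result.records)
    bonus = 0
    if result.consensus_round is not None:
        bonus = 5 * (round_cap - result.consensus_round)
    payoffs: dict[int, int] = {}
    for node, recs in by_node.items():
        active_rounds = sum(r.active for r in recs)
        eligible = any(r.active for r in recs if r.round >= last_round - 1)
        payoffs[node] = active_rounds + (bonus if eligible else 0)
    return payoffs


# ---------------------------------------------------------------------------
# Tidy I/O

SCHEMA_VERSION = "1"


def _encode_display(pairs: tuple[tuple[int, int], ...]) -> str:
    return "|".join(f"{p}:{c}" for p, c in pairs)


def _decode_display(s) -> tuple[tuple[int, int], ...]:
    if isinstance(s, tuple):
        return s
    if not isinstance(s, str) or s == "":
        return ()
    return tuple((int(p), int(c)) for p, c in (item.split(":") for item in s.split("|")))


def records_to_frame(records: list[RoundRecord]) -> pd.DataFrame:
    rows = [
        {
            "session_id": r.session_id,
            "setting": r.setting,
            "round": r.round,
            "node": r.node,
            "role": r.role,
            "chosen_color": r.chosen_color,
            "displayed_direct": _encode_display(r.displayed_direct),
            "displayed_distant": _encode_display(r.displayed_distant),
            "active": int(r.active),
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame) -> list[RoundRecord]:
    return [
        RoundRecord(
            session_id=str(row.session_id),
            setting=str(row.setting),
            round=int(row.round),
            node=int(row.node),
            role=str(row.role),
            chosen_color=int(row.chosen_color),
            displayed_direct=_decode_display(row.displayed_direct),
            displayed_distant=_decode_display(row.displayed_distant),
            active=bool(row.active),
        )
        for row in df.itertuples()
    ]


def write_session_csv(sessions: list[Session], path: str | Path) -> None:
    frames = [records_to_frame(res.records) for s in sessions for res in s.settings]
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(path, index=False)


def read_session_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    df["round"] = df["round"].astype(int)
    return df


def curve_from_records(df: pd.DataFrame, *, include_bots: bool = True) -> AdoptionCurve:
    """Cumulative adopter proportion per round from tidy round records of a
    single session-setting (an adopter is a seat that has shown the
    innovation colour in any round so far)."""
    if df["setting"].nunique() != 1 or df["session_id"].nunique() != 1:
        raise ValueError("expected records of exactly one session-setting")
    if not include_bots:
        df = df[df["role"] != "bot"]
    wide = df.pivot_table(index="node", columns="round", values="chosen_color", aggfunc="first")
    wide = wide.sort_index(axis=1)
    ever = np.maximum.accumulate(wide.to_numpy(), axis=1)
    prop = ever.mean(axis=0)
    return AdoptionCurve(rounds=np.asarray(wide.columns, dtype=int), proportion=prop)
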