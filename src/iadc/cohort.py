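"""Synthetic session cohorts emulating the contest study's design.

No raw data from the study are deposited, so every downstream analysis is
exercised on simulated cohorts that reproduce the *design*: 80 six-person
sessions split between a treated and a placebo-like arm, each playing one
simultaneous and one sequential 15-round block (order counterbalanced by
session parity) with real-time feedback, integer contributions 0..20,
zero-inflated attacker contributions, near-ceiling defender contributions,
and configurable treatment contrasts (more attacker non-contribution,
stronger attacker tracking of defender history, lower attacker within-group
noise under treatment).

The behavioral model is deliberately simple and fully documented: each
round a group-level target contribution is formed from a baseline location
shifted by ``tracking_weight x (recent opponent history - its running
mean)``; members jitter the target with Gaussian noise and then draw a
binomial(20, target/20) contribution (a discretized, bounded draw whose
mean is controllable), zeroed with the role's zero-inflation probability.
In sequential blocks later movers anchor toward the contributions they
observed. Decision times are log-normal per (role, contributed) cell with
a small rate of injected >180 s outliers.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from iadc.engine import ENDOWMENT, GROUP_SIZE


@dataclass
class AgentParams:
    """Behavioral parameters for one role in one treatment arm."""

    zero_inflation: float       # probability of a hard zero contribution
    location: float             # baseline mean of the non-zero draw (MU)
    noise_scale: float          # sd of member-level jitter around the target
    tracking_weight: float = 0.0    # <= 0; response to rival history (MU/MU)
    anchor_weight: float = 0.5      # pull toward observed teammates (seq.)
    group_sd: float = 1.5           # sd of the session-level norm offset

    def __post_init__(self) -> None:
        if not 0.0 <= self.zero_inflation <= 1.0:
            raise ValueError("zero_inflation must be a probability")
        if self.tracking_weight > 0:
            raise ValueError("tracking_weight must be <= 0 (attack the weak)")
        if not 0.0 <= self.anchor_weight <= 1.0:
            raise ValueError("anchor_weight must be in [0, 1]")


@dataclass
class DecisionTimeParams:
    """Log10-scale decision-time distribution for one (role, cell)."""

    log10_mean: float
    log10_sd: float = 0.22


#: Arm labels; "treated" mirrors the neuropeptide arm, "placebo" the control.
ARMS = ("placebo", "treated")

_DEFAULT_AGENTS = {
    ("attacker", "placebo"): AgentParams(0.40, 8.5, 3.5, -0.05),
    ("attacker", "treated"): AgentParams(0.48, 8.0, 2.5, -0.35),
    ("defender", "placebo"): AgentParams(0.09, 8.8, 2.8, 0.0),
    ("defender", "treated"): AgentParams(0.09, 8.8, 2.8, 0.0),
}

_DEFAULT_TIMES = {
    ("attacker", True): DecisionTimeParams(0.95),
    ("attacker", False): DecisionTimeParams(0.78),
    ("defender", True): DecisionTimeParams(0.92),
    ("defender", False): DecisionTimeParams(0.85),
}


@dataclass
class CohortConfig:
    """Design and behavioral configuration of a synthetic cohort."""

    n_sessions: int = 80
    treatment_split: tuple[int, int] = (40, 40)  # (placebo, treated)
    n_rounds: int = 15
    master_seed: int = 20190125
    agents: dict = field(default_factory=lambda: copy.deepcopy(_DEFAULT_AGENTS))
    times: dict = field(default_factory=lambda: copy.deepcopy(_DEFAULT_TIMES))
    slow_time_rate: float = 0.005   # injected >180 s decisions

    def __post_init__(self) -> None:
        if sum(self.treatment_split) != self.n_sessions:
            raise ValueError("treatment_split must sum to n_sessions")

    def null(self) -> "CohortConfig":
        """Copy with treatment effects removed (treated arm = placebo arm)."""
        cfg = copy.deepcopy(self)
        for role in ("attacker", "defender"):
            cfg.agents[(role, "treated")] = copy.deepcopy(
                cfg.agents[(role, "placebo")]
            )
        return cfg

    def arm_of(self, session_index: int) -> str:
        return "placebo" if session_index < self.treatment_split[0] else "treated"

    def block_order(self, session_index: int) -> tuple[str, str]:
        """Counterbalanced block order, alternating by session parity."""
        if session_index % 2 == 0:
            return ("simultaneous", "sequential")
        return ("sequential", "simultaneous")


def make_policy(role: str, params: AgentParams, rng: np.random.Generator,
                location_offset: float = 0.0):
    """Contribution policy for one member.

    The policy signature matches :func:`iadc.engine.play_block`:
    ``policy(round_index, history, observed_teammates) -> int``. The
    tracking term shifts the target by
    ``tracking_weight * (recent opponent history - running mean)`` where
    "recent" is the mean opponent pool of the last two rounds; defenders
    have ``tracking_weight = 0`` by default and ignore history.
    ``location_offset`` carries the session-level norm (drawn once per
    session x role with sd ``group_sd``), the source of between-group
    heterogeneity that the intraclass correlation picks up.
    """

    def opponent_pools(history):
        if role == "attacker":
            return [o.g_defender for o in history]
        return [o.g_attacker for o in history]

    def policy(round_index, history, observed_teammates):
        if observed_teammates and params.anchor_weight >= 1.0:
            # full anchoring: later movers copy the group norm exactly
            return int(round(float(np.mean(observed_teammates))))
        if rng.random() < params.zero_inflation:
            return 0
        target = params.location + location_offset
        pools = opponent_pools(history)
        if len(pools) >= 2 and params.tracking_weight != 0.0:
            recent = (pools[-1] + pools[-2]) / 2.0
            baseline = float(np.mean(pools))
            target = target + params.tracking_weight * (recent - baseline)
        member_mean = target + rng.normal(0.0, params.noise_scale)
        if observed_teammates:
            w = params.anchor_weight
            member_mean = (1 - w) * member_mean + w * float(
                np.mean(observed_teammates)
            )
        p = float(np.clip(member_mean / ENDOWMENT, 0.0, 1.0))
        return int(rng.binomial(ENDOWMENT, p))

    return policy


def _draw_time(role, contributed, cfg: CohortConfig, rng) -> float:
    if rng.random() < cfg.slow_time_rate:
        return float(rng.uniform(181.0, 300.0))
    tp = cfg.times[(role, contributed)]
    return float(10.0 ** rng.normal(tp.log10_mean, tp.log10_sd))


def generate_session(config: CohortConfig, session_index: int) -> pd.DataFrame:
    """One session: 2 blocks x n_rounds x 6 members, deterministic in
    (master_seed, session_index)."""
    if not 0 <= session_index < config.n_sessions:
        raise ValueError("session_index out of range")
    from iadc.engine import play_block  # local import avoids cycle at import time

    arm = config.arm_of(session_index)
    ss = np.random.SeedSequence(config.master_seed, spawn_key=(session_index,))
    seed_block, seed_policy, seed_time, seed_norm = ss.spawn(4)
    time_rng = np.random.default_rng(seed_time)
    norm_rng = np.random.default_rng(seed_norm)
    offsets = {
        role: norm_rng.normal(0.0, config.agents[(role, arm)].group_sd)
        for role in ("attacker", "defender")
    }
    policy_seeds = seed_policy.spawn(2)  # one per block
    block_seeds = seed_block.spawn(2)

    sid = f"S{session_index:03d}"
    frames = []
    for pos, protocol in enumerate(config.block_order(session_index), start=1):
        prng = np.random.default_rng(policy_seeds[pos - 1])
        att = [
            make_policy("attacker", config.agents[("attacker", arm)], prng,
                        offsets["attacker"])
            for _ in range(GROUP_SIZE)
        ]
        dfd = [
            make_policy("defender", config.agents[("defender", arm)], prng,
                        offsets["defender"])
            for _ in range(GROUP_SIZE)
        ]
        res = play_block(
            att, dfd, protocol, config.n_rounds,
            rng_seed=np.random.default_rng(block_seeds[pos - 1]),
            session_id=sid,
        )
        rows = []
        for rec in res.records:
            rows.append(
                {
                    "session_id": sid,
                    "treatment": int(arm == "treated"),
                    "block": "sim" if protocol == "simultaneous" else "seq",
                    "block_position": pos,
                    "round": rec.round_index,
                    "role": rec.role,
                    "member": rec.member_index,
                    "contribution": rec.contribution,
                    "decision_time_s": _draw_time(
                        rec.role, rec.contribution > 0, config, time_rng
                    ),
                    "decision_order": rec.decision_order,
                }
            )
        frames.append(pd.DataFrame(rows))
    return pd.concat(frames, ignore_index=True)


def generate_cohort(config: CohortConfig | None = None) -> pd.DataFrame:
    """Full cohort table; sessions are independent (distinct sub-seeds)."""
    config = config or CohortConfig()
    frames = [
        generate_session(config, i) for i in range(config.n_sessions)
    ]
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# direct generative model for tracking-recovery studies
# ---------------------------------------------------------------------------

def simulate_tracking_series(
    w: float,
    n_rounds: int = 15,
    rng: np.random.Generator | None = None,
    defense_mean: float = 26.0,
    defense_sd: float = 8.0,
):
    """Attack series with a known *standardized* tracking weight.

    The defender pool series is iid Gaussian (clipped to 0..60); the attack
    series is built so that the population standardized coefficient on the
    history level ``alpha`` is exactly ``w``:
    ``A_j = w * z(alpha_j) + sqrt(1 - w^2) * noise``. Used to validate that
    the tracking regression recovers known effects.

    Returns ``(attack_series, defense_series)`` of length n_rounds; the
    first two attack values are padding (the fit uses rounds 3..n).
    """
    if not -1.0 <= w <= 1.0:
        raise ValueError("standardized weight must lie in [-1, 1]")
    rng = rng or np.random.default_rng()
    d = np.clip(rng.normal(defense_mean, defense_sd, size=n_rounds), 0, 60)
    alpha = (d[1:-1] + d[:-2]) / 2.0
    za = (alpha - alpha.mean()) / alpha.std(ddof=1)
    eps = rng.normal(0.0, 1.0, size=len(za))
    a = w * za + np.sqrt(max(0.0, 1.0 - w * w)) * eps
    attack = np.concatenate([[0.0, 0.0], a])
    return attack, d


def config_to_dict(config: CohortConfig) -> dict:
    """YAML/JSON-serializable form of a cohort configuration."""
    d = {
        "n_sessions": config.n_sessions,
        "treatment_split": list(config.treatment_split),
        "n_rounds": config.n_rounds,
        "master_seed": config.master_seed,
        "slow_time_rate": config.slow_time_rate,
        "agents": {
            f"{role}/{arm}": asdict(p)
            for (role, arm), p in config.agents.items()
        },
        "times": {
            f"{role}/{'contribute' if c else 'no_contribute'}": asdict(p)
            for (role, c), p in config.times.items()
        },
    }
    return d


def config_from_dict(d: dict) -> CohortConfig:
    cfg = CohortConfig(
        n_sessions=d.get("n_sessions", 80),
        treatment_split=tuple(d.get("treatment_split", (40, 40))),
        n_rounds=d.get("n_rounds", 15),
        master_seed=d.get("master_seed", 20190125),
        slow_time_rate=d.get("slow_time_rate", 0.005),
    )
    for key, p in d.get("agents", {}).items():
        role, arm = key.split("/")
        cfg.agents[(role, arm)] = AgentParams(**p)
    for key, p in d.get("times", {}).items():
        role, cell = key.split("/")
        cfg.times[(role, cell == "contribute")] = DecisionTimeParams(**p)
    return cfg
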