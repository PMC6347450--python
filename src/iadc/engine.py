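"""One-round rules and block play for the intergroup attacker-defender contest (IADC).

The IADC pits a three-person attacker group against a three-person defender
group. Each member privately commits an integer number of monetary units
(MU, 0..20) to the group pool; contributions are forfeited regardless of the
outcome (all-pay). Attackers win a round only if their pool strictly exceeds
the defender pool; on a tie or less, defenders survive. When attackers win,
each defender is left with nothing and the defender group's unspent
endowment (the spoils, ``60 - G_defender``) is split equally among the three
attackers on top of their own leftovers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np

ENDOWMENT = 20
GROUP_SIZE = 3

Role = Literal["attacker", "defender"]
Block = Literal["simultaneous", "sequential"]


@dataclass(frozen=True)
class RoundRecord:
    """One member's decision in one contest round."""

    session_id: str
    block: Block
    round_index: int          # 1-based
    role: Role
    member_index: int         # 1..3
    contribution: int         # MU, 0..20
    decision_time: float | None = None
    decision_order: int | None = None  # 1..3, sequential blocks only

    def __post_init__(self) -> None:
        if not (0 <= self.contribution <= ENDOWMENT):
            raise ValueError(
                f"contribution {self.contribution} out of range for "
                f"{self.role} member {self.member_index}"
            )
        if (self.decision_order is not None) != (self.block == "sequential"):
            raise ValueError(
                "decision_order must be present iff block is sequential"
            )


@dataclass(frozen=True)
class GroupRoundOutcome:
    """A resolved round: pools, winner and per-member payoffs."""

    g_attacker: int
    g_defender: int
    attackers_win: bool
    attacker_payoffs: tuple[float, float, float]
    defender_payoffs: tuple[float, float, float]

    @property
    def spoils_per_attacker(self) -> float:
        """Spoils share per attacker in a winning round, else 0."""
        if not self.attackers_win:
            return 0.0
        return (GROUP_SIZE * ENDOWMENT - self.g_defender) / GROUP_SIZE

    @property
    def total_payoff(self) -> float:
        return sum(self.attacker_payoffs) + sum(self.defender_payoffs)


def _validate_side(contribs: Sequence[int], role: Role) -> list[int]:
    if len(contribs) != GROUP_SIZE:
        raise ValueError(f"{role} side needs exactly {GROUP_SIZE} contributions")
    out = []
    for i, c in enumerate(contribs, start=1):
        if isinstance(c, (bool, float)) and not float(c).is_integer():
            raise ValueError(f"{role} member {i}: non-integer contribution {c!r}")
        ci = int(c)
        if ci != c:
            raise ValueError(f"{role} member {i}: non-integer contribution {c!r}")
        if not 0 <= ci <= ENDOWMENT:
            raise ValueError(
                f"{role} member {i}: contribution {ci} outside [0, {ENDOWMENT}]"
            )
        out.append(ci)
    return out


def resolve_round(
    attacker_contribs: Sequence[int], defender_contribs: Sequence[int]
) -> GroupRoundOutcome:
    """Resolve a single round from the six individual contributions.

    Attackers win iff their pool strictly exceeds the defender pool; ties
    leave the defenders standing. Money is conserved: total payoff across
    the six members always equals ``120 - G_attacker - G_defender``.
    """
    att = _validate_side(attacker_contribs, "attacker")
    dfd = _validate_side(defender_contribs, "defender")
    ga, gd = sum(att), sum(dfd)
    win = ga > gd
    if win:
        spoils = (GROUP_SIZE * ENDOWMENT - gd) / GROUP_SIZE
        att_pay = tuple(ENDOWMENT - c + spoils for c in att)
        def_pay = (0.0, 0.0, 0.0)
    else:
        att_pay = tuple(float(ENDOWMENT - c) for c in att)
        def_pay = tuple(float(ENDOWMENT - c) for c in dfd)
    return GroupRoundOutcome(ga, gd, win, att_pay, def_pay)


def resolve_rounds(
    attacker_contribs: np.ndarray, defender_contribs: np.ndarray
) -> dict[str, np.ndarray]:
    """Vectorized resolution of many rounds.

    Parameters
    ----------
    attacker_contribs, defender_contribs : int arrays of shape (n_rounds, 3)

    Returns
    -------
    dict with arrays ``g_attacker``, ``g_defender``, ``attackers_win``,
    ``attacker_payoffs`` (n, 3), ``defender_payoffs`` (n, 3).
    """
    a = np.asarray(attacker_contribs)
    d = np.asarray(defender_contribs)
    if a.ndim != 2 or a.shape[1] != GROUP_SIZE or a.shape != d.shape:
        raise ValueError("expected arrays of shape (n_rounds, 3)")
    if np.issubdtype(a.dtype, np.floating) or np.issubdtype(d.dtype, np.floating):
        raise ValueError("contributions must be integers")
    for arr, role in ((a, "attacker"), (d, "defender")):
        bad = np.where((arr < 0) | (arr > ENDOWMENT))
        if bad[0].size:
            r, m = bad[0][0], bad[1][0]
            raise ValueError(
                f"{role} member {m + 1}: contribution {arr[r, m]} outside "
                f"[0, {ENDOWMENT}] in round {r + 1}"
            )
    ga = a.sum(axis=1)
    gd = d.sum(axis=1)
    win = ga > gd
    spoils = np.where(win, (GROUP_SIZE * ENDOWMENT - gd) / GROUP_SIZE, 0.0)
    att_pay = (ENDOWMENT - a) + spoils[:, None]
    def_pay = np.where(win[:, None], 0.0, (ENDOWMENT - d).astype(float))
    return {
        "g_attacker": ga,
        "g_defender": gd,
        "attackers_win": win,
        "attacker_payoffs": att_pay,
        "defender_payoffs": def_pay,
    }


# A policy maps (round_index, history, observed_teammates) -> contribution.
# `history` is the list of GroupRoundOutcome from earlier rounds (public
# feedback); `observed_teammates` holds earlier same-group decisions in the
# current sequential round (empty under the simultaneous protocol).
Policy = Callable[[int, list[GroupRoundOutcome], list[int]], int]


@dataclass
class BlockResult:
    records: list[RoundRecord] = field(default_factory=list)
    outcomes: list[GroupRoundOutcome] = field(default_factory=list)


def play_block(
    attacker_policies: Sequence[Policy],
    defender_policies: Sequence[Policy],
    protocol: Block,
    n_rounds: int = 15,
    rng_seed: int | np.random.Generator | None = 0,
    session_id: str = "S0",
) -> BlockResult:
    """Play a block of rounds with real-time feedback between rounds.

    Under the sequential protocol a fresh random within-group decision order
    is drawn every round; the second mover observes the first decision and
    the third mover observes both earlier ones.
    """
    if len(attacker_policies) != GROUP_SIZE or len(defender_policies) != GROUP_SIZE:
        raise ValueError("exactly three policies per side are required")
    if protocol not in ("simultaneous", "sequential"):
        raise ValueError(f"unknown protocol {protocol!r}")
    rng = np.random.default_rng(rng_seed)
    result = BlockResult()
    history: list[GroupRoundOutcome] = []
    for j in range(1, n_rounds + 1):
        contribs: dict[Role, list[int]] = {}
        orders: dict[Role, list[int]] = {}
        for role, policies in (
            ("attacker", attacker_policies),
            ("defender", defender_policies),
        ):
            vals = [0] * GROUP_SIZE
            if protocol == "sequential":
                order = rng.permutation(GROUP_SIZE)
                seen: list[int] = []
                pos = [0] * GROUP_SIZE
                for rank, m in enumerate(order, start=1):
                    c = policies[m](j, history, list(seen))
                    vals[m] = c
                    seen.append(c)
                    pos[m] = rank
                orders[role] = pos
            else:
                for m, pol in enumerate(policies):
                    vals[m] = pol(j, history, [])
            contribs[role] = vals
        outcome = resolve_round(contribs["attacker"], contribs["defender"])
        for role in ("attacker", "defender"):
            for m in range(GROUP_SIZE):
                result.records.append(
                    RoundRecord(
                        session_id=session_id,
                        block=protocol,
                        round_index=j,
                        role=role,
                        member_index=m + 1,
                        contribution=contribs[role][m],
                        decision_order=(
                            orders[role][m] if protocol == "sequential" else None
                        ),
                    )
                )
        result.outcomes.append(outcome)
        history.append(outcome)
    return result
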