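"""Tabular session schema: one row per member x round.

Columns
-------
session_id : str            session identifier
treatment : int {0, 1}      0 placebo-like, 1 treated arm (constant in session)
block : {"sim", "seq"}      decision protocol of the 15-round block
block_position : int {1, 2} order of the block within the session
round : int 1..n_rounds
role : {"attacker", "defender"}
member : int 1..3
contribution : int 0..20
decision_time_s : float, optional
decision_order : int 1..3, sequential rounds only
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = [
    "session_id", "treatment", "block", "block_position", "round",
    "role", "member", "contribution",
]
OPTIONAL_COLUMNS = ["decision_time_s", "decision_order"]


class SchemaError(ValueError):
    """Raised when a session table violates the schema; collects violations."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        head = violations[:20]
        more = f" (+{len(violations) - 20} more)" if len(violations) > 20 else ""
        super().__init__("invalid session table:\n  " + "\n  ".join(head) + more)


def validate_sessions(df: pd.DataFrame) -> list[str]:
    """Return a list of violations (empty when the table is valid)."""
    v: list[str] = []
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        return [f"missing columns: {missing}"]

    contrib = pd.to_numeric(df["contribution"], errors="coerce")
    bad = df.index[contrib.isna() | (contrib % 1 != 0)
                   | (contrib < 0) | (contrib > 20)]
    for i in bad[:50]:
        v.append(f"row {i}: contribution {df.at[i, 'contribution']!r} "
                 "not an integer in [0, 20]")

    bad_role = df.index[~df["role"].isin(["attacker", "defender"])]
    for i in bad_role[:10]:
        v.append(f"row {i}: unknown role {df.at[i, 'role']!r}")
    bad_block = df.index[~df["block"].isin(["sim", "seq"])]
    for i in bad_block[:10]:
        v.append(f"row {i}: unknown block {df.at[i, 'block']!r}")
    bad_member = df.index[~df["member"].isin([1, 2, 3])]
    for i in bad_member[:10]:
        v.append(f"row {i}: member {df.at[i, 'member']!r} not in 1..3")

    if v:
        return v

    counts = df.groupby(["session_id", "block", "round"]).size()
    wrong = counts[counts != 6]
    for key, n in wrong.items():
        v.append(f"(session={key[0]}, block={key[1]}, round={key[2]}): "
                 f"{n} rows, expected 6")
    per_role = df.groupby(["session_id", "block", "round", "role"]).size()
    wrong_role = per_role[per_role != 3]
    for key, n in wrong_role.items():
        v.append(f"(session={key[0]}, block={key[1]}, round={key[2]}, "
                 f"role={key[3]}): {n} members, expected 3")

    tr = df.groupby("session_id")["treatment"].nunique()
    for sid in tr.index[tr > 1]:
        v.append(f"session {sid}: treatment varies within session")
    bad_tr = df.index[~df["treatment"].isin([0, 1])]
    for i in bad_tr[:10]:
        v.append(f"row {i}: treatment {df.at[i, 'treatment']!r} not 0/1")

    if "decision_order" in df.columns:
        seq = df["block"] == "seq"
        miss = df.index[seq & df["decision_order"].isna()]
        if len(miss):
            v.append(f"{len(miss)} sequential rows lack decision_order")
        extra = df.index[~seq & df["decision_order"].notna()]
        if len(extra):
            v.append(f"{len(extra)} simultaneous rows carry decision_order")
    return v


def read_sessions(path) -> pd.DataFrame:
    """Read and validate a session CSV; raises SchemaError on violations."""
    df = pd.read_csv(path)
    if "decision_order" in df.columns:
        df["decision_order"] = pd.to_numeric(
            df["decision_order"], errors="coerce"
        ).astype("Int64")
    violations = validate_sessions(df)
    if violations:
        raise SchemaError(violations)
    df["contribution"] = df["contribution"].astype(int)
    return df


def write_sessions(df: pd.DataFrame, path) -> None:
    """Write a session table in the canonical column order."""
    cols = REQUIRED_COLUMNS + [c for c in OPTIONAL_COLUMNS if c in df.columns]
    out = df[cols].copy()
    out.to_csv(path, index=False)


def group_pools(df: pd.DataFrame) -> pd.DataFrame:
    """Per (session, block, round) pools and the round winner."""
    pools = (
        df.groupby(["session_id", "treatment", "block", "round"])
        .apply(
            lambda g: pd.Series(
                {
                    "g_attacker": g.loc[g.role == "attacker", "contribution"].sum(),
                    "g_defender": g.loc[g.role == "defender", "contribution"].sum(),
                }
            ),
            include_groups=False,
        )
        .reset_index()
    )
    pools["attackers_win"] = pools["g_attacker"] > pools["g_defender"]
    return pools
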