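"""Cohort-level analysis pipeline: metrics, ANOVA wrappers, tracking,
mediation, and the equilibrium comparison.

The statistical wrappers delegate to pingouin (mixed ANOVA, t-tests with
Cohen's d) — routine machinery, fixed here only in factor coding and
effect-size reporting. The substantive computations (tracking
weights, the mediation chain and the equilibrium benchmark) live in their
own modules.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pingouin as pg

from iadc import metrics as m
from iadc import tracking as tr
from iadc.equilibrium import solve_symmetric_equilibrium
from iadc.io import group_pools, validate_sessions, SchemaError
from iadc.mediation import SerialMediation

log = logging.getLogger("iadc.analysis")


def group_block_metrics(df: pd.DataFrame) -> pd.DataFrame:
    """Per session x role x block summary of the coordination measures."""
    pools = group_pools(df)
    rows = []
    for (sid, blk), sub in df.groupby(["session_id", "block"]):
        p = pools[(pools.session_id == sid) & (pools.block == blk)]
        p = p.sort_values("round")
        for role in ("attacker", "defender"):
            side = sub[sub.role == role]
            wide = side.pivot_table(index="round", columns="member",
                                    values="contribution")
            wgv = wide.var(axis=1, ddof=1)
            contribs = side.sort_values(["round", "member"])["contribution"]
            arr = contribs.to_numpy().reshape(-1, 3)
            row = {
                "session_id": sid,
                "treatment": int(side["treatment"].iloc[0]),
                "block": blk,
                "role": role,
                "mean_contribution": float(side["contribution"].mean()),
                "mean_within_group_variance": float(wgv.mean()),
                "n_noncontributors": int((side["contribution"] == 0).sum()),
            }
            if role == "attacker":
                oc = m.contest_outcomes(
                    p["g_attacker"].to_numpy(), p["g_defender"].to_numpy(), arr
                )
                row.update(
                    success_rate=oc.success_rate,
                    mean_spoils_win=oc.mean_spoils_win,
                    mean_leftover_loss=oc.mean_leftover_loss,
                )
            rows.append(row)
    return pd.DataFrame(rows)


def icc_by_condition(df: pd.DataFrame) -> pd.DataFrame:
    """ICC(1) per (role, block, treatment): groups are sessions, the member x
    round contributions within the block are the observations."""
    rows = []
    for (role, blk, trt), sub in df.groupby(["role", "block", "treatment"]):
        wide = sub.pivot_table(
            index="session_id", columns=["round", "member"],
            values="contribution",
        )
        rows.append(
            {
                "role": role,
                "block": blk,
                "treatment": trt,
                "icc": m.icc_group_cohesion(wide.to_numpy()),
                "n_groups": wide.shape[0],
                "k_obs": wide.shape[1],
            }
        )
    return pd.DataFrame(rows)


def mixed_anova_role_treatment(
    gb_metrics: pd.DataFrame, dv: str
) -> pd.DataFrame:
    """2 (Role, within) x 2 (Treatment, between) mixed ANOVA on a
    session-level dv, averaging the two blocks first.

    Returns the pingouin table with F, df, p and partial eta squared.
    """
    tab = (
        gb_metrics.groupby(["session_id", "treatment", "role"])[dv]
        .mean()
        .reset_index()
    )
    return pg.mixed_anova(
        data=tab, dv=dv, within="role", subject="session_id",
        between="treatment",
    )


def ttest_between_arms(values: pd.DataFrame, dv: str) -> dict:
    """Welch-free two-sample t-test (pooled, as in balanced designs) with
    Cohen's d and its 95% CI; `values` needs columns [treatment, dv]."""
    a = values.loc[values.treatment == 1, dv].dropna()
    b = values.loc[values.treatment == 0, dv].dropna()
    res = pg.ttest(a, b, correction=False)
    row = res.iloc[0]
    return {
        "t": float(row["T"]),
        "dof": float(row["dof"]),
        "p": float(row["p_val"]),
        "cohen_d": float(row["cohen_d"]),
        "ci95": [float(x) for x in row["CI95"]],
        "n": [int(len(a)), int(len(b))],
    }


def equilibrium_comparison(df: pd.DataFrame, level: str = "group") -> dict:
    """Observed per-member means and win rate against the mixed-equilibrium
    benchmark."""
    sol = solve_symmetric_equilibrium(level=level)
    pools = group_pools(df)
    obs_attack = float(
        df.loc[df.role == "attacker", "contribution"].mean()
    )
    obs_defense = float(
        df.loc[df.role == "defender", "contribution"].mean()
    )
    obs_win = float(pools["attackers_win"].mean())
    return {
        "benchmark": sol.as_dict(),
        "observed": {
            "mean_attack": obs_attack,
            "mean_defense": obs_defense,
            "attacker_win_rate": obs_win,
        },
        "deviation": {
            "attack": obs_attack - sol.expected_attack,
            "defense": obs_defense - sol.expected_defense,
            "win_rate": obs_win - sol.attacker_win_prob,
        },
    }


def mediation_table(df: pd.DataFrame, block: str = "sim",
                    y: str = "mean_spoils_win") -> pd.DataFrame:
    """Group-level table for the serial mediation chain.

    X = treatment, M1 = attacker tracking weight (Fisher z) in `block`,
    M2 = attacker mean within-group variance in `block`, Y = spoils from
    winning (or spoils + leftovers with ``y="spoils_plus_leftovers"``).
    Winless groups have missing spoils and are dropped listwise downstream.
    """
    fits = tr.fit_cohort_tracking(df[df.block == block])
    fits = fits[fits.role == "attacker"].set_index("session_id")
    gb = group_block_metrics(df)
    gb = gb[(gb.role == "attacker") & (gb.block == block)].set_index("session_id")
    out = pd.DataFrame(
        {
            "X": gb["treatment"],
            "M1": fits["alpha_z"],
            "M2": gb["mean_within_group_variance"],
        }
    )
    if y == "spoils_plus_leftovers":
        out["Y"] = gb["mean_spoils_win"].fillna(0.0) + gb[
            "mean_leftover_loss"
        ].fillna(0.0)
    else:
        out["Y"] = gb[y]
    return out.reset_index()


def run_full_analysis(
    df: pd.DataFrame,
    out_dir: str | Path | None = None,
    n_boot: int = 5000,
    seed: int | None = 0,
    equilibrium_level: str = "group",
) -> dict:
    """Run the whole analysis battery on a validated session table.

    Returns a dict bundle; when `out_dir` is given, also writes tidy CSVs
    (metrics, tracking fits, ICC, ANOVA tables) and JSON results
    (equilibrium comparison, mediation) plus a short log.
    """
    violations = validate_sessions(df)
    if violations:
        raise SchemaError(violations)

    log.info("computing group-block metrics")
    gb = group_block_metrics(df)
    icc = icc_by_condition(df)
    times = m.preprocess_decision_times(df) if "decision_time_s" in df else None

    log.info("fitting tracking regressions")
    fits = tr.fit_cohort_tracking(df)

    anovas = {}
    for dv in ("mean_contribution", "n_noncontributors",
               "mean_within_group_variance"):
        anovas[dv] = mixed_anova_role_treatment(gb, dv)

    att_sim = gb[(gb.role == "attacker") & (gb.block == "sim")]
    ttests = {
        "spoils_win": ttest_between_arms(att_sim, "mean_spoils_win"),
        "leftover_loss": ttest_between_arms(att_sim, "mean_leftover_loss"),
    }

    log.info("mediation bootstrap (n_boot=%d)", n_boot)
    med_tab = mediation_table(df).dropna()
    med = SerialMediation.from_dataframe(med_tab, "X", "M1", "M2", "Y").fit(
        n_boot=n_boot, seed=seed
    )

    eq = equilibrium_comparison(df, level=equilibrium_level)

    bundle = {
        "group_block_metrics": gb,
        "icc": icc,
        "tracking_fits": fits,
        "anova": anovas,
        "ttests": ttests,
        "mediation": med,
        "equilibrium": eq,
        "decision_times": times,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        gb.to_csv(out / "group_block_metrics.csv", index=False)
        icc.to_csv(out / "icc.csv", index=False)
        fits.to_csv(out / "tracking_fits.csv", index=False)
        pd.concat(anovas, names=["dv"]).reset_index(level=0).to_csv(
            out / "anova.csv", index=False
        )
        with open(out / "equilibrium.json", "w") as fh:
            json.dump(eq, fh, indent=2)
        with open(out / "mediation.json", "w") as fh:
            json.dump(
                {
                    "indirect": med.indirect,
                    "se": med.se,
                    "ci": [med.ci_low, med.ci_high],
                    "n_boot": med.n_boot,
                    "method": med.method,
                    "paths": {
                        "a": med.paths.a,
                        "d": med.paths.d,
                        "b": med.paths.b,
                        "direct": med.paths.direct,
                        "total": med.paths.total["X"],
                    },
                    "ttests": ttests,
                },
                fh,
                indent=2,
            )
        with open(out / "run.log", "w") as fh:
            fh.write(
                f"sessions={df.session_id.nunique()} rows={len(df)} "
                f"n_boot={n_boot} seed={seed}\n"
            )
        log.info("results written to %s", out)
    return bundle
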