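"""History-tracking regression: does a group time its attacks to its rival's
recent defense?

For a 15-round block the attacker group's mean contribution on round j
(j = 3..15) is regressed on two features of the rival's history:

* the *level* ``alpha_j = (D_{j-1} + D_{j-2}) / 2`` — the rival pool
  averaged over the two preceding rounds, and
* the *change* ``beta_j = D_{j-1} - D_{j-2}``.

All variables are z-scored within the group-block before ordinary least
squares, so the reported weights are standardized (bounded by 1 in absolute
value for orthogonal regressors) and can be Fisher-z transformed for
group-level inference. A negative alpha weight means the group attacks when
the rival's recent defense is low — the track-and-attack signature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

FISHER_CLIP = 0.999


def build_history_design(opponent_totals) -> pd.DataFrame:
    """Lagged history features (alpha_j, beta_j) for j = 3..n_rounds.

    ``alpha_j`` is the mean of the opponent group totals in the two previous
    rounds; ``beta_j`` their difference (last minus before-last).
    """
    d = np.asarray(opponent_totals, dtype=float)
    if d.ndim != 1 or len(d) < 3:
        raise ValueError("need a series of at least 3 rounds")
    alpha = (d[1:-1] + d[:-2]) / 2.0
    beta = d[1:-1] - d[:-2]
    rounds = np.arange(3, len(d) + 1)
    return pd.DataFrame({"round": rounds, "alpha": alpha, "beta": beta})


def fisher_z(w: float, clip: float = FISHER_CLIP) -> float:
    """artanh transform with clipping to keep +/-1 weights finite."""
    return float(np.arctanh(np.clip(w, -clip, clip)))


def _zscore(x: np.ndarray) -> tuple[np.ndarray, bool]:
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        return np.zeros_like(x), True
    return (x - x.mean()) / sd, False


@dataclass(frozen=True)
class TrackingResults:
    """Standardized tracking weights for one group-block series."""

    alpha_weight: float
    beta_weight: float
    n_obs: int
    degenerate: bool
    session_id: str | None = None
    role: str | None = None
    block: str | None = None

    @property
    def alpha_z(self) -> float:
        return fisher_z(self.alpha_weight)

    @property
    def beta_z(self) -> float:
        return fisher_z(self.beta_weight)

    def summary(self) -> str:
        lines = [
            "Tracking regression (standardized OLS on rival history)",
            f"  n_obs:        {self.n_obs}",
            f"  alpha weight: {self.alpha_weight: .4f}  (z = {self.alpha_z: .4f})",
            f"  beta  weight: {self.beta_weight: .4f}",
            f"  degenerate:   {self.degenerate}",
        ]
        return "\n".join(lines)


class TrackingModel:
    """OLS of a group's contribution series on its rival's history.

    Parameters
    ----------
    own_series : per-round mean (or total) contribution of the focal group,
        rounds 1..n. Only rounds 3..n enter the fit.
    opponent_totals : the rival group's pool per round, rounds 1..n.

    Variables are z-scored within the series; a zero-variance outcome or
    regressor yields weight 0 with the ``degenerate`` flag set rather than
    an error, so cohort-level summaries can keep every group.
    """

    def __init__(self, own_series, opponent_totals, *, session_id=None,
                 role=None, block=None):
        own = np.asarray(own_series, dtype=float)
        opp = np.asarray(opponent_totals, dtype=float)
        if own.shape != opp.shape:
            raise ValueError("own and opponent series must be aligned")
        design = build_history_design(opp)
        self.endog = own[2:]
        self.design = design
        self._meta = dict(session_id=session_id, role=role, block=block)

    @classmethod
    def from_block(cls, block: pd.DataFrame, role: str) -> "TrackingModel":
        """Build from a tidy block table (one session-block, both roles)."""
        other = "defender" if role == "attacker" else "attacker"
        own = (
            block[block["role"] == role]
            .groupby("round")["contribution"].mean().sort_index().to_numpy()
        )
        opp = (
            block[block["role"] == other]
            .groupby("round")["contribution"].sum().sort_index().to_numpy()
        )
        sid = block["session_id"].iloc[0] if "session_id" in block else None
        blk = block["block"].iloc[0] if "block" in block else None
        return cls(own, opp, session_id=sid, role=role, block=blk)

    def fit(self) -> TrackingResults:
        y, y_bad = _zscore(self.endog)
        a, a_bad = _zscore(self.design["alpha"].to_numpy())
        b, b_bad = _zscore(self.design["beta"].to_numpy())
        degenerate = y_bad or a_bad or b_bad
        if y_bad or (a_bad and b_bad):
            return TrackingResults(0.0, 0.0, len(y), True, **self._meta)
        X = np.column_stack([np.ones_like(y), a, b])
        # pseudo-inverse tolerates collinear alpha/beta; flagged, not hidden
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        rank = np.linalg.matrix_rank(X)
        if rank < 3:
            degenerate = True
        wa = 0.0 if a_bad else float(coef[1])
        wb = 0.0 if b_bad else float(coef[2])
        return TrackingResults(wa, wb, len(y), degenerate, **self._meta)


def fit_tracking(own_series, opponent_totals, **meta) -> TrackingResults:
    """Functional shorthand for ``TrackingModel(...).fit()``."""
    return TrackingModel(own_series, opponent_totals, **meta).fit()


def fit_cohort_tracking(table: pd.DataFrame) -> pd.DataFrame:
    """Per session x role x block tracking fits for a whole cohort table.

    Returns a tidy frame with one row per group-block: standardized alpha
    and beta weights, their Fisher-z transforms and the degeneracy flag.
    """
    rows = []
    for (sid, blk), sub in table.groupby(["session_id", "block"], sort=True):
        for role in ("attacker", "defender"):
            res = TrackingModel.from_block(sub, role).fit()
            rows.append(
                {
                    "session_id": sid,
                    "block": blk,
                    "role": role,
                    "alpha_weight": res.alpha_weight,
                    "beta_weight": res.beta_weight,
                    "alpha_z": res.alpha_z,
                    "beta_z": res.beta_z,
                    "n_obs": res.n_obs,
                    "degenerate": res.degenerate,
                }
            )
    return pd.DataFrame(rows)


def tracking_correlates(fits: pd.DataFrame, metrics: pd.DataFrame) -> pd.DataFrame:
    """Cross-group correlations between tracking strength and outcomes.

    Parameters
    ----------
    fits : one row per group (e.g. attacker side, one block) with column
        ``alpha_z``.
    metrics : aligned rows (same order / same key) with columns such as
        ``mean_within_group_variance`` and ``mean_spoils_win``.

    Returns
    -------
    DataFrame of pairwise Pearson correlations between ``alpha_z`` and each
    metric column, with n. Missing metric values (e.g. spoils for winless
    groups) are dropped pairwise.
    """
    if len(fits) != len(metrics):
        raise ValueError("fits and metrics must be row-aligned")
    if len(fits) < 3:
        raise ValueError("need at least 3 groups to correlate")
    out = []
    x = fits["alpha_z"].to_numpy(dtype=float)
    for col in metrics.columns:
        y = metrics[col].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3:
            r = np.nan
        else:
            r = float(np.corrcoef(x[ok], y[ok])[0, 1])
        out.append({"metric": col, "r_with_alpha_z": r, "n": int(ok.sum())})
    return pd.DataFrame(out)
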