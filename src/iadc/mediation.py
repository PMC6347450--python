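"""Serial two-mediator mediation with BCa bootstrap inference.

The causal chain of interest is treatment -> tracking strength (M1) ->
within-group coordination (M2) -> spoils from winning (Y), estimated with
four least-squares regressions on group-level data:

1. ``Y  = b11 X + b10``                    (total effect)
2. ``M1 = b21 X + b20``                    (X -> M1, path a)
3. ``M2 = b31 X + b32 M1 + b30``           (M1 -> M2, path d)
4. ``Y  = b41 X + b42 M1 + b43 M2 + b40``  (M2 -> Y, path b; direct c')

The serial indirect effect is the product ``a * d * b``. Inference uses a
case-resampling bootstrap of groups with bias-corrected and accelerated
(BCa) confidence limits: the bias correction z0 is the normal quantile of
the fraction of bootstrap draws below the point estimate, and the
acceleration is the jackknife skewness of the statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    """Raise naming the first column whose addition does not raise rank."""
    rank = 0
    for j in range(X.shape[1]):
        r = np.linalg.matrix_rank(X[:, : j + 1])
        if r == rank:
            raise ValueError(f"rank-deficient design: column {names[j]!r} "
                             "is collinear with earlier terms")
        rank = r


def _ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return coef


@dataclass(frozen=True)
class MediationPaths:
    """Coefficients of the four regressions (intercepts included)."""

    total: dict        # eq 1
    m1_on_x: dict      # eq 2
    m2_on_xm1: dict    # eq 3
    y_on_xm1m2: dict   # eq 4

    @property
    def a(self) -> float:
        return self.m1_on_x["X"]

    @property
    def d(self) -> float:
        return self.m2_on_xm1["M1"]

    @property
    def b(self) -> float:
        return self.y_on_xm1m2["M2"]

    @property
    def direct(self) -> float:
        return self.y_on_xm1m2["X"]

    @property
    def indirect(self) -> float:
        return self.a * self.d * self.b


@dataclass(frozen=True)
class MediationResults:
    paths: MediationPaths
    indirect: float
    se: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int | None
    method: str          # "bca" or "percentile" (degenerate fallback)
    n_obs: int

    def summary(self) -> str:
        p = self.paths
        return "\n".join(
            [
                "Serial mediation  X -> M1 -> M2 -> Y",
                f"  n = {self.n_obs} groups, {self.n_boot} bootstrap resamples"
                f" ({self.method})",
                f"  a  (X -> M1):   {p.a: .4f}",
                f"  d  (M1 -> M2):  {p.d: .4f}",
                f"  b  (M2 -> Y):   {p.b: .4f}",
                f"  c' (direct):    {p.direct: .4f}",
                f"  total (eq 1):   {p.total['X']: .4f}",
                f"  indirect a*d*b: {self.indirect: .4f}  SE = {self.se:.4f}",
                f"  95% CI:         [{self.ci_low: .4f}, {self.ci_high: .4f}]",
            ]
        )


def fit_serial_mediation(X, M1, M2, Y) -> MediationPaths:
    """The four OLS fits of the serial mediation chain."""
    X, M1, M2, Y = (np.asarray(v, dtype=float).ravel() for v in (X, M1, M2, Y))
    n = len(X)
    if not (len(M1) == len(M2) == len(Y) == n):
        raise ValueError("X, M1, M2, Y must be aligned")
    if np.isnan(np.concatenate([X, M1, M2, Y])).any():
        raise ValueError("missing values: apply listwise deletion first")
    one = np.ones(n)
    D2 = np.column_stack([one, X])
    D3 = np.column_stack([one, X, M1])
    D4 = np.column_stack([one, X, M1, M2])
    _check_rank(D4, ["intercept", "X", "M1", "M2"])
    c1 = _ols(D2, Y)
    c2 = _ols(D2, M1)
    c3 = _ols(D3, M2)
    c4 = _ols(D4, Y)
    return MediationPaths(
        total={"intercept": c1[0], "X": c1[1]},
        m1_on_x={"intercept": c2[0], "X": c2[1]},
        m2_on_xm1={"intercept": c3[0], "X": c3[1], "M1": c3[2]},
        y_on_xm1m2={"intercept": c4[0], "X": c4[1], "M1": c4[2], "M2": c4[3]},
    )


def _indirect_batch(X, M1, M2, Y) -> np.ndarray:
    """Indirect effect a*d*b for each row of (B, n) sample matrices."""
    B, n = X.shape
    one = np.ones_like(X)

    def batched_slope(cols, y, want):
        # cols: list of (B, n) regressors incl. intercept; want: index
        G = np.stack(cols, axis=1)                      # (B, k, n)
        XtX = np.einsum("bkn,bln->bkl", G, G) / n       # O(1) entries
        Xty = np.einsum("bkn,bn->bk", G, y) / n
        k = XtX.shape[1]
        ok = np.abs(np.linalg.det(XtX)) > 1e-12
        coef = np.full((XtX.shape[0], k), np.nan)
        if ok.any():
            coef[ok] = np.linalg.solve(XtX[ok], Xty[ok, :, None])[..., 0]
        return coef[:, want]

    a = batched_slope([one, X], M1, 1)
    d = batched_slope([one, X, M1], M2, 2)
    b = batched_slope([one, X, M1, M2], Y, 3)
    return a * d * b


def bootstrap_indirect(
    X, M1, M2, Y,
    n_boot: int = 5000,
    seed: int | None = None,
    ci_level: float = 0.95,
) -> MediationResults:
    """Case-resampling bootstrap of the serial indirect effect with BCa CI.

    Groups (rows) are resampled with replacement; each resample refits the
    three mediator/outcome regressions. If the bootstrap distribution is
    degenerate (all draws identical) the interval falls back to the
    percentile method with a warning. Requires at least 10 groups.
    """
    X, M1, M2, Y = (np.asarray(v, dtype=float).ravel() for v in (X, M1, M2, Y))
    n = len(X)
    if n < 10:
        raise ValueError("need at least 10 groups for bootstrap inference")
    paths = fit_serial_mediation(X, M1, M2, Y)
    point = paths.indirect

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    with np.errstate(all="ignore"):
        boot = _indirect_batch(X[idx], M1[idx], M2[idx], Y[idx])
    boot = boot[np.isfinite(boot)]
    if len(boot) < n_boot * 0.9:
        warnings.warn("more than 10% of bootstrap resamples were singular")
    se = float(boot.std(ddof=1)) if len(boot) > 1 else 0.0

    alpha = (1.0 - ci_level) / 2.0
    method = "bca"
    if np.ptp(boot) <= 1e-12 * max(1.0, abs(point)):
        warnings.warn("degenerate bootstrap distribution; falling back to "
                      "the percentile interval")
        method = "percentile"
        lo = hi = float(boot[0]) if len(boot) else point
        return MediationResults(paths, point, se, lo, hi, n_boot, seed,
                                method, n)

    # bias correction: fraction of draws below the point estimate
    frac = np.clip(np.mean(boot < point), 1.0 / len(boot),
                   1.0 - 1.0 / len(boot))
    z0 = stats.norm.ppf(frac)
    # acceleration: jackknife skewness
    jack = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        jack[i] = fit_serial_mediation(X[mask], M1[mask], M2[mask],
                                       Y[mask]).indirect
        mask[i] = True
    jm = jack.mean()
    num = np.sum((jm - jack) ** 3)
    den = 6.0 * np.sum((jm - jack) ** 2) ** 1.5
    acc = num / den if den > 0 else 0.0

    def adj(a_level):
        z = stats.norm.ppf(a_level)
        return stats.norm.cdf(z0 + (z0 + z) / (1.0 - acc * (z0 + z)))

    lo_q, hi_q = adj(alpha), adj(1.0 - alpha)
    ci_low, ci_high = np.quantile(boot, [lo_q, hi_q])
    return MediationResults(paths, point, se, float(ci_low), float(ci_high),
                            n_boot, seed, method, n)


class SerialMediation:
    """Model object for the serial two-mediator chain.

    ``SerialMediation(X, M1, M2, Y).fit()`` returns point estimates only;
    ``.fit(n_boot=5000, seed=...)`` adds BCa bootstrap inference.
    """

    def __init__(self, X, M1, M2, Y):
        self.X, self.M1, self.M2, self.Y = X, M1, M2, Y

    @classmethod
    def from_dataframe(cls, df, x: str, m1: str, m2: str, y: str,
                       dropna: bool = True) -> "SerialMediation":
        sub = df[[x, m1, m2, y]]
        if dropna:
            sub = sub.dropna()
        return cls(sub[x], sub[m1], sub[m2], sub[y])

    def fit(self, n_boot: int | None = None, seed: int | None = None,
            ci_level: float = 0.95):
        if n_boot is None:
            return fit_serial_mediation(self.X, self.M1, self.M2, self.Y)
        return bootstrap_indirect(self.X, self.M1, self.M2, self.Y,
                                  n_boot=n_boot, seed=seed, ci_level=ci_level)
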