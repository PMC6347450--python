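"""Independent oracles used only by the test suite.

These deliberately avoid the package's own code paths: support enumeration
for bimatrix games, brute-force enumeration of group-total distributions
and expected payoffs, and hand-computed one-way ANOVA mean squares.
"""

from itertools import combinations, product

import numpy as np


def support_enumeration(A: np.ndarray, B: np.ndarray, tol: float = 1e-10):
    """All Nash equilibria of the bimatrix game (A, B) by support enumeration.

    Suitable for small games only. Returns a list of (x, y) strategy pairs.
    """
    m, n = A.shape
    equilibria = []
    rows = range(m)
    cols = range(n)
    for ka in range(1, m + 1):
        for kb in range(1, n + 1):
            for sa in combinations(rows, ka):
                for sb in combinations(cols, kb):
                    eq = _solve_support(A, B, list(sa), list(sb), tol)
                    if eq is not None:
                        equilibria.append(eq)
    # deduplicate
    uniq = []
    for x, y in equilibria:
        if not any(np.allclose(x, x2, atol=1e-8) and np.allclose(y, y2, atol=1e-8)
                   for x2, y2 in uniq):
            uniq.append((x, y))
    return uniq


def _solve_support(A, B, sa, sb, tol):
    m, n = A.shape
    ka, kb = len(sa), len(sb)
    # y over sb making row player indifferent across sa; x over sa for col.
    My = np.zeros((ka + 1, kb + 1))
    My[:ka, :kb] = A[np.ix_(sa, sb)]
    My[:ka, kb] = -1.0          # common payoff v
    My[ka, :kb] = 1.0           # sum y = 1
    rhs_y = np.zeros(ka + 1)
    rhs_y[ka] = 1.0
    Mx = np.zeros((kb + 1, ka + 1))
    Mx[:kb, :ka] = B[np.ix_(sa, sb)].T
    Mx[:kb, ka] = -1.0
    Mx[kb, :ka] = 1.0
    rhs_x = np.zeros(kb + 1)
    rhs_x[kb] = 1.0
    try:
        sol_y, res_y, rank_y, _ = np.linalg.lstsq(My, rhs_y, rcond=None)
        sol_x, res_x, rank_x, _ = np.linalg.lstsq(Mx, rhs_x, rcond=None)
    except np.linalg.LinAlgError:
        return None
    if np.linalg.norm(My @ sol_y - rhs_y) > 1e-8:
        return None
    if np.linalg.norm(Mx @ sol_x - rhs_x) > 1e-8:
        return None
    y = np.zeros(n)
    y[sb] = sol_y[:kb]
    v = sol_y[kb]
    x = np.zeros(m)
    x[sa] = sol_x[:ka]
    w = sol_x[ka]
    if (x < -tol).any() or (y < -tol).any():
        return None
    x = np.clip(x, 0, None); x /= x.sum()
    y = np.clip(y, 0, None); y /= y.sum()
    # best-response conditions off support
    if (A @ y > v + 1e-8).any():
        return None
    if (x @ B > w + 1e-8).any():
        return None
    return x, y


def bimatrix_epsilon(A, B, x, y) -> float:
    """Best-response gap of (x, y) in the bimatrix game (A, B)."""
    return max(float((A @ y).max() - x @ A @ y),
               float((x @ B).max() - x @ B @ y))


def brute_force_group_pmf(p, n_members):
    """Group-total pmf by explicit enumeration of all member tuples."""
    k = len(p)
    out = np.zeros((k - 1) * n_members + 1)
    for combo in product(range(k), repeat=n_members):
        pr = 1.0
        for c in combo:
            pr *= p[c]
        out[sum(combo)] += pr
    return out


def mc_member_payoff(role, c, teammate_pmf, opponent_pmf, endowment,
                     group_size, rng, n_draws=100_000):
    """Monte-Carlo expected payoff of a member, straight from the rules."""
    e, g = endowment, group_size
    t = rng.choice(len(teammate_pmf), size=n_draws, p=teammate_pmf)
    o = rng.choice(len(opponent_pmf), size=n_draws, p=opponent_pmf)
    if role == "attacker":
        win = (c + t) > o
        pay = (e - c) + win * (g * e - o) / g
    else:
        survive = o <= (c + t)
        pay = survive * (e - c)
    return pay.mean(), pay.std(ddof=1) / np.sqrt(n_draws)


def anova_icc1(groups: np.ndarray) -> float:
    """ICC(1) from explicitly written one-way ANOVA sums of squares."""
    n, k = groups.shape
    grand = groups.mean()
    ss_between = sum(k * (row.mean() - grand) ** 2 for row in groups)
    ss_within = sum(((row - row.mean()) ** 2).sum() for row in groups)
    msb = ss_between / (n - 1)
    msw = ss_within / (n * (k - 1))
    return (msb - msw) / (msb + (k - 1) * msw)
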