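"""Mixed-strategy equilibrium benchmarks for the attacker-defender contest.

Two complementary benchmarks are provided for the 3-vs-3 all-pay contest
with integer contributions 0..e and defender-favoring ties:

``level="member"``
    The six-player game taken literally: each member keeps their leftover
    ``e - c``; a winning attacker adds an equal spoils share
    ``(3e - G_D)/3``. Role-symmetric strategies are found by damped
    fictitious play over the integer grid (teammate and opponent totals via
    exact convolution), then polished to machine precision by a Newton
    solve of the support-restricted indifference system. Free-riding on
    teammates' contributions makes this equilibrium low-effort.

``level="group"``
    The representative-member (group-contest) reduction: with contributions
    perfect substitutes within a group, the contest between groups behaves
    like a two-player all-pay auction in per-member stakes — a bid
    ``x`` costs ``x``, the attacker wins iff ``x > y`` and takes the
    defender's leftover ``e - y``; the surviving defender keeps ``e - y``.
    Because the two payoffs sum to ``2e - x - y`` (a function of own bids
    only), the game is strategically zero-sum and is solved exactly by
    linear programming.

Both solvers report per-member expected contributions, the attacker win
probability, and the verified best-response gap ``epsilon``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import fsolve, linprog


def group_total_pmf(individual_pmf, n_members: int, tol: float = 1e-8) -> np.ndarray:
    """Exact n-fold convolution of a member strategy into a group-total pmf."""
    p = np.asarray(individual_pmf, dtype=float)
    if p.ndim != 1 or (p < -tol).any():
        raise ValueError("pmf must be a 1-D nonnegative array")
    if abs(p.sum() - 1.0) > tol:
        raise ValueError(f"pmf sums to {p.sum():.6f}, not 1")
    if n_members < 0:
        raise ValueError("n_members must be >= 0")
    out = np.array([1.0])
    for _ in range(n_members):
        out = np.convolve(out, p)
    s = out.sum()
    return out / s


def expected_member_payoff(
    role: str,
    own_contribution: int,
    teammate_total_pmf,
    opponent_total_pmf,
    endowment: int = 20,
    group_size: int = 3,
    tie_to_defender: bool = True,
) -> float:
    """Expected one-round payoff of a member given group-total distributions.

    The attacker keeps ``e - c`` and, when the attacker pool strictly
    exceeds the defender pool (ties go to defenders), additionally receives
    the equal spoils share ``(group_size * e - G_D) / group_size``. The
    defender keeps ``e - c`` only on survival.
    """
    e, g = endowment, group_size
    c = own_contribution
    if not 0 <= c <= e:
        raise ValueError(f"own_contribution {c} outside [0, {e}]")
    tm = np.asarray(teammate_total_pmf, dtype=float)
    opp = np.asarray(opponent_total_pmf, dtype=float)
    for name, p in (("teammate", tm), ("opponent", opp)):
        if abs(p.sum() - 1.0) > 1e-8 or (p < -1e-12).any():
            raise ValueError(f"{name} pmf is not normalized")
    tvals = np.arange(len(tm))
    if role == "attacker":
        dvals = np.arange(len(opp))
        w = opp * (g * e - dvals) / g
        cw = np.concatenate([[0.0], np.cumsum(w)])
        # attacker wins iff own + teammates > D  (or >= if ties to attacker)
        shift = 0 if tie_to_defender else 1
        idx = np.clip(c + tvals + shift, 0, len(opp))
        return float(e - c + tm @ cw[idx])
    elif role == "defender":
        cdf = np.concatenate([[0.0], np.cumsum(opp)])
        # survives iff A <= own + teammates (or < if ties to attacker)
        shift = 1 if tie_to_defender else 0
        idx = np.clip(c + tvals + shift, 0, len(opp))
        return float((e - c) * (tm @ cdf[idx]))
    raise ValueError(f"unknown role {role!r}")


@dataclass
class EquilibriumSolution:
    """A role-symmetric mixed-strategy equilibrium and derived benchmarks."""

    attacker_strategy: np.ndarray
    defender_strategy: np.ndarray
    expected_attack: float
    expected_defense: float
    attacker_win_prob: float
    epsilon: float
    iterations: int
    endowment: int
    group_size: int
    level: str
    extra_fixed_points: list = field(default_factory=list)

    @property
    def defender_survival_prob(self) -> float:
        return 1.0 - self.attacker_win_prob

    def as_dict(self) -> dict:
        return {
            "level": self.level,
            "endowment": self.endowment,
            "group_size": self.group_size,
            "attacker_strategy": self.attacker_strategy.tolist(),
            "defender_strategy": self.defender_strategy.tolist(),
            "expected_attack": self.expected_attack,
            "expected_defense": self.expected_defense,
            "attacker_win_prob": self.attacker_win_prob,
            "defender_survival_prob": self.defender_survival_prob,
            "epsilon": self.epsilon,
            "iterations": self.iterations,
        }

    def summary(self) -> str:
        return (
            f"Equilibrium ({self.level} level, e={self.endowment}, "
            f"n={self.group_size}):\n"
            f"  expected attack per member:  {self.expected_attack:8.4f} MU\n"
            f"  expected defense per member: {self.expected_defense:8.4f} MU\n"
            f"  attacker win probability:    {self.attacker_win_prob:8.4f}\n"
            f"  defender survival:           {self.defender_survival_prob:8.4f}\n"
            f"  best-response gap epsilon:   {self.epsilon:.3e}"
        )


class EquilibriumError(RuntimeError):
    """Raised when the solver cannot certify an equilibrium."""

    def __init__(self, msg: str, epsilon: float | None = None):
        super().__init__(msg)
        self.epsilon = epsilon


# ---------------------------------------------------------------------------
# member-level solver: damped fictitious play + Newton support polish
# ---------------------------------------------------------------------------

def _member_payoff_vectors(pa, pd, e, g, tie_to_defender):
    """Payoff of every own pure strategy for each role, others at (pa, pd)."""
    tm_a = group_total_pmf(pa, g - 1)
    tm_d = group_total_pmf(pd, g - 1)
    opp_a = group_total_pmf(pd, g)  # attacker faces defender totals
    opp_d = group_total_pmf(pa, g)
    n = e + 1
    dvals = np.arange(len(opp_a))
    w = opp_a * (g * e - dvals) / g
    cw = np.concatenate([[0.0], np.cumsum(w)])
    cdf = np.concatenate([[0.0], np.cumsum(opp_d)])
    tvals_a = np.arange(len(tm_a))
    tvals_d = np.arange(len(tm_d))
    ua = np.empty(n)
    ud = np.empty(n)
    shift_a = 0 if tie_to_defender else 1
    shift_d = 1 if tie_to_defender else 0
    for c in range(n):
        ua[c] = e - c + tm_a @ cw[np.clip(c + tvals_a + shift_a, 0, len(opp_a))]
        ud[c] = (e - c) * (tm_d @ cdf[np.clip(c + tvals_d + shift_d, 0, len(opp_d))])
    return ua, ud


def _epsilon(pa, pd, e, g, tie_to_defender):
    ua, ud = _member_payoff_vectors(pa, pd, e, g, tie_to_defender)
    return max(ua.max() - pa @ ua, ud.max() - pd @ ud)


def _newton_polish(pa, pd, e, g, tie_to_defender, support_tol=1e-4, rounds=25):
    """Solve the indifference system on the current supports exactly.

    Unknowns are the probabilities on each role's support plus the two
    equilibrium payoff levels; equations are within-support indifference
    and normalization. After each solve, profitable off-support strategies
    are added and zero/negative weights dropped, until the full
    best-response gap is at numerical zero.
    """
    n = e + 1
    sa = np.flatnonzero(pa > support_tol)
    sd = np.flatnonzero(pd > support_tol)
    best = (pa, pd, _epsilon(pa, pd, e, g, tie_to_defender))
    for _ in range(rounds):
        ka, kd = len(sa), len(sd)

        def sys(x):
            qa = np.zeros(n)
            qd = np.zeros(n)
            qa[sa] = x[:ka]
            qd[sd] = x[ka:ka + kd]
            va, vd = x[-2], x[-1]
            # keep utilities evaluable for slightly negative iterates
            ua, ud = _member_payoff_vectors(
                np.clip(qa, 0, None) / max(np.clip(qa, 0, None).sum(), 1e-12),
                np.clip(qd, 0, None) / max(np.clip(qd, 0, None).sum(), 1e-12),
                e, g, tie_to_defender,
            )
            return np.concatenate([
                ua[sa] - va,
                ud[sd] - vd,
                [qa[sa].sum() - 1.0, qd[sd].sum() - 1.0],
            ])

        x0 = np.concatenate([pa[sa] / pa[sa].sum(), pd[sd] / pd[sd].sum(),
                             [20.0, 10.0]])
        x, info, ier, _ = fsolve(sys, x0, full_output=True, xtol=1e-13,
                                 maxfev=4000)
        qa = np.zeros(n); qa[sa] = x[:ka]
        qd = np.zeros(n); qd[sd] = x[ka:ka + kd]
        if ier != 1 or (qa < -1e-9).any() or (qd < -1e-9).any():
            # drop most negative weight and retry, else give up on polish
            if (qa < -1e-9).any() or (qd < -1e-9).any():
                if qa.min() <= qd.min():
                    sa = sa[sa != np.argmin(qa)]
                else:
                    sd = sd[sd != np.argmin(qd)]
                if len(sa) == 0 or len(sd) == 0:
                    break
                continue
            break
        qa = np.clip(qa, 0, None); qa /= qa.sum()
        qd = np.clip(qd, 0, None); qd /= qd.sum()
        ua, ud = _member_payoff_vectors(qa, qd, e, g, tie_to_defender)
        eps = max(ua.max() - qa @ ua, ud.max() - qd @ ud)
        if eps < best[2]:
            best = (qa, qd, eps)
        if eps < 1e-11:
            break
        # grow supports with the most profitable deviations
        va, vd = qa @ ua, qd @ ud
        grow = False
        ca = np.argmax(ua)
        if ua[ca] > va + 1e-11 and ca not in sa:
            sa = np.sort(np.append(sa, ca)); grow = True
        cd = np.argmax(ud)
        if ud[cd] > vd + 1e-11 and cd not in sd:
            sd = np.sort(np.append(sd, cd)); grow = True
        if not grow:
            break
        pa, pd = qa, qd
    return best


def _qre_refine(pa, pd, e, g, tie_to_defender, taus=(0.2, 0.05, 0.02, 0.008,
                                                     0.003, 0.001)):
    """Follow the logit quantal-response branch toward the Nash limit.

    Solving the smoothed fixed point with a root finder handles
    equilibria that are unstable under forward best-response iteration.
    """
    n = e + 1
    with np.errstate(divide="ignore"):
        x = np.concatenate([np.log(pa + 1e-9), np.log(pd + 1e-9)])

    def qre_map(x, tau):
        la, ld = x[:n], x[n:]
        qa = np.exp(la - la.max()); qa /= qa.sum()
        qd = np.exp(ld - ld.max()); qd /= qd.sum()
        ua, ud = _member_payoff_vectors(qa, qd, e, g, tie_to_defender)
        ra = la - ua / tau
        rd = ld - ud / tau
        return np.concatenate([ra - ra.mean(), rd - rd.mean()])

    for tau in taus:
        x, _, ier, _ = fsolve(qre_map, x, args=(tau,), full_output=True,
                              xtol=1e-12, maxfev=20000)
    la, ld = x[:n], x[n:]
    qa = np.exp(la - la.max()); qa /= qa.sum()
    qd = np.exp(ld - ld.max()); qd /= qd.sum()
    return qa, qd


def _solve_member_level(e, g, tie_to_defender, tolerance, max_iter, damping):
    n = e + 1
    pa = np.full(n, 1.0 / n)
    pd = np.full(n, 1.0 / n)
    eps = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        ua, ud = _member_payoff_vectors(pa, pd, e, g, tie_to_defender)
        eps = max(ua.max() - pa @ ua, ud.max() - pd @ ud)
        if eps < tolerance:
            break
        step = damping / (1 + damping * it)
        bra = int(np.argmax(np.round(ua, 12)))  # argmax tie -> lower index
        brd = int(np.argmax(np.round(ud, 12)))
        pa = (1 - step) * pa
        pa[bra] += step
        pd = (1 - step) * pd
        pd[brd] += step
    if eps >= tolerance:
        pa, pd = _qre_refine(pa, pd, e, g, tie_to_defender)
    pa, pd, eps = _newton_polish(pa, pd, e, g, tie_to_defender)
    if eps >= tolerance:
        raise EquilibriumError(
            f"member-level solver did not converge: epsilon={eps:.3e} after "
            f"{it} fictitious-play iterations plus Newton polish",
            epsilon=eps,
        )
    win = _win_probability_iid(pa, pd, g, tie_to_defender)
    vals = np.arange(n)
    return EquilibriumSolution(
        pa, pd, float(pa @ vals), float(pd @ vals), win, float(eps), it,
        e, g, "member",
    )


def _win_probability_iid(pa, pd, g, tie_to_defender=True):
    """P(attacker total beats defender total), members drawing iid."""
    A = group_total_pmf(pa, g)
    D = group_total_pmf(pd, g)
    cdfD = np.cumsum(D)
    strict = float(sum(A[k] * cdfD[k - 1] for k in range(1, len(A))))
    if tie_to_defender:
        return strict
    return strict + float(A @ D[: len(A)])


# ---------------------------------------------------------------------------
# group-level benchmark: exact LP on the strategically zero-sum reduction
# ---------------------------------------------------------------------------

def _solve_matrix_game(M):
    """Max-min mixed strategy of the row player in zero-sum matrix M."""
    m, n = M.shape
    c = np.zeros(m + 1)
    c[-1] = -1.0
    A_ub = np.hstack([-M.T, np.ones((n, 1))])
    A_eq = np.zeros((1, m + 1))
    A_eq[0, :m] = 1.0
    res = linprog(
        c, A_ub=A_ub, b_ub=np.zeros(n), A_eq=A_eq, b_eq=[1.0],
        bounds=[(0, None)] * m + [(None, None)], method="highs",
    )
    if not res.success:
        raise EquilibriumError(f"LP failed: {res.message}")
    p = np.clip(res.x[:m], 0, None)
    return p / p.sum()


def reduced_contest_payoffs(endowment: int, tie_to_defender: bool = True):
    """Per-member stake bimatrix of the representative-member contest."""
    e = endowment
    x = np.arange(e + 1)[:, None]  # attacker bid per member
    y = np.arange(e + 1)[None, :]  # defender bid per member
    win = (x > y) if tie_to_defender else (x >= y)
    ua = (e - x + win * (e - y)).astype(float)
    ud = (np.where(win, 0, e - y) + 0.0 * x).astype(float)
    return ua, ud


def _solve_group_level(e, g, tie_to_defender, tolerance):
    ua_m, ud_m = reduced_contest_payoffs(e, tie_to_defender)
    # payoffs sum to f(x)+g(y): subtract the y-part from ua -> zero-sum game
    total = ua_m + ud_m
    if not np.allclose(total, total[:, :1] + total[:1, :] - total[0, 0]):
        raise EquilibriumError("reduction lost strategic zero-sum structure")
    M = ua_m - (total[:1, :] - total[0, 0])
    pa = _solve_matrix_game(M)
    pd = _solve_matrix_game(-M.T)
    ua = ua_m @ pd
    ud = pa @ ud_m
    eps = max(ua.max() - pa @ ua, ud.max() - pd @ ud)
    if eps >= tolerance:
        raise EquilibriumError(f"LP equilibrium fails epsilon check: {eps:.3e}",
                               epsilon=eps)
    cdfd = np.cumsum(pd)
    win = float(sum(pa[k] * cdfd[k - 1] for k in range(1, e + 1)))
    if not tie_to_defender:
        win += float(pa @ pd)
    vals = np.arange(e + 1)
    return EquilibriumSolution(
        pa, pd, float(pa @ vals), float(pd @ vals), win, float(eps), 1,
        e, g, "group",
    )


def solve_symmetric_equilibrium(
    endowment: int = 20,
    group_size: int = 3,
    tie_to_defender: bool = True,
    tolerance: float = 1e-3,
    max_iter: int = 5000,
    damping: float = 0.5,
    level: str = "member",
) -> EquilibriumSolution:
    """Solve for a role-symmetric mixed-strategy equilibrium.

    Parameters
    ----------
    level : {"member", "group"}
        "member" solves the literal six-player game (damped fictitious play
        with exact convolutions, Newton-polished). "group" solves the
        representative-member reduction exactly by linear programming; this
        is the benchmark usually quoted for team all-pay contests.
    tolerance : certified best-response gap required for success.
    max_iter, damping : fictitious-play controls (member level only).
    """
    if endowment < 0:
        raise ValueError("endowment must be nonnegative")
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    if endowment == 0:
        point = np.array([1.0])
        return EquilibriumSolution(
            point, point.copy(), 0.0, 0.0,
            0.0 if tie_to_defender else 1.0, 0.0, 0,
            endowment, group_size, level,
        )
    if level == "group" or group_size == 1:
        sol = _solve_group_level(endowment, group_size, tie_to_defender,
                                 tolerance)
        return EquilibriumSolution(
            sol.attacker_strategy, sol.defender_strategy,
            sol.expected_attack, sol.expected_defense, sol.attacker_win_prob,
            sol.epsilon, sol.iterations, endowment, group_size, level,
        )
    if level != "member":
        raise ValueError(f"unknown level {level!r}")
    return _solve_member_level(
        endowment, group_size, tie_to_defender, tolerance, max_iter, damping
    )
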