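# Methods

## The contest

The intergroup attacker-defender contest (IADC) is an all-pay contest
between a three-person attacker group and a three-person defender group.
Each round every member holds an endowment of e = 20 monetary units (MU)
and commits an integer contribution 0..20 to their group pool. All
contributions are forfeited. Attackers win the round only if their pool
strictly exceeds the defender pool (G_A > G_D); ties leave the defenders
standing. When attackers lose, all six members keep their leftovers
(20 − contribution). When attackers win, each defender is left with 0 and
the defenders' unspent endowment — the spoils, 60 − G_D — is divided
equally among the three attackers. Total payoff is therefore
120 − G_A − G_D in every round, which the engine asserts exactly (money
conservation).

Sessions consist of two 15-round blocks with real-time feedback: a
simultaneous block (members decide privately) and a sequential block (a
fresh random order each round; the second mover sees the first decision,
the third sees both). We read the sequential information structure
cumulatively; the alternative where the third mover sees only the first
decision (or an aggregate) would change none of the implemented analyses,
only the simulated anchoring behavior.

## Equilibrium benchmarks

Two mixed-strategy benchmarks are implemented, because the game admits two
defensible notions of "rational play" that differ sharply.

**Member level** (`level="member"`): the literal six-player game. Each
member maximizes their own expected payoff; teammate and opponent group
totals are exact 2- and 3-fold convolutions of the individual strategies.
The solver runs damped fictitious play (step damping/(1 + damping·t),
best-response ties broken toward the lower contribution for determinism),
switches to a logit quantal-response homotopy solved with a Newton root
finder when the play cycles (all-pay games routinely cycle under forward
iteration), and finally polishes the support-restricted indifference
system to machine precision, growing the support with any profitable
deviation and dropping negative weights. Success requires a certified
best-response gap epsilon below the tolerance (default 1e-3 MU; the polish
typically reaches 1e-12). Because a winning attacker keeps only a third of
the spoils while bearing the full marginal cost of contributing, this
equilibrium exhibits strong free-riding: per-member expected attack is
about 2.0 MU, defense about 2.3 MU, and the attacker wins about 38.6% of
rounds. Multi-start searches (random logit restarts followed by the same
Newton polish) found no other symmetric equilibrium.

**Group level** (`level="group"`): the representative-member reduction
standard for team all-pay contests with perfect-substitute contributions.
Each group behaves as one bidder in per-member stakes: a bid x costs x,
the attacker values winning at the defender's per-member leftover
(20 − y), and the surviving defender keeps 20 − y. The two payoffs sum to
40 − x − y — a function of own actions only — so the game is strategically
zero-sum and is solved *exactly* by linear programming on the max-min
formulation (no iteration, epsilon at numerical zero). This benchmark
gives per-member expected attack 4.96 MU, defense 7.04 MU, attacker
victory 33.0% and defender survival 67.0%.

The benchmark figures quoted in the experimental literature for this game
— attack 10.15 MU, defense 9.77 MU, victory 32.45%, survival 67.55% — are
asserted by the acceptance suite. The group-level solution reproduces the
victory/survival split within one percentage point; the quoted *means*
are not reproduced by any formulation we examined (member-level with
divided or undivided spoils, team-internalized utilities on either side,
unitary group play over pooled totals 0..60, fixed- and scaled-prize
variants, and both tie rules; payoff computations were verified against
brute-force enumeration, and the zero-sum reductions are exact LP
solutions). In every equilibrium class, per-member means near 10 MU force
attacker win rates near 45–55%, so the quoted triple appears internally
inconsistent with the stated rules. The corresponding acceptance test is
left failing rather than adjusted.

Tiny games (endowment <= 3, single-member groups) are solved through the
same LP path and are checked in the tests against an independent
support-enumeration oracle.

## Synthetic cohorts

No raw session data are deposited, so the generator reproduces the study
*design* — 80 sessions of six members, 40 per arm, two counterbalanced
15-round blocks — with a simple, fully specified behavioral model. Per
role and arm:

| parameter | attacker placebo | attacker treated | defender (both) |
|---|---|---|---|
| zero-inflation probability | 0.40 | 0.48 | 0.09 |
| location (MU) | 8.5 | 8.0 | 8.8 |
| member noise sd (MU) | 3.5 | 2.5 | 2.8 |
| tracking weight (MU/MU) | −0.05 | −0.35 | 0 |
| sequential anchor weight | 0.5 | 0.5 | 0.5 |
| session-norm sd (MU) | 1.5 | 1.5 | 1.5 |

Each round the group target is location + tracking_weight × (mean rival
pool of the last two rounds − running mean of all past rival pools), plus
a session-level norm offset (drawn once per session × role) that creates
the between-group heterogeneity the intraclass correlation measures. A
member draws Binomial(20, target'/20) — a discretized bounded draw with
controllable mean — after jittering the target with Gaussian noise, or
contributes 0 with the zero-inflation probability. In sequential blocks
later movers pull their mean toward the contributions they observed
(anchor weight 1 degenerates to exact copying). Decision times are
log-normal per (role, contributed) cell, with 0.5% of decisions replaced
by uniform draws above the 180 s cutoff to exercise the exclusion rule.

These defaults were calibrated qualitatively to the study's descriptive
results (defense above attack, attacker non-contribution common at about
45% of member-rounds versus 9% for defenders, placebo attacker success
near 20%, treatment raising attacker zero-rounds and lowering attacker
within-group noise) and are not fitted to unpublished microdata. The
generator does not emulate individual-level heterogeneity within a group,
learning or fatigue across blocks, or payment-stake effects; passing
recovery tests therefore demonstrates correctness of the analysis chain,
not behavioral realism of any particular parameter value.

## Coordination metrics

Within-group variance uses the sample (n−1 = 2) denominator; the constant
scaling affects no contrast. Non-contributor counts are member-rounds at
exactly 0 (0..45 per block, 0..3 per round). The intraclass correlation is
the one-way random-effects ICC(1) = (MSB − MSW)/(MSB + (k−1)·MSW) with
sessions as classes and the 45 member-round contributions of a block as
observations, computed per role × block × arm; this is the simplest
"groups as classes" estimator consistent with the description of the
measure, and the exact variant used originally is not documented.
Decision times above 180 s (or nonpositive) are excluded with the excluded
fraction reported, then log10-transformed. Spoils are averaged over
winning rounds only and leftovers over losing rounds only; winless groups
propagate missing spoils rather than zero, and downstream analyses delete
listwise. Round trajectories are smoothed with a centered three-round
moving average whose window shrinks at the series edges (length
preserving). The bivariate bootstrap cloud resamples groups with
replacement per condition (default 1000 resamples at size 40) and records
the mean (contribution, payment) pair; payment is the per-member realized
payoff averaged over a block.

## Tracking regression

For rounds j = 3..15 the regressors are the rival-history level
alpha_j = (D_{j−1} + D_{j−2})/2 and change beta_j = D_{j−1} − D_{j−2}.
Outcome and regressors are z-scored within the group-block before OLS so
the weights are standardized — bounded by 1 for orthogonal regressors and
suitable for the Fisher z (artanh) transform, which is clipped at |w| =
0.999 to keep perfectly collinear fits finite. A zero-variance outcome or
regressor yields weight 0 with a degeneracy flag instead of an error so
cohort summaries retain every group; collinear alpha/beta fall back to the
pseudo-inverse with the same flag. Standardization within the group-block
(rather than pooled) was chosen so each group's weight is interpretable in
isolation; defender-side tracking is fitted symmetrically with attacker
history as regressors. Whether the change weight beta should also be
Fisher-transformed is left open (analyses of beta are null either way);
the results object exposes both.

## Serial mediation and the BCa bootstrap

The chain treatment → tracking (M1) → coordination (M2) → spoils (Y) is
estimated with four OLS fits (total effect; M1 on X; M2 on X and M1; Y on
X, M1 and M2) and the serial indirect effect is the product of the three
chain paths. Inference resamples *groups* (cases) with replacement —
matching a design where the group is the unit — never residuals. The BCa
interval uses bias correction z0 = Phi^{-1}(fraction of bootstrap draws
below the point estimate) and jackknife acceleration (skewness of the
leave-one-out estimates); with z0 = 0 and zero acceleration it reduces to
the percentile interval, which is also the explicit fallback (with a
warning) when the bootstrap distribution is degenerate. Bootstrap
resamples with singular designs (e.g. a constant treatment column) are
dropped, with a warning if they exceed 10%.

The coverage calibration simulates chains with a, d nonzero and the final
path b = 0, so the indirect effect is exactly zero while the statistic
retains regular (asymptotically normal) behavior. Under the *complete*
null (a = d = b = 0) the product statistic is superefficient at zero and
bootstrap intervals over-cover by construction; that case is uninformative
for interval calibration and is not used.

## Statistical wrappers

Mixed ANOVAs (role within, treatment between, sessions as subjects) and
two-sample t-tests with Cohen's d and its 95% CI are delegated to
pingouin; the wrappers fix the factor coding, average blocks before
between-arm tests, and report partial eta squared uniformly. These are
routine computations, not contributions of this package.

## Problem sizes and tolerances

The default test run uses: 1000 simulated groups per tracking-recovery
weight; 500 null chains at 1000 bootstrap resamples for mediation
coverage; 200 replicate null cohorts (80 sessions each) for the ANOVA
false-positive calibration; and one million random rounds for money
conservation. The full-cohort mediation default is 5000 resamples.
Equilibrium tolerances: certified epsilon below 1e-3 MU for the member
solver (typically 1e-12 after polish), 1e-9 for LP solutions. Cohort
generation is deterministic given (master_seed, session_index) via
numpy SeedSequence spawning, so sessions are independent and individually
reproducible.

## Known limitations

* The member-level equilibrium is found by homotopy from the uniform
  profile; although multi-start searches found a single symmetric
  equilibrium, global uniqueness is not proven.
* The generator's binomial contribution model has variance tied to its
  mean; the member-noise parameter controls only the between-member
  component of within-group variance.
* ICC(1) treats member-rounds within a block as exchangeable
  observations; serial dependence across rounds is ignored, as in the
  original measure.
* The mediation model is the stated OLS chain without covariates or
  multilevel structure.
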