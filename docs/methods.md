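# Methods

## Model

The transmission game couples a standard susceptible–infected contact
process to an incentivized binary choice.  The population of *N* players
(even, default 100) holds a color state, blue or purple, with purple
absorbing.  Before round 1, exactly *n₀* = 8 players drawn uniformly
without replacement are purple.  Each of *T* = 25 rounds proceeds:

1. every player chooses G or H; choices are exogenous functions of the
   round index only (the game is asynchronous — no color feedback exists,
   so no strategy can condition on the epidemic state);
2. a perfect matching of the *N* players is drawn uniformly at random;
3. in every mixed (blue–purple) pair the blue member turns purple with
   probability `p_gg`, `p_gh` or `p_hh` according to the pair's two
   actions; like-colored pairs never change.  Pairs are disjoint, so all
   transitions within a round are simultaneous and newly infected players
   transmit only from the next round;
4. every player (purple included) accrues the points of their action:
   purple players keep choosing, and their actions still modulate the risk
   of their blue partners.

After round *T*, blue players earn `points / points_per_currency` GBP;
purple players earn 0.

Parameters, defaults and units:

| parameter | default | meaning |
|---|---|---|
| `n_players` | 100 | population size (must be even; the matching admits no sit-out) |
| `n_rounds` | 25 | decision rounds |
| `n_initial_purple` | 8 | seeded infections (exact count, not i.i.d.) |
| `p_gg`, `p_gh`, `p_hh` | 0.05, 0.15, 0.25 | mixed-pair transmission probability by pair actions; must be non-decreasing |
| `value_g`, `value_h` | 8, 40 | points per round |
| `points_per_currency` | 200 | points per GBP at settlement |

The three pair probabilities are stored explicitly rather than as
base + increment so that non-default configurations need not form an
arithmetic progression; the defaults satisfy the 0.05 + 0.1·(#H) rule.
Scores are kept in whole points internally; conversion to currency happens
only at reporting.

## Uniform matching and the mixed-pair distribution

A uniformly shuffled order paired consecutively is exactly uniform over
all (N−1)!! perfect matchings (tested empirically for N = 4: each of the 3
matchings appears with frequency 1/3 within Monte-Carlo error).  With *n*
purple players, the number of mixed pairs *m* satisfies

    P(m) = C(n, m) · C(N−n, m) · m! · M(n−m) · M(N−n−m) / M(N),

where M(k) = (k−1)!! counts perfect matchings of k items (M(0)=1, M odd =
0): choose the purple and blue members of mixed pairs, match them m! ways,
and match both residual groups internally.  The support requires n−m even.
M(k) is evaluated in log space (`lgamma`) so N = 100 does not overflow; an
exact rational mode (`exact=True`, `fractions.Fraction`) backs the small-N
oracle comparisons.

## Exact solvers

**Homogeneous populations.**  When all players follow the same sequence,
exchangeability makes the purple count a Markov chain on {0,…,N}.  Round
*t* uses the pair probability of that round's universal action; the number
of new infections given *m* mixed pairs is Binomial(m, p).  Transition
matrices of size (N+1)² are precomputed and cached per distinct p.  A
normalization guard re-scales each round and raises if total mass drifts
by more than 1e-10.

**Single deviant.**  One focal player follows a different sequence than
the shared population.  The joint state is (purple count *j* among the
N−1 others, deviant color).  Each round decomposes exactly: the deviant's
partner is uniform over the others (purple with probability j/(N−1)); the
deviant's pair uses the probability of (deviant action, shared action);
conditional on the partner, the residual N−2 others are uniformly matched
among themselves and evolve by the homogeneous law.  This decomposition is
*validated, not assumed*: both solvers match a brute-force enumeration
oracle — exhaustive over initial outbreaks, matchings and infection
subsets in exact rational arithmetic — to ≤ 1e-12 at N ∈ {2, 4, 6},
T ≤ 3.

Expected payoffs follow as `points(seq)/rate × P(blue at end)`: points are
deterministic given the sequence, so only survival is random.

## Monte-Carlo engine

`run_game` is the per-game reference implementation.  `simulate_ensemble`
advances all replicates in lockstep: per round, one (reps × N) uniform
draw is argsorted row-wise to give every replicate an independent uniform
permutation, pairs are the consecutive entries, and infections are applied
with one vectorized Bernoulli draw per pair.  A single
`numpy.random.Generator` seeded from `SeedSequence(seed)` drives
everything — strategy realization, outbreak seeding, matchings,
transmissions — in a fixed order, so the same seed and inputs give a
bit-identical summary regardless of platform.  The engine was chosen over
per-replicate substreams because it keeps 50,000-game ensembles in the
low seconds while preserving the reproducibility contract; the two paths
are cross-checked distributionally in the tests.

Prediction bands at coverage q are the central empirical percentile
intervals [(50−q/2)%, (50+q/2)%] per round (NumPy's linear interpolation);
the same interpolation at nested q yields nested intervals.  The mean
payoff scores purple players 0.  Optional `bootstrap_rows` resamples
choice-matrix rows with replacement independently per replicate, a
robustness check on the strategy composition.

Problem sizes used by the shipped checks: 10,000 replicates for the
uniform-strategy baselines, 20,000 per grid point for the payoff sweep,
50,000 for the simulator/analytic cross-validation — sizes at which the
Monte-Carlo standard error is comfortably below each comparison's
tolerance.

## Strategy patterns and synthetic cohorts

Realized sequences partition into all-safe (Gᵀ), all-risky (Hᵀ),
risky-safe (Hʰ G^{T−h}, 1 ≤ h ≤ T−1) and switch (everything else).  A
single safe→risky change falls in *switch*: the taxonomy defines only the
risky→safe single change as its own class, and the residual class absorbs
the rest.  The partition is verified exhaustively over all 2ᵀ sequences
for T ≤ 12.

The cohort generator draws each player's pattern from explicit weights —
default 148/600, 73/600, 93/600, 286/600, the exact reference counts
(their rounded percentages sum to 100.1%, so the counts are used) — then
fills rows by construction; switch rows are i.i.d. Bernoulli(p_H) draws
rejection-sampled until they classify as switch, guaranteeing label
fidelity.  Defaults chosen once:

* `risky_safe_h`: uniform on 1..T−1 — no empirical switch-round
  distribution is available; this is a placeholder and the main caveat
  when interpreting cohort-based simulations.
* `switch_p_h` = 0.329, calibrated so the default mixture's expected
  overall risky-choice rate matches the reported 35.6%:
  (73/600)·1 + (93/600)·0.5 + (286/600)·p = 0.356.

The generator reproduces marginal pattern frequencies and the aggregate
risky rate; it does **not** model round trends (e.g. risk declining over
rounds), within-player autocorrelation beyond the pattern classes, or
covariates such as risk attitude.  Passing cohort-based tests therefore
shows the machinery is correct for the stated mixture, not that any
particular empirical population is reproduced; per-participant matrices
would be required for that, and results depending on them (such as a
realized-cohort outbreak rate) are only qualitatively approximable here.

## Findings the exact analysis adds

Two results of the package's own analyses sharpen coarser claims that
motivated the game design:

* **The risky action's dominance has a boundary exception.**  Against
  every shared strategy tested except one, a lone all-H deviant strictly
  out-earns a lone all-G deviant (e.g. 2.698 vs 0.770 GBP against an
  all-safe population).  Against a fully risky population the exact chain
  puts the *safe* deviant marginally ahead: 0.10038 vs 0.10011 GBP, a
  0.28% relative gap that 10⁵–10⁶-replicate simulations cannot resolve
  (the 400,000-replicate check in this package agrees with the exact
  values within its standard error).  Single-round deviations toward H
  still always pay; it is the compounding of 25 of them at the highest
  exposure level that narrowly tips the balance.
* **The population optimum sits near, not below, a 10% risky share.**  On
  a unit-step grid over the number of always-H players, mean population
  payoff peaks at k = 12 (0.8376 ± 0.0001 GBP at 500,000 replicates per
  point, versus 0.8360 at k = 10); on a 10-point grid the maximum appears
  at 10%.  Adjacent grid points differ by less than a typical 5,000-
  replicate standard error, so sweep argmaxes at moderate replicate
  counts scatter over roughly 10–14.

## Numerical choices and edge cases

* Probability vectors are renormalized each round behind a 1e-10 drift
  guard; enumeration comparisons run at 1e-12.
* T = 0 games are legal and return the outbreak point mass.
* `n_initial_purple = N` gives all-zero payoffs; zero transmission
  probabilities freeze the outbreak and collapse all prediction bands.
* Odd population sizes are rejected everywhere (parameters, CSV reader,
  matching) — the model defines no sit-out rule.
* Ties in the payoff sweep resolve to the first (smallest-k) maximum.

## Known limitations

No recovery or removal dynamics, no heterogeneous susceptibility, no
within-game feedback to strategies — all deliberate properties of the
game being modeled.  The analytic module covers homogeneous and
single-deviant scenarios only; heterogeneous mixtures (k risky vs N−k
safe) are simulated, not solved, as a multi-class exact chain was out of
scope.  Cohort realism is bounded by the aggregate statistics listed
above.
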