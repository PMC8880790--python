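# transgame

Simulation and exact analysis of the **pairwise transmission game**: a
discrete-round epidemic game used to study risk-taking under outbreak
dynamics with real monetary stakes.

## The game

An even population of *N* players (default 100) starts "blue"; *n₀* players
(default 8) are switched to "purple" (infected) before play.  In each of
*T* rounds (default 25) every player — without ever seeing any colors —
chooses between

* **G** (safe): 8 points, low transmission risk, and
* **H** (risky): 40 points, high transmission risk.

All players are then paired by a uniform random perfect matching.  In a
mixed (blue–purple) pair the blue player turns purple with probability

| pair actions | GG | GH/HG | HH |
|---|---|---|---|
| transmission probability | 0.05 | 0.15 | 0.25 |

(i.e. a base 0.05 plus 0.1 per H chosen in the pair).  Purple is
absorbing.  After round *T*, blue players convert their accumulated points
into money at 1 GBP per 200 points; purple players earn nothing — so the
maximum stake is 25 × 40 / 200 = GBP 5.00.

This is a social dilemma with a risk–reward tradeoff: risky choices raise a
player's own expected payoff in essentially all populations while degrading
everyone else's survival odds.

## What the package computes

* **`transgame.simulator`** — a rep-vectorized Monte-Carlo engine:
  ensembles of 10⁴–10⁵ games in seconds, with per-round means, medians and
  central prediction bands (inner 10/25/67/95% by default), optional
  row-bootstrap of the choice matrix, and a bit-reproducible seeding
  contract.
* **`transgame.analytic`** — exact solvers that replace simulation for two
  scenario families.  When all players share one strategy, the purple count
  is a Markov chain on {0,…,N}: the number of mixed pairs *m* under a
  uniform matching has pmf ∝ C(n,m)·C(N−n,m)·m!·M(n−m)·M(N−n−m) with
  M(k)=(k−1)!!, and new infections are Binomial(m, p).  A single deviant
  against a shared strategy is solved exactly on the joint state
  (others' purple count, deviant color).  Both are validated against
  brute-force enumeration over all matchings and infection outcomes at
  small N.  `best_response_table` turns deviant survival into expected
  payoffs.
* **`transgame.strategies`** — constructors for round-indexed strategies
  and classification of realized sequences into the four decision patterns
  (*all-safe*, *all-risky*, *risky-safe* = front-loaded H block, *switch* =
  residual).
* **`transgame.cohort`** — synthetic cohorts mixing the four patterns at
  the empirically reported proportions (24.7/12.2/15.5/47.7%) with an
  overall risky-choice rate calibrated to 35.6%.
* **`transgame.cli`** — a `transgame` command with `simulate`, `analytic`,
  `deviant`, `bestresponse`, `classify` and `cohort` subcommands, CSV/JSON
  I/O and run manifests.

## Worked example

```sh
$ transgame analytic --strategy allG
expected final purple: 22.952 of 100 (22.95%)
```

With everyone safe, the exact chain says 22.95% of players end purple on
average — even universal caution loses about a quarter of the population,
because mixed GG pairs still transmit at 0.05.

```sh
$ transgame simulate --strategy allG --reps 10000 --seed 7
final mean purple: 22.92% (MC SE ~ 0.420 pp); mean payoff GBP 0.7708
```

The Monte-Carlo ensemble reproduces the exact value within its standard
error.  Replacing `allG` with `allH` drives the outbreak to ~98% and the
mean payoff to ~GBP 0.10.

```sh
$ transgame bestresponse
    scenario  shared_payoff  deviant_g_payoff  deviant_h_payoff  h_dominates
        allG         0.7705            0.7705            2.6982         True
 riskysafe:5         1.0372            0.6146            1.5521         True
riskysafe:15         0.5488            0.2796            0.3496         True
        allH         0.1001            0.1004            0.1001        False
```

Against safe or front-loaded populations, a lone risky deviant earns a
multiple of the safe deviant's payoff — the social-dilemma incentive.  At
the fully risky boundary the two deviants are payoff-equivalent to three
decimal places, with the safe deviant marginally ahead in the exact chain
(0.1004 vs 0.1001); see `docs/methods.md`.

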