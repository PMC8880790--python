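"""Exact probability computations for tractable scenario families.

Two scenario families admit exact solutions and replace Monte-Carlo
simulation entirely:

* **homogeneous** — every player follows the same round-indexed action
  sequence.  Players are then exchangeable and the purple count alone is a
  Markov chain on ``{0, ..., N}``.
* **single deviant** — one focal player follows a different sequence while
  the remaining ``N-1`` players share a strategy.  The joint state
  (purple count among the others, deviant color) is Markov.

The combinatorial core is the distribution of the number of mixed
(blue-purple) pairs under a uniform random perfect matching.  With ``n``
purple among ``N`` players, the probability of exactly ``m`` mixed pairs is

    P(m) = C(n, m) C(N-n, m) m! M(n-m) M(N-n-m) / M(N)

where ``M(k) = (k-1)!!`` is the number of perfect matchings of ``k`` items
(``M(0) = 1``, ``M(odd) = 0``): choose which purple and which blue players
sit in mixed pairs, match them in ``m!`` ways, and match each residual group
internally.  Given ``m`` mixed pairs and per-pair transmission probability
``p``, the number of new infections is Binomial(m, p).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from typing import Dict, List, Sequence

import numpy as np
from scipy import stats

from .core import Action, GameParams, pair_transmission_prob, strategy_points


def log_matchings(k: int) -> float:
    """log of M(k), the number of perfect matchings of ``k`` labeled items.

    M(k) = (k-1)!! = k! / (2^(k/2) (k/2)!) for even k; -inf for odd k.
    Computed in log space so N = 100 does not overflow.
    """
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    if k % 2 == 1:
        return -math.inf
    half = k // 2
    return math.lgamma(k + 1) - half * math.log(2.0) - math.lgamma(half + 1)


@lru_cache(maxsize=None)
def _matchings_exact(k: int) -> int:
    """Exact M(k) as an integer (double factorial), for the rational mode."""
    if k % 2 == 1:
        return 0
    return math.factorial(k) // (2 ** (k // 2) * math.factorial(k // 2))


def mixed_pair_pmf(N: int, n: int, exact: bool = False) -> np.ndarray | Dict[int, Fraction]:
    """Distribution of the number of mixed pairs in a uniform perfect matching.

    Parameters
    ----------
    N
        Even population size.
    n
        Current number of purple players, ``0 <= n <= N``.
    exact
        If True, return a dict ``{m: Fraction}`` computed in exact rational
        arithmetic (used by the small-N oracle comparisons); otherwise a
        float vector of length ``min(n, N-n) + 1`` indexed by ``m``.

    The support is ``m <= min(n, N-n)`` with ``n - m`` even (each residual
    group must itself admit a perfect matching).
    """
    if N < 2 or N % 2 != 0:
        raise ValueError(f"N must be even and >= 2, got {N}")
    if not 0 <= n <= N:
        raise ValueError(f"n must be in [0, N], got {n}")
    m_max = min(n, N - n)
    if exact:
        total = _matchings_exact(N)
        out: Dict[int, Fraction] = {}
        for m in range(m_max + 1):
            if (n - m) % 2 != 0:
                continue
            w = (
                math.comb(n, m)
                * math.comb(N - n, m)
                * math.factorial(m)
                * _matchings_exact(n - m)
                * _matchings_exact(N - n - m)
            )
            if w:
                out[m] = Fraction(w, total)
        return out
    log_total = log_matchings(N)
    pmf = np.zeros(m_max + 1)
    for m in range(m_max + 1):
        if (n - m) % 2 != 0:
            continue
        lw = (
            math.lgamma(n + 1)
            - math.lgamma(n - m + 1)
            + math.lgamma(N - n + 1)
            - math.lgamma(N - n - m + 1)
            - math.lgamma(m + 1)
            + log_matchings(n - m)
            + log_matchings(N - n - m)
            - log_total
        )
        pmf[m] = math.exp(lw)
    s = pmf.sum()
    if not math.isclose(s, 1.0, abs_tol=1e-10):
        raise AssertionError(f"mixed-pair pmf normalization drift: sum={s}")
    return pmf / s


def homogeneous_transition(N: int, n: int, p: float) -> np.ndarray:
    """One Markov step of the purple count under a shared per-pair probability.

    Returns the pmf (length ``N + 1``) of the next purple count
    ``n + X`` where ``X | m ~ Binomial(m, p)`` and ``m`` is the mixed-pair
    count under a uniform matching.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be a probability, got {p}")
    pmf_m = mixed_pair_pmf(N, n)
    out = np.zeros(N + 1)
    for m, pm in enumerate(pmf_m):
        if pm == 0.0:
            continue
        x = np.arange(m + 1)
        out[n + x] += pm * stats.binom.pmf(x, m, p)
    return out


@lru_cache(maxsize=None)
def _transition_matrix(N: int, p: float) -> np.ndarray:
    """(N+1)x(N+1) row-stochastic matrix; row n is homogeneous_transition."""
    T = np.zeros((N + 1, N + 1))
    for n in range(N + 1):
        T[n] = homogeneous_transition(N, n, p)
    return T


@dataclass(frozen=True)
class PurpleDistribution:
    """Exact per-round distributions of the purple count.

    ``probs`` has shape ``(T + 1, N + 1)``; row 0 is the state after the
    initial outbreak, row t the state after round t.
    """

    probs: np.ndarray

    @property
    def n_rounds(self) -> int:
        return self.probs.shape[0] - 1

    @property
    def n_players(self) -> int:
        return self.probs.shape[1] - 1

    def mean_by_round(self) -> np.ndarray:
        """Expected purple count after the outbreak and after each round."""
        counts = np.arange(self.probs.shape[1])
        return self.probs @ counts

    def final(self) -> np.ndarray:
        return self.probs[-1]


@dataclass(frozen=True)
class DeviantDistribution:
    """Joint per-round distributions of (total purple count, deviant color).

    ``joint`` has shape ``(T + 1, N + 1, 2)``; the last axis indexes the
    deviant's color (0 = blue, 1 = purple).  ``survival[t]`` is the
    probability that the deviant is still blue after round t.
    """

    joint: np.ndarray
    survival: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "survival", self.joint[:, :, 0].sum(axis=1))

    @property
    def n_rounds(self) -> int:
        return self.joint.shape[0] - 1

    def final_survival(self) -> float:
        return float(self.survival[-1])


def _round_probs(seq: Sequence[Action | str], params: GameParams) -> List[float]:
    """Per-round shared-pair transmission probability for a homogeneous game."""
    return [pair_transmission_prob(a, a, params) for a in seq]


def evolve_homogeneous(
    shared: Sequence[Action | str] | str, params: GameParams
) -> PurpleDistribution:
    """Exact purple-count chain when every player follows ``shared``.

    Starts from a point mass at ``n_initial_purple`` and applies one
    transition per round with the pair probability implied by that round's
    (universal) action.
    """
    shared = [Action.parse(a) for a in shared]
    if len(shared) != params.n_rounds:
        raise ValueError(
            f"shared strategy length {len(shared)} != n_rounds {params.n_rounds}"
        )
    N = params.n_players
    probs = np.zeros((params.n_rounds + 1, N + 1))
    probs[0, params.n_initial_purple] = 1.0
    state = probs[0]
    for t, p in enumerate(_round_probs(shared, params), start=1):
        state = state @ _transition_matrix(N, p)
        s = state.sum()
        if abs(s - 1.0) > 1e-10:
            raise AssertionError(f"distribution drift at round {t}: sum={s}")
        state = state / s
        probs[t] = state
    return PurpleDistribution(probs=probs)


def evolve_deviant(
    shared: Sequence[Action | str] | str,
    deviant: Sequence[Action | str] | str,
    params: GameParams,
) -> DeviantDistribution:
    """Exact joint chain for one deviant against a shared population strategy.

    Each round the deviant's partner is uniform over the ``N - 1`` others
    (purple with probability ``n_other / (N - 1)``); the deviant's pair uses
    the transmission probability of (deviant action, shared action), while
    the residual ``N - 2`` others are matched uniformly among themselves and
    evolve by the homogeneous law.
    """
    shared = [Action.parse(a) for a in shared]
    deviant = [Action.parse(a) for a in deviant]
    if len(shared) != params.n_rounds or len(deviant) != params.n_rounds:
        raise ValueError("both strategy sequences must have length n_rounds")
    N, n0 = params.n_players, params.n_initial_purple
    # state[c, j]: deviant color c (0 blue / 1 purple), j purple among others
    state = np.zeros((2, N))  # j in 0..N-1
    # exactly n0 of N seeds purple, uniformly: deviant purple w.p. n0/N
    if n0 < N:
        state[0, n0] = 1.0 - n0 / N
    if n0 > 0:
        state[1, n0 - 1] = n0 / N

    joint = np.zeros((params.n_rounds + 1, N + 1, 2))
    _accumulate_joint(joint[0], state)

    for t in range(params.n_rounds):
        p_mix = pair_transmission_prob(deviant[t], shared[t], params)
        p_ss = pair_transmission_prob(shared[t], shared[t], params)
        resid = _transition_matrix(N - 2, p_ss) if N > 2 else None
        new = np.zeros_like(state)
        for c in (0, 1):
            for j in range(N):
                mass = state[c, j]
                if mass == 0.0:
                    continue
                q = j / (N - 1)  # partner purple
                for partner_purple, branch in ((True, mass * q), (False, mass * (1 - q))):
                    if branch == 0.0:
                        continue
                    j_res = j - 1 if partner_purple else j
                    if resid is not None:
                        res_next = resid[j_res]  # pmf over 0..N-2
                    else:
                        res_next = np.array([1.0])
                    if partner_purple:
                        # partner stays purple, contributes +1 to others' count
                        if c == 0:
                            # mixed pair: deviant may switch
                            _scatter(new[1], res_next, 1, branch * p_mix)
                            _scatter(new[0], res_next, 1, branch * (1 - p_mix))
                        else:
                            _scatter(new[1], res_next, 1, branch)
                    else:
                        if c == 1:
                            # mixed pair: partner may switch
                            _scatter(new[1], res_next, 1, branch * p_mix)
                            _scatter(new[1], res_next, 0, branch * (1 - p_mix))
                        else:
                            _scatter(new[c], res_next, 0, branch)
        s = new.sum()
        if abs(s - 1.0) > 1e-10:
            raise AssertionError(f"deviant chain drift at round {t + 1}: sum={s}")
        state = new / s
        _accumulate_joint(joint[t + 1], state)
    return DeviantDistribution(joint=joint)


def _scatter(target: np.ndarray, pmf: np.ndarray, shift: int, weight: float) -> None:
    """Add ``weight * pmf`` into ``target`` at offset ``shift``."""
    if weight == 0.0:
        return
    target[shift : shift + len(pmf)] += weight * pmf


def _accumulate_joint(slot: np.ndarray, state: np.ndarray) -> None:
    """Convert (color, others-count) state into (total count, color) table."""
    N = state.shape[1]
    for c in (0, 1):
        for j in range(N):
            slot[j + c, c] += state[c, j]


def expected_payoff(
    seq: Sequence[Action | str] | str, survival: float, params: GameParams
) -> float:
    """Expected currency payoff of a sequence given a survival probability.

    Points are deterministic given the sequence; only end-of-game color is
    random, so E[payoff] = points / points_per_currency * P(blue at end).
    """
    if not 0.0 <= survival <= 1.0:
        raise ValueError(f"survival must be a probability, got {survival}")
    return strategy_points(seq, params) / params.points_per_currency * survival


def best_response_table(
    scenarios: Dict[str, Sequence[Action | str] | str], params: GameParams
):
    """Deviant payoffs against each shared-strategy scenario.

    For each named shared strategy, computes the expected payoff of a lone
    all-G deviant and a lone all-H deviant (via the exact deviant chain) and
    of a player following the shared strategy itself (via the homogeneous
    chain).  Returns a pandas DataFrame with a boolean ``h_dominates``
    column flagging scenarios where the all-H deviant strictly beats the
    all-G deviant — the social-dilemma signature.
    """
    import pandas as pd

    if not scenarios:
        raise ValueError("scenario list must be non-empty")
    T = params.n_rounds
    all_g = [Action.G] * T
    all_h = [Action.H] * T
    rows = []
    for name, shared in scenarios.items():
        shared = [Action.parse(a) for a in shared]
        homog = evolve_homogeneous(shared, params)
        shared_survival = 1.0 - homog.mean_by_round()[-1] / params.n_players
        dev_g = evolve_deviant(shared, all_g, params).final_survival()
        dev_h = evolve_deviant(shared, all_h, params).final_survival()
        pay_g = expected_payoff(all_g, dev_g, params)
        pay_h = expected_payoff(all_h, dev_h, params)
        rows.append(
            dict(
                scenario=name,
                shared_payoff=expected_payoff(shared, shared_survival, params),
                deviant_g_survival=dev_g,
                deviant_h_survival=dev_h,
                deviant_g_payoff=pay_g,
                deviant_h_payoff=pay_h,
                h_dominates=pay_h > pay_g,
            )
        )
    return pd.DataFrame(rows)
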