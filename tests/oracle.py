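"""Brute-force enumeration oracle for tiny games.

Enumerates every initial outbreak, every per-round perfect matching and
every infection outcome, propagating exact probabilities over color
configurations.  Exponential in N and T — usable only for N <= 6, T <= 3 —
and deliberately independent of the package's Markov-chain solvers.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from typing import Dict, List, Sequence, Tuple

State = frozenset  # set of purple player indices


def all_perfect_matchings(players: Sequence[int]) -> List[Tuple[Tuple[int, int], ...]]:
    """Every perfect matching of ``players`` as tuples of sorted pairs."""
    players = sorted(players)
    if not players:
        return [()]
    first, rest = players[0], players[1:]
    out = []
    for i, partner in enumerate(rest):
        remaining = rest[:i] + rest[i + 1 :]
        for sub in all_perfect_matchings(remaining):
            out.append(((first, partner),) + sub)
    return out


def enumerate_game(
    choices: Sequence[Sequence[str]],  # N rows of 'G'/'H', length T each
    n_initial_purple: int,
    p_gg: Fraction,
    p_gh: Fraction,
    p_hh: Fraction,
) -> List[Dict[State, Fraction]]:
    """Exact distribution over purple-sets after the outbreak and each round."""
    N = len(choices)
    T = len(choices[0])
    probs = {"GG": p_gg, "GH": p_gh, "HG": p_gh, "HH": p_hh}
    seeds = list(itertools.combinations(range(N), n_initial_purple))
    dist: Dict[State, Fraction] = {}
    for s in seeds:
        dist[frozenset(s)] = Fraction(1, len(seeds))
    history = [dict(dist)]
    matchings = all_perfect_matchings(range(N))
    w_match = Fraction(1, len(matchings))
    for t in range(T):
        new: Dict[State, Fraction] = {}
        for state, mass in dist.items():
            for matching in matchings:
                mixed = [
                    (a, b) for a, b in matching if (a in state) != (b in state)
                ]
                base = mass * w_match
                # enumerate which mixed pairs transmit
                for hit in itertools.product([False, True], repeat=len(mixed)):
                    w = base
                    infected = set(state)
                    for (a, b), h in zip(mixed, hit):
                        pa = probs[choices[a][t] + choices[b][t]]
                        if h:
                            w *= pa
                            infected.add(a if b in state else b)
                        else:
                            w *= 1 - pa
                    if w:
                        key = frozenset(infected)
                        new[key] = new.get(key, Fraction(0)) + w
        dist = new
        history.append(dict(dist))
    return history


def purple_count_pmf(dist: Dict[State, Fraction], N: int) -> List[Fraction]:
    out = [Fraction(0)] * (N + 1)
    for state, mass in dist.items():
        out[len(state)] += mass
    return out


def joint_count_color_pmf(
    dist: Dict[State, Fraction], N: int, deviant: int
) -> List[List[Fraction]]:
    """[n][c] table: total purple count n, deviant color c (0 blue, 1 purple)."""
    out = [[Fraction(0), Fraction(0)] for _ in range(N + 1)]
    for state, mass in dist.items():
        out[len(state)][1 if deviant in state else 0] += mass
    return out
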