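"""Monte-Carlo engine for the transmission game.

Two execution paths share one stochastic model:

* :func:`run_game` realizes a single game with an ordinary per-game
  ``numpy`` Generator — the readable reference implementation.
* :func:`simulate_ensemble` advances all replicates in lockstep with
  rep-vectorized array operations (one permutation matrix per round), which
  is what makes 10^4–10^5 replicates cheap.  A single generator seeded from
  ``SeedSequence(seed)`` drives the whole ensemble, so identical seed and
  inputs give a bit-identical summary.

Each round of a game: draw a uniform random perfect matching (shuffle the
players and pair them consecutively — every matching is equally likely);
in each blue-purple pair the blue player switches to purple with the
probability implied by the pair's two current-round actions; blue-blue and
purple-purple pairs never change.  Pairs are disjoint, so all switches in a
round are simultaneous and newly infected players can transmit only from
the next round on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .core import Action, Color, GameParams, payoff
from .strategies import StrategySpec, make_strategy


@dataclass(frozen=True)
class ChoiceMatrix:
    """Exogenous N x T grid of actions (row = player, column = round).

    Stored internally as a boolean array (True = H).  The matrix is fixed
    before simulation: the asynchronous game provides no feedback, so
    choices cannot depend on realized colors.
    """

    is_h: np.ndarray  # (N, T) bool
    player_ids: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.is_h, dtype=bool)
        object.__setattr__(self, "is_h", arr)
        if arr.ndim != 2:
            raise ValueError("choice matrix must be 2-dimensional (players x rounds)")
        if arr.shape[0] % 2 != 0 or arr.shape[0] < 2:
            raise ValueError(
                f"number of players must be even and >= 2, got {arr.shape[0]}"
            )
        if not self.player_ids:
            object.__setattr__(
                self, "player_ids", tuple(f"p{i + 1}" for i in range(arr.shape[0]))
            )
        elif len(self.player_ids) != arr.shape[0]:
            raise ValueError("player_ids length must match number of rows")

    @property
    def n_players(self) -> int:
        return self.is_h.shape[0]

    @property
    def n_rounds(self) -> int:
        return self.is_h.shape[1]

    @classmethod
    def from_rows(
        cls,
        rows: Sequence[Sequence[Action | str] | str],
        player_ids: Sequence[str] = (),
    ) -> "ChoiceMatrix":
        """Build from per-player action sequences (strings or Action lists)."""
        data = [[Action.parse(a) is Action.H for a in row] for row in rows]
        lengths = {len(r) for r in data}
        if len(lengths) > 1:
            raise ValueError(f"ragged rows: lengths {sorted(lengths)}")
        return cls(is_h=np.array(data, dtype=bool), player_ids=tuple(player_ids))

    @classmethod
    def from_specs(
        cls,
        specs: Sequence[StrategySpec],
        rng: Optional[np.random.Generator] = None,
    ) -> "ChoiceMatrix":
        """Realize one strategy spec per player into a matrix."""
        return cls.from_rows([make_strategy(s, rng) for s in specs])

    def row_actions(self, i: int) -> List[Action]:
        return [Action.H if h else Action.G for h in self.is_h[i]]


@dataclass(frozen=True)
class GameResult:
    """One realized game."""

    purple_counts: np.ndarray  # length T+1; [0] = after initial outbreak
    final_colors: Tuple[Color, ...]
    points: np.ndarray  # per player
    payoffs: np.ndarray  # per player, GBP


@dataclass(frozen=True)
class EnsembleSummary:
    """Cross-replicate summary of simulated games."""

    mean_purple_by_round: np.ndarray  # proportions, length T+1
    median_purple_by_round: np.ndarray
    bands: Dict[float, Tuple[np.ndarray, np.ndarray]]  # level -> (lo, hi)
    mean_payoff: float  # GBP per player, purple scored 0
    mean_points_surviving: float  # mean points among end-blue players
    reps: int
    seed: int

    @property
    def final_mean_purple_pct(self) -> float:
        return 100.0 * float(self.mean_purple_by_round[-1])


def draw_matching(n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw a uniform random perfect matching of ``n`` players.

    Returns an ``(n/2, 2)`` array of player indices.  Implemented by pairing
    a uniformly shuffled order consecutively, which is exactly uniform over
    all ``(n-1)!!`` perfect matchings.
    """
    if n < 2 or n % 2 != 0:
        raise ValueError(f"n must be even and >= 2, got {n}")
    perm = rng.permutation(n)
    return perm.reshape(-1, 2)


def _pair_probs(params: GameParams, n_h: np.ndarray) -> np.ndarray:
    """Map per-pair H counts (0, 1 or 2) to transmission probabilities."""
    table = np.array([params.p_gg, params.p_gh, params.p_hh])
    return table[n_h]


def run_game(
    choices: ChoiceMatrix, params: GameParams, rng: np.random.Generator
) -> GameResult:
    """Simulate one complete game."""
    N, T = choices.n_players, choices.n_rounds
    if N != params.n_players or T != params.n_rounds:
        raise ValueError(
            f"choice matrix is {N}x{T} but params specify "
            f"{params.n_players}x{params.n_rounds}"
        )
    purple = np.zeros(N, dtype=bool)
    seeds = rng.choice(N, size=params.n_initial_purple, replace=False)
    purple[seeds] = True
    counts = np.zeros(T + 1, dtype=int)
    counts[0] = params.n_initial_purple
    for t in range(T):
        pairs = draw_matching(N, rng)
        a, b = pairs[:, 0], pairs[:, 1]
        n_h = choices.is_h[a, t].astype(int) + choices.is_h[b, t].astype(int)
        p = _pair_probs(params, n_h)
        mixed = purple[a] ^ purple[b]
        hit = mixed & (rng.random(N // 2) < p)
        # infect the blue member of each transmitting mixed pair
        purple[a[hit & ~purple[a]]] = True
        purple[b[hit & ~purple[b]]] = True
        counts[t + 1] = purple.sum()
    values = np.where(choices.is_h, params.value_h, params.value_g)
    points = values.sum(axis=1).astype(float)
    colors = tuple(Color.PURPLE if q else Color.BLUE for q in purple)
    payoffs = np.array([payoff(pt, c, params) for pt, c in zip(points, colors)])
    return GameResult(
        purple_counts=counts, final_colors=colors, points=points, payoffs=payoffs
    )


def _simulate_counts(
    is_h: np.ndarray,
    params: GameParams,
    reps: int,
    rng: np.random.Generator,
    bootstrap_rows: bool,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized core: all replicates in lockstep.

    Returns ``(counts, purple, row_map)`` where ``counts`` is (reps, T+1)
    purple counts, ``purple`` the final (reps, N) color mask and ``row_map``
    the (reps, N) strategy-row assignment (identity unless bootstrapping).
    """
    N, T = is_h.shape
    rep_idx = np.arange(reps)[:, None]
    if bootstrap_rows:
        row_map = rng.integers(0, N, size=(reps, N))
    else:
        row_map = np.broadcast_to(np.arange(N), (reps, N))

    purple = np.zeros((reps, N), dtype=bool)
    seed_cols = np.argsort(rng.random((reps, N)), axis=1)[:, : params.n_initial_purple]
    purple[rep_idx, seed_cols] = True

    counts = np.zeros((reps, T + 1), dtype=np.int64)
    counts[:, 0] = params.n_initial_purple
    table = np.array([params.p_gg, params.p_gh, params.p_hh])
    for t in range(T):
        perm = np.argsort(rng.random((reps, N)), axis=1)
        a, b = perm[:, 0::2], perm[:, 1::2]
        h_t = is_h[row_map, t]  # (reps, N): this round's action per seat
        n_h = h_t[rep_idx, a].astype(np.int8) + h_t[rep_idx, b].astype(np.int8)
        p = table[n_h]
        pa, pb = purple[rep_idx, a], purple[rep_idx, b]
        hit = (pa ^ pb) & (rng.random((reps, N // 2)) < p)
        purple[rep_idx, a] = pa | (hit & ~pa)
        purple[rep_idx, b] = pb | (hit & ~pb)
        counts[:, t + 1] = purple.sum(axis=1)
    return counts, purple, row_map


def summarize_bands(
    samples: np.ndarray, levels: Sequence[float] = (10, 25, 67, 95)
) -> Tuple[np.ndarray, Dict[float, Tuple[np.ndarray, np.ndarray]]]:
    """Central empirical prediction intervals per round.

    For coverage level ``q`` (percent), the band is the
    ``[(50 - q/2)th, (50 + q/2)th]`` percentile interval of the per-round
    samples; nested levels give nested intervals.  Returns the median and a
    ``{level: (lo, hi)}`` dict.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("cannot summarize empty samples")
    for q in levels:
        if not 0 < q <= 100:
            raise ValueError(f"coverage level must be in (0, 100], got {q}")
    median = np.percentile(samples, 50, axis=0)
    bands = {
        float(q): (
            np.percentile(samples, 50 - q / 2, axis=0),
            np.percentile(samples, 50 + q / 2, axis=0),
        )
        for q in levels
    }
    return median, bands


def simulate_ensemble(
    choices_or_specs: Union[ChoiceMatrix, Sequence[StrategySpec]],
    params: GameParams,
    reps: int,
    seed: int,
    bootstrap_rows: bool = False,
    levels: Sequence[float] = (10, 25, 67, 95),
) -> EnsembleSummary:
    """Simulate ``reps`` independent games and summarize the ensemble.

    Parameters
    ----------
    choices_or_specs
        Either a fixed :class:`ChoiceMatrix` or one :class:`StrategySpec`
        per player (realized once, with randomness drawn from the ensemble
        seed, before any game is run).
    reps
        Number of independent replicate games (>= 1).
    seed
        Master seed; the only source of randomness.
    bootstrap_rows
        If True, each replicate resamples the matrix rows with replacement
        (a nonparametric robustness check on the strategy composition).
    levels
        Coverage percentages for the central prediction bands.
    """
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if isinstance(choices_or_specs, ChoiceMatrix):
        choices = choices_or_specs
    else:
        choices = ChoiceMatrix.from_specs(list(choices_or_specs), rng)
    N, T = choices.n_players, choices.n_rounds
    if N != params.n_players or T != params.n_rounds:
        raise ValueError(
            f"choice matrix is {N}x{T} but params specify "
            f"{params.n_players}x{params.n_rounds}"
        )
    counts, purple, row_map = _simulate_counts(
        choices.is_h, params, reps, rng, bootstrap_rows
    )
    props = counts / N
    median, bands = summarize_bands(props, levels)
    values = np.where(choices.is_h, params.value_h, params.value_g)
    points_per_row = values.sum(axis=1).astype(float)  # (N,)
    seat_points = points_per_row[row_map]  # (reps, N)
    seat_payoffs = np.where(purple, 0.0, seat_points / params.points_per_currency)
    blue = ~purple
    mean_points_surv = (
        float(seat_points[blue].mean()) if blue.any() else float("nan")
    )
    return EnsembleSummary(
        mean_purple_by_round=props.mean(axis=0),
        median_purple_by_round=median,
        bands=bands,
        mean_payoff=float(seat_payoffs.mean()),
        mean_points_surviving=mean_points_surv,
        reps=reps,
        seed=seed,
    )
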