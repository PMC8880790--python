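"""Core game definitions: actions, colors, parameters and payoff arithmetic.

The transmission game is a discrete-round epidemic game played by an even
number of players.  Each round every player picks one of two actions:

* ``G`` — careful: low reward (8 points by default), low transmission risk;
* ``H`` — risky: high reward (40 points), high transmission risk.

Players are uniformly randomly paired each round.  In a mixed (blue-purple)
pair the blue player may switch to purple; the probability depends on the
pair's two current-round actions.  Only players still blue at the end of the
game convert their accumulated points into money.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Iterable, Sequence


class Action(str, enum.Enum):
    """One of the two per-round choices."""

    G = "G"  #: low risk, low reward
    H = "H"  #: high risk, high reward

    @classmethod
    def parse(cls, symbol: object) -> "Action":
        """Coerce a symbol (``'G'``/``'H'`` or an :class:`Action`) to an Action.

        Raises
        ------
        ValueError
            If the symbol is not one of the two admissible actions.
        """
        if isinstance(symbol, Action):
            return symbol
        if isinstance(symbol, str):
            s = symbol.strip().upper()
            if s == "G":
                return cls.G
            if s == "H":
                return cls.H
        raise ValueError(f"invalid action symbol {symbol!r}: expected 'G' or 'H'")


class Color(str, enum.Enum):
    """Infection state of a player.  Transitions are one-way blue → purple."""

    BLUE = "blue"  #: uninfected, payoff-eligible
    PURPLE = "purple"  #: infected, forfeits all payoff


#: Default parameter values for the standard 100-player game.
_DEFAULTS = dict(
    n_players=100,
    n_rounds=25,
    n_initial_purple=8,
    p_gg=0.05,
    p_gh=0.15,
    p_hh=0.25,
    value_g=8,
    value_h=40,
    points_per_currency=200,
)


@dataclass(frozen=True)
class GameParams:
    """The nine numeric parameters defining one game configuration.

    Parameters
    ----------
    n_players
        Population size N; must be even (the matching is a perfect pairing,
        no sit-out rule exists for an odd player).
    n_rounds
        Number of decision rounds T.
    n_initial_purple
        Number of players switched to purple before round 1 (the seed
        outbreak); drawn uniformly without replacement.
    p_gg, p_gh, p_hh
        Per-round transmission probability in a mixed pair when the pair's
        actions are GG, GH/HG and HH respectively.  Must be non-decreasing.
    value_g, value_h
        Points scored per round for the respective action.
    points_per_currency
        Points per unit of currency (GBP) when converting a blue player's
        score to money.
    """

    n_players: int = _DEFAULTS["n_players"]
    n_rounds: int = _DEFAULTS["n_rounds"]
    n_initial_purple: int = _DEFAULTS["n_initial_purple"]
    p_gg: float = _DEFAULTS["p_gg"]
    p_gh: float = _DEFAULTS["p_gh"]
    p_hh: float = _DEFAULTS["p_hh"]
    value_g: float = _DEFAULTS["value_g"]
    value_h: float = _DEFAULTS["value_h"]
    points_per_currency: float = _DEFAULTS["points_per_currency"]

    def __post_init__(self) -> None:
        if self.n_players < 2 or self.n_players % 2 != 0:
            raise ValueError(
                f"n_players must be even and >= 2, got {self.n_players} "
                "(the round pairing is a perfect matching)"
            )
        if not 0 <= self.n_initial_purple <= self.n_players:
            raise ValueError(
                f"n_initial_purple must be in [0, n_players], got {self.n_initial_purple}"
            )
        if self.n_rounds < 0:
            raise ValueError(f"n_rounds must be >= 0, got {self.n_rounds}")
        if not (0.0 <= self.p_gg <= self.p_gh <= self.p_hh <= 1.0):
            raise ValueError(
                "transmission probabilities must satisfy "
                f"0 <= p_gg <= p_gh <= p_hh <= 1, got "
                f"({self.p_gg}, {self.p_gh}, {self.p_hh})"
            )
        if self.value_g > self.value_h:
            raise ValueError(
                f"value_g ({self.value_g}) must not exceed value_h ({self.value_h})"
            )
        if self.points_per_currency <= 0:
            raise ValueError(
                f"points_per_currency must be > 0, got {self.points_per_currency}"
            )

    def with_overrides(self, **kwargs: object) -> "GameParams":
        """Return a copy with the given fields replaced (and re-validated)."""
        return replace(self, **kwargs)  # type: ignore[arg-type]


def pair_transmission_prob(a: Action | str, b: Action | str, params: GameParams) -> float:
    """Transmission probability for a mixed pair with actions ``a`` and ``b``.

    Symmetric in its two arguments.  At the default parameters the rule is
    equivalently ``p_gg + 0.1 * (#H among the two actions)``.
    """
    a = Action.parse(a)
    b = Action.parse(b)
    n_h = (a is Action.H) + (b is Action.H)
    return (params.p_gg, params.p_gh, params.p_hh)[n_h]


def strategy_points(seq: Sequence[Action | str] | str, params: GameParams) -> float:
    """Total points scored by an action sequence over the whole game.

    Points accrue every round regardless of color; color only gates the
    conversion to money (see :func:`payoff`).
    """
    actions = [Action.parse(a) for a in seq]
    if len(actions) != params.n_rounds:
        raise ValueError(
            f"sequence length {len(actions)} != n_rounds {params.n_rounds}"
        )
    return sum(
        params.value_h if a is Action.H else params.value_g for a in actions
    )


def payoff(points: float, final_color: Color, params: GameParams) -> float:
    """Convert a final score into currency (GBP).

    Blue players earn ``points / points_per_currency``; purple players earn 0.
    """
    if points < 0:
        raise ValueError(f"points must be >= 0, got {points}")
    if final_color is Color.PURPLE:
        return 0.0
    return points / params.points_per_currency


def actions_to_bool(seq: Iterable[Action | str]) -> "list[bool]":
    """Map a sequence of actions to booleans (True where the action is H)."""
    return [Action.parse(a) is Action.H for a in seq]
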