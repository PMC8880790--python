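"""Strategy construction and decision-pattern classification.

The game is asynchronous: players never learn their own or their partner's
color during play, so a strategy is just a fixed, round-indexed action
sequence.  Realized sequences fall into four mutually exclusive patterns:

* ``all_safe`` — G in every round;
* ``all_risky`` — H in every round;
* ``risky_safe`` — H for an initial block of rounds, then G for the rest
  (a single risky→safe change; the front-loaded risk pattern);
* ``switch`` — the residual class: everything else, i.e. more than one
  change of action or a safe→risky single change.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import Action


class PatternLabel(str, enum.Enum):
    ALL_SAFE = "all_safe"
    ALL_RISKY = "all_risky"
    RISKY_SAFE = "risky_safe"
    SWITCH = "switch"


@dataclass(frozen=True)
class StrategySpec:
    """Declarative recipe for an action sequence.

    ``kind`` is one of ``all_g``, ``all_h``, ``risky_safe`` (H for the first
    ``h`` rounds, G after) or ``bernoulli`` (i.i.d. H with probability
    ``p_h`` per round).
    """

    kind: str
    length: int
    h: Optional[int] = None
    p_h: Optional[float] = None

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError(f"length must be >= 0, got {self.length}")
        if self.kind == "risky_safe":
            if self.h is None or not 0 <= self.h <= self.length:
                raise ValueError(
                    f"risky_safe requires 0 <= h <= length, got h={self.h}"
                )
        elif self.kind == "bernoulli":
            if self.p_h is None or not 0.0 <= self.p_h <= 1.0:
                raise ValueError(
                    f"bernoulli requires 0 <= p_h <= 1, got p_h={self.p_h}"
                )
        elif self.kind not in ("all_g", "all_h"):
            raise ValueError(f"unknown strategy kind {self.kind!r}")


def make_strategy(
    spec: StrategySpec, rng: Optional[np.random.Generator] = None
) -> list[Action]:
    """Realize a spec as a concrete action sequence.

    ``bernoulli`` specs require an ``rng`` (a seeded ``numpy`` generator)
    so that stochastic strategies are reproducible.
    """
    T = spec.length
    if spec.kind == "all_g":
        return [Action.G] * T
    if spec.kind == "all_h":
        return [Action.H] * T
    if spec.kind == "risky_safe":
        assert spec.h is not None
        return [Action.H] * spec.h + [Action.G] * (T - spec.h)
    # bernoulli
    if rng is None:
        raise ValueError("bernoulli strategies require an rng for reproducibility")
    draws = rng.random(T) < float(spec.p_h)  # type: ignore[arg-type]
    return [Action.H if d else Action.G for d in draws]


def classify_pattern(seq: Sequence[Action | str] | str) -> PatternLabel:
    """Assign a realized sequence to one of the four decision patterns.

    The partition is exhaustive: all-G → ``all_safe``; all-H → ``all_risky``;
    ``H^h G^(T-h)`` with 1 <= h <= T-1 → ``risky_safe``; anything else
    (including a single safe→risky change) → ``switch``.
    """
    actions = [Action.parse(a) for a in seq]
    if not actions:
        raise ValueError("cannot classify an empty sequence")
    is_h = [a is Action.H for a in actions]
    if not any(is_h):
        return PatternLabel.ALL_SAFE
    if all(is_h):
        return PatternLabel.ALL_RISKY
    h = sum(is_h)
    if all(is_h[:h]) and not any(is_h[h:]):
        return PatternLabel.RISKY_SAFE
    return PatternLabel.SWITCH


def parse_strategy_spec(text: str, length: int) -> StrategySpec:
    """Parse the CLI mini-language: ``allG``, ``allH``, ``riskysafe:<h>``,
    ``bernoulli:<p>``.  (``file:<path>`` is handled by the CLI itself.)
    """
    t = text.strip()
    low = t.lower()
    if low == "allg":
        return StrategySpec("all_g", length)
    if low == "allh":
        return StrategySpec("all_h", length)
    if low.startswith("riskysafe:"):
        return StrategySpec("risky_safe", length, h=int(t.split(":", 1)[1]))
    if low.startswith("bernoulli:"):
        return StrategySpec("bernoulli", length, p_h=float(t.split(":", 1)[1]))
    raise ValueError(
        f"cannot parse strategy spec {text!r}: expected allG, allH, "
        "riskysafe:<h> or bernoulli:<p>"
    )
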