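"""Egg-production equations: the latent daily mature-egg stock.

A synovigenic parasitoid carries a stock of mature eggs that is drawn
down by oviposition, replenished by maturation, and possibly reduced by
resorption.  Eight nested equations describe the stock e(t):

========  ====================================================================
equation  behaviour
========  ====================================================================
1         unlimited eggs (the stock never constrains oviposition)
2         fixed initial stock e0, never replenished (strictly pro-ovigenic)
3         production h0 * g**(t-1) added each day; no resorption, no cap
4         as 3 plus overnight resorption of a proportion r of unlaid eggs
5         as 4 but resorption acts only on the excess over a threshold u
6         as 4 plus a storage capacity C that caps the stock
7         as 5 plus the storage capacity C
8         as 3 plus the storage capacity C (production and cap, no
          resorption)
========  ====================================================================

Within a day the order of events is: the female lays eggs, unlaid eggs
are (partially) resorbed overnight, the next day's production is added,
and finally the capacity cap is applied.  Production on day t therefore
becomes available on day t+1; day-1 oviposition draws only on the
emergence stock e0.

Parameters (all non-negative):

e0 : mature eggs at emergence (eggs)
h0 : egg production on the first day of life (eggs/day)
g  : daily multiplicative change of the production rate (day^-1);
     g < 1 is senescing production, g > 1 accelerating
r  : proportion of (excess) unlaid eggs resorbed overnight, in [0, 1]
u  : resorption threshold (eggs); the stock is never resorbed below u
cap: egg storage capacity C (eggs); ``inf`` disables the cap

The stock is modelled as a continuous quantity; only the observed
parasitism counts are integers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EggParams",
    "EggTrajectory",
    "EGG_EQUATIONS",
    "EGG_PARAM_NAMES",
    "UNLIMITED",
    "initial_stock",
    "daily_production",
    "resorb",
    "update_stock",
]

#: sentinel stock for the unlimited-egg equation
UNLIMITED: float = math.inf

EGG_EQUATIONS: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8)

#: free parameters of each equation, in canonical order
EGG_PARAM_NAMES: dict[int, tuple[str, ...]] = {
    1: (),
    2: ("e0",),
    3: ("e0", "h0", "g"),
    4: ("e0", "h0", "g", "r"),
    5: ("e0", "h0", "g", "r", "u"),
    6: ("e0", "h0", "g", "r", "cap"),
    7: ("e0", "h0", "g", "r", "u", "cap"),
    8: ("e0", "h0", "g", "cap"),
}

_RESORB_ALL = frozenset({4, 6})
_RESORB_THRESHOLD = frozenset({5, 7})
_CAPPED = frozenset({6, 7, 8})


@dataclass(frozen=True)
class EggParams:
    """Parameter set for an egg-production equation (neutral defaults)."""

    e0: float = 0.0
    h0: float = 0.0
    g: float = 1.0
    r: float = 0.0
    u: float = 0.0
    cap: float = UNLIMITED

    def __post_init__(self) -> None:
        if min(self.e0, self.h0, self.g, self.u, self.cap) < 0:
            raise ValueError("egg parameters must be non-negative")
        if not 0.0 <= self.r <= 1.0:
            raise ValueError("resorption proportion r must lie in [0, 1]")


@dataclass
class EggTrajectory:
    """Daily record of the latent egg budget of one female.

    ``stock[t-1]`` is the mature-egg stock at the start of day t (after
    any cap), ``laid``/``resorbed``/``produced`` the amounts moved during
    day t and the following night.
    """

    stock: list[float] = field(default_factory=list)
    laid: list[float] = field(default_factory=list)
    resorbed: list[float] = field(default_factory=list)
    produced: list[float] = field(default_factory=list)

    def as_arrays(self) -> dict[str, np.ndarray]:
        return {
            "stock": np.asarray(self.stock, dtype=float),
            "laid": np.asarray(self.laid, dtype=float),
            "resorbed": np.asarray(self.resorbed, dtype=float),
            "produced": np.asarray(self.produced, dtype=float),
        }


def _check_eq(eq: int) -> int:
    eq = int(eq)
    if eq not in EGG_EQUATIONS:
        raise ValueError(f"egg equation must be one of {EGG_EQUATIONS}, got {eq}")
    return eq


def initial_stock(eq: int, p: EggParams) -> float:
    """Mature-egg stock at emergence (start of day 1)."""
    eq = _check_eq(eq)
    if eq == 1:
        return UNLIMITED
    if eq in _CAPPED:
        return min(p.e0, p.cap)
    return p.e0


def daily_production(eq: int, p: EggParams, day: int) -> float:
    """Eggs matured on 1-based day ``day``: h0 * g**(day - 1).

    Equations 1 and 2 have no maturation term and return 0.
    """
    eq = _check_eq(eq)
    if day < 1:
        raise ValueError("day is 1-based")
    if eq in (1, 2):
        return 0.0
    return p.h0 * p.g ** (day - 1)


def resorb(eq: int, p: EggParams, remaining: float) -> float:
    """Stock left after overnight resorption of unlaid eggs."""
    eq = _check_eq(eq)
    if remaining < 0:
        raise ValueError("remaining stock must be non-negative")
    if eq in _RESORB_ALL:
        return (1.0 - p.r) * remaining
    if eq in _RESORB_THRESHOLD:
        return remaining - p.r * max(0.0, remaining - p.u)
    return remaining


def update_stock(eq: int, p: EggParams, remaining: float, day: int) -> float:
    """Stock at the start of day ``day + 1`` given ``remaining`` unlaid
    eggs at the end of day ``day``.

    Applies, in order: overnight resorption, addition of day ``day + 1``'s
    production, and the storage-capacity cap.
    """
    eq = _check_eq(eq)
    if remaining < 0:
        raise ValueError("remaining stock must be non-negative")
    if eq == 1:
        return UNLIMITED
    if eq == 2:
        return remaining
    nxt = resorb(eq, p, remaining) + daily_production(eq, p, day + 1)
    if eq in _CAPPED:
        nxt = min(nxt, p.cap)
    return nxt
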