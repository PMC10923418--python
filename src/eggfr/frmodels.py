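"""Daily functional-response equations for parasitoids.

A functional response f(n) gives the expected number of hosts a female
attacks in one day when ``n`` hosts are offered.  Six variants are
supported, labelled A-F:

========  ====================================================================
equation  form
========  ====================================================================
A         type I: f = a*n, capped at n (linear up to the supply)
B         type II: Holling disc equation with constant attack rate a
C         type III: attack rate rises linearly with host number, b + a*n
D         as C, but the attack rate rises with the female's cumulative
          lifetime host exposure instead of the current density
E         type III: attack rate proportional to a power of host number,
          a * n**(s-1), so the numerator of the disc equation is a*n**s
F         as E, with cumulative experience added to the density inside
          the power
========  ====================================================================

All type II/III variants share the Holling disc denominator
``1 + lambda*H*n`` where ``lambda`` is the (possibly density- or
experience-dependent) attack rate and ``H`` the handling time in days,
so for H > 0 the response saturates at 1/H hosts per day.  The exposure
window is one day throughout (daily host replacement design), so no
separate exposure-time parameter appears.

Parameters
----------
b : attack rate at emergence at zero host density (day^-1); equations C, D
a : attack-rate change (day^-1 per host for the linear forms, scale
    constant for the power forms); all equations
H : handling time (days); equations B-F
s : density exponent, s = 1 + q >= 1 (dimensionless); equations E, F

Experience (equations D, F) is the cumulative number of hosts *offered*
to the female on all days strictly before the current one; a newly
emerged female has zero experience.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

__all__ = ["FREquation", "FRParams", "attack_rate", "fr_expected", "FR_PARAM_NAMES"]


class FREquation(str, Enum):
    """Identifier of one of the six functional-response equations."""

    A = "A"
    B = "B"
    C = "C"
    D = "D"
    E = "E"
    F = "F"

    @property
    def uses_experience(self) -> bool:
        return self in (FREquation.D, FREquation.F)

    @property
    def param_names(self) -> tuple[str, ...]:
        return FR_PARAM_NAMES[self]


#: free parameters of each equation, in canonical order
FR_PARAM_NAMES: dict[FREquation, tuple[str, ...]] = {
    FREquation.A: ("a",),
    FREquation.B: ("a", "H"),
    FREquation.C: ("b", "a", "H"),
    FREquation.D: ("b", "a", "H"),
    FREquation.E: ("a", "s", "H"),
    FREquation.F: ("a", "s", "H"),
}


@dataclass(frozen=True)
class FRParams:
    """Parameter set for a functional-response equation.

    Unused fields are ignored by equations that do not declare them; the
    defaults are neutral (b = 0, H = 0, s = 1).
    """

    a: float = 0.0
    b: float = 0.0
    H: float = 0.0
    s: float = 1.0

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0 or self.H < 0:
            raise ValueError("a, b and H must be non-negative")
        if self.s < 1:
            raise ValueError("density exponent s must be >= 1")


def attack_rate(
    eq: FREquation, params: FRParams, n: float, cum_hosts: float = 0.0
) -> float:
    """Instantaneous attack rate lambda (day^-1) for ``n`` hosts offered.

    ``cum_hosts`` is the female's cumulative host exposure on prior days;
    it only enters equations D and F.
    """
    eq = FREquation(eq)
    if n < 0:
        raise ValueError("host number n must be non-negative")
    if cum_hosts < 0:
        raise ValueError("cumulative host exposure must be non-negative")
    if eq in (FREquation.A, FREquation.B):
        return params.a
    if eq is FREquation.C:
        return params.b + params.a * n
    if eq is FREquation.D:
        return params.b + params.a * cum_hosts
    if eq is FREquation.E:
        return params.a * n ** (params.s - 1.0) if n > 0 else 0.0
    # F: experience shifts the density seen by the power-law kernel
    x = cum_hosts + n
    return params.a * x ** (params.s - 1.0) if x > 0 else 0.0


def fr_expected(
    eq: FREquation, params: FRParams, n: float, cum_hosts: float = 0.0
) -> float:
    """Expected hosts attacked in one day, clamped to [0, n].

    Equation A is linear (type I) and saturates only through the clamp at
    the number of hosts on offer; B-F follow the disc equation
    ``lambda*n / (1 + lambda*H*n)``.
    """
    eq = FREquation(eq)
    if n < 0:
        raise ValueError("host number n must be non-negative")
    if n == 0:
        return 0.0
    if eq is FREquation.A:
        f = params.a * n
    else:
        lam = attack_rate(eq, params, n, cum_hosts)
        f = lam * n / (1.0 + lam * params.H * n)
    return min(max(f, 0.0), float(n))
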