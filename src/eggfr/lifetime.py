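"""Lifetime parasitism model: behaviour coupled to physiology by the
law of the minimum.

Each day of a female's life she is offered ``n`` fresh hosts.  The
number of eggs she is expected to lay is

    p(n, t) = min( f(n), e(t), n )

where f(n) is a functional-response equation (module
:mod:`eggfr.frmodels`) describing what her searching behaviour allows,
and e(t) the latent mature-egg stock (module :mod:`eggfr.eggmodels`)
describing what her physiology allows.  A female can never lay more
eggs than she possesses, nor parasitize more hosts than are on offer.

Observed daily parasitism counts k_t (emerged wasps) are modelled as
binomial, k_t ~ Binomial(n_t, p_t / n_t): each offered host is
independently parasitized with the per-host probability implied by the
expected count.  Development failure and superparasitism are absorbed
into this observation noise.  The egg stock is propagated through the
days of a female's life with the *observed* counts as the eggs spent,
which makes e(t) a deterministic function of the data and the
parameters and keeps the likelihood tractable (no latent-state
integration is required).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .eggmodels import (
    EGG_EQUATIONS,
    EGG_PARAM_NAMES,
    EggParams,
    EggTrajectory,
    daily_production,
    initial_stock,
    update_stock,
)
from .frmodels import FR_PARAM_NAMES, FREquation, FRParams, fr_expected

__all__ = [
    "ModelSpec",
    "MODEL_GRID",
    "ExperimentDataset",
    "DATASET_COLUMNS",
    "expected_parasitized",
    "female_loglik",
    "dataset_loglik",
    "simulate_female",
    "expected_trajectory",
]

logger = logging.getLogger(__name__)

#: required CSV / DataFrame schema for experiment data
DATASET_COLUMNS = ("female_id", "day", "n_offered", "n_parasitized")


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: a functional-response equation paired with an
    egg-production equation, e.g. ``C5``."""

    fr: FREquation
    egg: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "fr", FREquation(self.fr))
        if int(self.egg) not in EGG_EQUATIONS:
            raise ValueError(f"unknown egg equation {self.egg!r}")
        object.__setattr__(self, "egg", int(self.egg))

    @property
    def name(self) -> str:
        return f"{self.fr.value}{self.egg}"

    @classmethod
    def from_name(cls, name: str) -> "ModelSpec":
        name = name.strip()
        if len(name) != 2 or name[0] not in "ABCDEF" or name[1] not in "12345678":
            raise ValueError(
                f"model name {name!r} is not in the 48-model grid "
                "(letter A-F followed by digit 1-8)"
            )
        return cls(FREquation(name[0]), int(name[1]))

    @property
    def param_names(self) -> tuple[str, ...]:
        """Free parameters of this model, functional response first."""
        return FR_PARAM_NAMES[self.fr] + EGG_PARAM_NAMES[self.egg]


#: the full candidate family: 6 functional responses x 8 egg equations
MODEL_GRID: tuple[ModelSpec, ...] = tuple(
    ModelSpec(fr, egg)
    for fr, egg in itertools.product(FREquation, EGG_EQUATIONS)
)


class ExperimentDataset:
    """Per-female daily offered/parasitized counts.

    Wraps a DataFrame with columns ``female_id, day, n_offered,
    n_parasitized``; days within a female must be consecutive from 1 and
    counts must satisfy 0 <= n_parasitized <= n_offered.
    """

    def __init__(self, df: pd.DataFrame, metadata: dict | None = None):
        missing = [c for c in DATASET_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"dataset is missing required columns {missing}")
        extra = [c for c in df.columns if c not in DATASET_COLUMNS]
        if extra:
            logger.warning("ignoring extra dataset columns %s", extra)
        df = df.loc[:, list(DATASET_COLUMNS)].copy()
        df["day"] = df["day"].astype(int)
        df["n_offered"] = df["n_offered"].astype(int)
        df["n_parasitized"] = df["n_parasitized"].astype(int)
        if len(df) == 0:
            raise ValueError("dataset contains no observations")
        if (df["n_offered"] < 0).any() or (df["n_parasitized"] < 0).any():
            raise ValueError("counts must be non-negative")
        if (df["n_parasitized"] > df["n_offered"]).any():
            raise ValueError("n_parasitized must not exceed n_offered")
        df = df.sort_values(["female_id", "day"], kind="stable").reset_index(drop=True)
        for fid, grp in df.groupby("female_id", sort=False):
            days = grp["day"].to_numpy()
            if days[0] != 1 or not np.array_equal(days, np.arange(1, len(days) + 1)):
                raise ValueError(
                    f"female {fid!r}: days must be consecutive starting at 1"
                )
        self.df = df
        self.metadata = dict(metadata or {})

    @property
    def n_obs(self) -> int:
        return len(self.df)

    @property
    def female_ids(self) -> list:
        return list(self.df["female_id"].unique())

    def females(self):
        """Yield ``(female_id, n_offered array, n_parasitized array)``."""
        for fid, grp in self.df.groupby("female_id", sort=False):
            yield fid, grp["n_offered"].to_numpy(), grp["n_parasitized"].to_numpy()

    def __len__(self) -> int:
        return self.n_obs

    def __eq__(self, other) -> bool:
        return isinstance(other, ExperimentDataset) and self.df.equals(other.df)


def expected_parasitized(
    model: ModelSpec,
    frp: FRParams,
    eggp: EggParams,
    n: float,
    day: int,
    stock: float,
    cum_hosts: float = 0.0,
) -> float:
    """Expected eggs laid on one day: min(f(n), stock, n)."""
    if stock < 0:
        raise ValueError("egg stock must be non-negative")
    f = fr_expected(model.fr, frp, n, cum_hosts)
    return min(f, stock, float(n))


_EPS = 1e-12


def _obs_loglik(n: int, k: int, p: float) -> float:
    """Binomial log-pmf of k successes in n trials with mean count p."""
    if n == 0:
        return 0.0
    prob = p / n
    if prob <= 0.0:
        return 0.0 if k == 0 else -math.inf
    if prob >= 1.0:
        if k == n:
            return 0.0
        prob = 1.0 - _EPS
    return (
        math.lgamma(n + 1)
        - math.lgamma(k + 1)
        - math.lgamma(n - k + 1)
        + k * math.log(prob)
        + (n - k) * math.log1p(-prob)
    )


def female_loglik(
    model: ModelSpec,
    frp: FRParams,
    eggp: EggParams,
    n_offered: np.ndarray,
    n_parasitized: np.ndarray,
) -> float:
    """Log-likelihood of one female's observation sequence.

    The latent stock is conditioned on the observed counts: eggs spent on
    day t are ``min(k_t, stock_t)`` and the stock is stepped forward with
    :func:`eggfr.eggmodels.update_stock`.
    """
    n_offered = np.asarray(n_offered)
    n_parasitized = np.asarray(n_parasitized)
    if np.any(n_parasitized > n_offered) or np.any(n_parasitized < 0):
        raise ValueError("invalid observations: need 0 <= k <= n")
    stock = initial_stock(model.egg, eggp)
    cum = 0.0
    ll = 0.0
    for day, (n, k) in enumerate(zip(n_offered, n_parasitized), start=1):
        n = int(n)
        k = int(k)
        p = expected_parasitized(model, frp, eggp, n, day, stock, cum)
        ll += _obs_loglik(n, k, p)
        if not math.isfinite(ll):
            return -math.inf
        laid = min(float(k), stock)
        stock = update_stock(model.egg, eggp, stock - laid, day)
        cum += n
    return ll


def dataset_loglik(
    model: ModelSpec, frp: FRParams, eggp: EggParams, dataset: ExperimentDataset
) -> float:
    """Log-likelihood of a full dataset (females independent)."""
    if dataset.n_obs == 0:
        raise ValueError("empty dataset")
    return sum(
        female_loglik(model, frp, eggp, n, k) for _, n, k in dataset.females()
    )


def simulate_female(
    model: ModelSpec,
    frp: FRParams,
    eggp: EggParams,
    offered_schedule,
    rng: np.random.Generator | int,
) -> tuple[np.ndarray, EggTrajectory]:
    """Simulate one female's daily parasitism counts.

    Each day draws k_t ~ Binomial(n_t, p_t / n_t) and propagates the
    latent stock with the drawn count, mirroring the likelihood.
    Returns the counts and the realized egg trajectory.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    offered = np.asarray(offered_schedule, dtype=int)
    if np.any(offered < 0):
        raise ValueError("offered host numbers must be non-negative")
    stock = initial_stock(model.egg, eggp)
    cum = 0.0
    traj = EggTrajectory()
    ks = np.zeros(len(offered), dtype=int)
    for day, n in enumerate(offered, start=1):
        n = int(n)
        p = expected_parasitized(model, frp, eggp, n, day, stock, cum)
        k = int(rng.binomial(n, p / n)) if n > 0 else 0
        ks[day - 1] = k
        laid = min(float(k), stock)
        remaining = stock - laid
        nxt = update_stock(model.egg, eggp, remaining, day)
        traj.stock.append(stock)
        traj.laid.append(laid)
        prod = daily_production(model.egg, eggp, day + 1)
        traj.produced.append(prod)
        # resorbed = what left the remaining pool beyond production/cap
        traj.resorbed.append(max(0.0, remaining + prod - nxt) if math.isfinite(nxt) else 0.0)
        stock = nxt
        cum += n
    return ks, traj


def expected_trajectory(
    model: ModelSpec,
    frp: FRParams,
    eggp: EggParams,
    offered_schedule,
) -> tuple[np.ndarray, EggTrajectory]:
    """Deterministic expected path: the stock is propagated with the
    *expected* daily laying instead of observed counts.

    This is the noise-free mean trajectory used for expected-parasitism
    curves and model-averaged predictions.
    """
    offered = np.asarray(offered_schedule, dtype=float)
    stock = initial_stock(model.egg, eggp)
    cum = 0.0
    traj = EggTrajectory()
    ps = np.zeros(len(offered))
    for day, n in enumerate(offered, start=1):
        p = expected_parasitized(model, frp, eggp, n, day, stock, cum)
        ps[day - 1] = p
        remaining = stock - p
        nxt = update_stock(model.egg, eggp, remaining, day)
        traj.stock.append(stock)
        traj.laid.append(p)
        prod = daily_production(model.egg, eggp, day + 1)
        traj.produced.append(prod)
        traj.resorbed.append(max(0.0, remaining + prod - nxt) if math.isfinite(nxt) else 0.0)
        stock = nxt
        cum += n
    return ps, traj
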