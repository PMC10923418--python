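"""Shared property checks used by both the unit suite and the
end-to-end acceptance suite.

Each function raises ``AssertionError`` on failure and returns None.
All randomness is driven by an explicit seed so reruns are identical.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from eggfr import (
    EggParams,
    FREquation,
    FRParams,
    ModelSpec,
    dataset_loglik,
    fr_expected,
    initial_stock,
    mh_sample,
    simulate_female,
    update_stock,
)
from eggfr.eggmodels import UNLIMITED
from eggfr.frmodels import FR_PARAM_NAMES
from eggfr.lifetime import ExperimentDataset
import pandas as pd

CACHAMAI_C = FRParams(b=0.073, a=0.003, H=0.005)
CACHAMAI_E = FRParams(a=0.018, s=1.676, H=0.005)
LAPACHOSUS_D = FRParams(b=0.109, a=0.001, H=0.004)


def _random_frparams(rng) -> FRParams:
    return FRParams(
        a=rng.uniform(0.0, 0.5),
        b=rng.uniform(0.0, 0.5),
        H=rng.uniform(0.0, 0.1),
        s=rng.uniform(1.0, 3.0),
    )


def check_fr_monotonicity(n_draws: int = 200, seed: int = 0) -> None:
    """f(n) is nondecreasing in n on the integer grid [0, 500] for random
    valid parameter draws, for every equation."""
    rng = np.random.default_rng(seed)
    grid = np.arange(0, 501)
    for _ in range(n_draws):
        p = _random_frparams(rng)
        cum = rng.uniform(0.0, 500.0)
        for eq in FREquation:
            f = np.array([fr_expected(eq, p, int(n), cum) for n in grid])
            assert np.all(np.diff(f) >= -1e-9), f"non-monotone f(n) for {eq}"
            assert np.all(f >= 0) and np.all(f <= grid), f"clamp violated for {eq}"


def check_asymptote() -> None:
    """For H > 0 the disc equation saturates at 1/H: f(1e6) * H ~ 1."""
    cases = [
        (FREquation.C, CACHAMAI_C, 0.0),
        (FREquation.E, CACHAMAI_E, 0.0),
        (FREquation.D, LAPACHOSUS_D, 300.0),
        (FREquation.F, FRParams(a=0.018, s=1.676, H=0.004), 300.0),
        (FREquation.B, FRParams(a=0.2, H=0.005), 0.0),
    ]
    for eq, p, cum in cases:
        f = fr_expected(eq, p, 10**6, cum)
        assert abs(f * p.H - 1.0) < 0.01, f"asymptote violated for {eq}"


def check_type3_signature() -> None:
    """Proportion attacked f(n)/n rises on an initial density interval for
    the type III equations and falls strictly for type II.

    For the experience variants the cumulative exposure scales with the
    density (a female kept at density n for two prior days has seen 2n
    hosts), which is how the design realizes their density dependence.
    """
    grid = np.arange(1, 30)

    def prop(eq, p, cum_factor=0.0):
        return np.array(
            [fr_expected(eq, p, int(n), cum_factor * n) / n for n in grid]
        )

    for eq, p, cf in [
        (FREquation.C, CACHAMAI_C, 0.0),
        (FREquation.E, CACHAMAI_E, 0.0),
        (FREquation.D, LAPACHOSUS_D, 2.0),
        (FREquation.F, FRParams(a=0.018, s=1.676, H=0.004), 2.0),
    ]:
        q = prop(eq, p, cf)
        assert q[1] > q[0], f"no rising initial interval for {eq}"
    qb = prop(FREquation.B, FRParams(a=0.2, H=0.005))
    assert np.all(np.diff(qb) < 0), "type II proportion must fall strictly"


def check_c_reduces_to_b() -> None:
    """Equation C with a = 0 is equation B with attack rate b, exactly."""
    pc = FRParams(b=0.21, a=0.0, H=0.013)
    pb = FRParams(a=0.21, H=0.013)
    for n in range(0, 200, 7):
        assert fr_expected(FREquation.C, pc, n) == fr_expected(FREquation.B, pb, n)


def _trajectory(eq: int, p: EggParams, lay_fracs) -> list[float]:
    """Stock sequence under a fixed fractional laying schedule."""
    stock = initial_stock(eq, p)
    out = [stock]
    for day, frac in enumerate(lay_fracs, start=1):
        laid = 0.0 if math.isinf(stock) else frac * stock
        stock = update_stock(eq, p, stock - laid, day)
        out.append(stock)
    return out


def check_egg_nesting(n_draws: int = 100, seed: int = 1) -> None:
    """Nesting equivalences of the egg-equation ladder on random
    parameters and 10-day trajectories, to 1e-9 eggs."""
    rng = np.random.default_rng(seed)
    big = 1e9
    for _ in range(n_draws):
        e0 = rng.uniform(0, 80)
        h0 = rng.uniform(0, 20)
        g = rng.uniform(0.5, 1.5)
        r = rng.uniform(0, 1)
        u = rng.uniform(0, 40)
        fracs = rng.uniform(0, 1, size=10)
        pairs = [
            (5, EggParams(e0=e0, h0=h0, g=g, r=r, u=0.0), 4, EggParams(e0=e0, h0=h0, g=g, r=r)),
            (4, EggParams(e0=e0, h0=h0, g=g, r=0.0), 3, EggParams(e0=e0, h0=h0, g=g)),
            (7, EggParams(e0=e0, h0=h0, g=g, r=r, u=u, cap=big), 5, EggParams(e0=e0, h0=h0, g=g, r=r, u=u)),
            (7, EggParams(e0=e0, h0=h0, g=g, r=r, u=0.0, cap=big), 4, EggParams(e0=e0, h0=h0, g=g, r=r)),
            (8, EggParams(e0=e0, h0=h0, g=g, cap=big), 3, EggParams(e0=e0, h0=h0, g=g)),
        ]
        for eq1, p1, eq2, p2 in pairs:
            t1 = np.array(_trajectory(eq1, p1, fracs))
            t2 = np.array(_trajectory(eq2, p2, fracs))
            assert np.max(np.abs(t1 - t2)) < 1e-9, f"eq {eq1} does not nest eq {eq2}"


def _independent_loglik(model: ModelSpec, frp: FRParams, eggp: EggParams,
                        females) -> float:
    """Brute-force oracle: per-observation binomial pmfs from first
    principles (math.comb), with its own stock recursion."""
    total = 0.0
    for n_arr, k_arr in females:
        if model.egg == 1:
            stock = math.inf
        elif model.egg in (6, 7, 8):
            stock = min(eggp.e0, eggp.cap)
        else:
            stock = eggp.e0
        cum = 0.0
        for day, (n, k) in enumerate(zip(n_arr, k_arr), start=1):
            if n > 0:
                if model.fr is FREquation.A:
                    f = frp.a * n
                else:
                    lam = {
                        FREquation.B: frp.a,
                        FREquation.C: frp.b + frp.a * n,
                        FREquation.D: frp.b + frp.a * cum,
                        FREquation.E: frp.a * n ** (frp.s - 1),
                        FREquation.F: frp.a * (cum + n) ** (frp.s - 1),
                    }[model.fr]
                    f = lam * n / (1 + lam * frp.H * n)
                f = min(max(f, 0.0), n)
                prob = min(f, stock, n) / n
                pmf = (
                    math.comb(n, k) * prob**k * (1 - prob) ** (n - k)
                    if 0 < prob < 1
                    else (1.0 if (prob <= 0 and k == 0) or (prob >= 1 and k == n) else 0.0)
                )
                if pmf == 0.0:
                    return -math.inf
                total += math.log(pmf)
            rem = stock - min(k, stock)
            if model.egg == 2:
                stock = rem
            elif model.egg != 1:
                if model.egg in (4, 6):
                    rem *= 1 - eggp.r
                elif model.egg in (5, 7):
                    rem -= eggp.r * max(0.0, rem - eggp.u)
                stock = rem + eggp.h0 * eggp.g**day
                if model.egg in (6, 7, 8):
                    stock = min(stock, eggp.cap)
            cum += n
    return total


def check_loglik_against_enumeration(seed: int = 2) -> None:
    """dataset_loglik equals a first-principles binomial oracle on random
    small datasets (all offered counts <= 10)."""
    rng = np.random.default_rng(seed)
    for name in ("A1", "B3", "C5", "D4", "E7", "F8", "C2"):
        model = ModelSpec.from_name(name)
        frp = FRParams(a=rng.uniform(0.05, 0.4), b=rng.uniform(0, 0.3),
                       H=rng.uniform(0, 0.05), s=rng.uniform(1, 2.5))
        eggp = EggParams(e0=rng.uniform(2, 30), h0=rng.uniform(0, 6),
                         g=rng.uniform(0.7, 1.3), r=rng.uniform(0, 1),
                         u=rng.uniform(0, 10), cap=rng.uniform(20, 60))
        rows, females = [], []
        for fid in range(4):
            days = int(rng.integers(2, 6))
            n_arr = rng.integers(1, 11, size=days)
            k_arr, _ = simulate_female(model, frp, eggp, n_arr, rng)
            females.append((n_arr, k_arr))
            for d in range(days):
                rows.append({"female_id": f"F{fid}", "day": d + 1,
                             "n_offered": int(n_arr[d]), "n_parasitized": int(k_arr[d])})
        data = ExperimentDataset(pd.DataFrame(rows))
        got = dataset_loglik(model, frp, eggp, data)
        want = _independent_loglik(model, frp, eggp, females)
        assert got == want or abs(got - want) < 1e-8 * max(1, abs(want)), name


def check_conjugate_toy(seed: int = 3) -> tuple[float, float]:
    """A constant-probability binomial model has a Beta(8, 14) posterior
    for data (n=20, k=7) under a uniform prior; the sampler must agree.

    Realized with equation A (f = a*n) and unlimited eggs, so the
    per-host probability is the single parameter a.  Returns (posterior
    mean error, quantile error) for reporting.
    """
    from eggfr.inference import Uniform

    model = ModelSpec.from_name("A1")
    data = ExperimentDataset(
        pd.DataFrame([
            {"female_id": "F1", "day": 1, "n_offered": 20, "n_parasitized": 7}
        ])
    )
    fit = mh_sample(model, data, priors={"a": Uniform(0.0, 1.0)},
                    iterations=24_000, burnin=4_000, seed=seed)
    draws = fit.chain[:, 0]
    post = stats.beta(8, 14)
    # Monte-Carlo SE of the chain mean via batch means
    batches = draws[: 20 * (len(draws) // 20)].reshape(20, -1).mean(axis=1)
    mcse = batches.std(ddof=1) / math.sqrt(len(batches))
    mean_err = abs(draws.mean() - post.mean())
    assert mean_err < 3 * mcse + 1e-3, (mean_err, mcse)
    qerr = 0.0
    for q in (0.025, 0.5, 0.975):
        qerr = max(qerr, abs(np.quantile(draws, q) - post.ppf(q)))
    assert qerr < 0.03, qerr
    return mean_err, qerr


def check_path_invariants(n_paths: int = 1000, seed: int = 4) -> None:
    """Simulated paths respect all stock and count constraints."""
    rng = np.random.default_rng(seed)
    from eggfr.lifetime import MODEL_GRID

    for i in range(n_paths):
        model = MODEL_GRID[int(rng.integers(len(MODEL_GRID)))]
        frp = _random_frparams(rng)
        eggp = EggParams(e0=rng.uniform(0, 60), h0=rng.uniform(0, 15),
                         g=rng.uniform(0.5, 1.5), r=rng.uniform(0, 1),
                         u=rng.uniform(0, 30), cap=rng.uniform(10, 80))
        schedule = rng.integers(0, 120, size=int(rng.integers(1, 8)))
        ks, traj = simulate_female(model, frp, eggp, schedule, rng)
        assert np.all(ks >= 0) and np.all(ks <= schedule)
        stock = np.array(traj.stock)
        laid = np.array(traj.laid)
        assert np.all(stock >= 0) and np.all(laid >= -1e-12)
        assert np.all(laid <= stock + 1e-9)
        if model.egg in (6, 7, 8):
            assert np.all(stock <= eggp.cap + 1e-9)
        if model.egg == 1:
            assert np.all(np.isinf(stock))
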