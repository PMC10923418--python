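"""Fast log-likelihood kernel used by the MCMC sampler.

The public likelihood functions in :mod:`eggfr.lifetime` are the
readable reference implementation.  Sampling evaluates the likelihood
hundreds of thousands of times, so the same recursion is also written
here as a flat numeric kernel over packed arrays and compiled with
numba when available; a pure-Python twin with identical semantics is
used otherwise.  The two paths are asserted equal in the test suite.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import gammaln

from .frmodels import FREquation
from .lifetime import ExperimentDataset, ModelSpec

__all__ = ["pack_dataset", "loglik_packed", "NUMBA_AVAILABLE"]

_EPS = 1e-12

_FR_CODE = {e: i for i, e in enumerate(FREquation)}  # A=0 .. F=5


def pack_dataset(dataset: ExperimentDataset):
    """Flatten a dataset into contiguous arrays for the kernel.

    Returns ``(n, k, logc, starts, lens)`` where ``logc`` holds the
    binomial coefficients log C(n, k) (parameter-independent) and
    ``starts``/``lens`` delimit each female's slice.
    """
    ns, ks, starts, lens = [], [], [], []
    pos = 0
    for _, n, k in dataset.females():
        ns.append(n)
        ks.append(k)
        starts.append(pos)
        lens.append(len(n))
        pos += len(n)
    n = np.concatenate(ns).astype(np.float64)
    k = np.concatenate(ks).astype(np.float64)
    logc = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return (
        n,
        k,
        logc.astype(np.float64),
        np.asarray(starts, dtype=np.int64),
        np.asarray(lens, dtype=np.int64),
    )


def _loglik_kernel(fr_code, egg_eq, b, a, H, s, e0, h0, g, r, u, cap,
                   n, k, logc, starts, lens):
    """Dataset log-likelihood over packed arrays (njit-compatible)."""
    total = 0.0
    for fi in range(starts.shape[0]):
        start = starts[fi]
        # initial stock
        if egg_eq == 1:
            stock = math.inf
        elif egg_eq >= 6:
            stock = min(e0, cap)
        else:
            stock = e0
        cum = 0.0
        for d in range(lens[fi]):
            idx = start + d
            nd = n[idx]
            kd = k[idx]
            day = d + 1
            # functional response
            if nd > 0.0:
                if fr_code == 0:  # A: type I
                    f = a * nd
                else:
                    if fr_code == 1:  # B
                        lam = a
                    elif fr_code == 2:  # C
                        lam = b + a * nd
                    elif fr_code == 3:  # D
                        lam = b + a * cum
                    elif fr_code == 4:  # E
                        lam = a * nd ** (s - 1.0)
                    else:  # F
                        x = cum + nd
                        lam = a * x ** (s - 1.0) if x > 0.0 else 0.0
                    f = lam * nd / (1.0 + lam * H * nd)
                if f < 0.0:
                    f = 0.0
                elif f > nd:
                    f = nd
                p = f
                if stock < p:
                    p = stock
                prob = p / nd
                if prob <= 0.0:
                    if kd > 0.0:
                        return -math.inf
                else:
                    if prob >= 1.0:
                        if kd == nd:
                            prob = -1.0  # flag: contribution 0
                        else:
                            prob = 1.0 - _EPS
                    if prob > 0.0:
                        total += (
                            logc[idx]
                            + kd * math.log(prob)
                            + (nd - kd) * math.log1p(-prob)
                        )
            else:
                p = 0.0
            # propagate latent stock with the observed count
            if egg_eq != 1:
                laid = kd if kd < stock else stock
                rem = stock - laid
                if egg_eq == 2:
                    stock = rem
                else:
                    if egg_eq == 4 or egg_eq == 6:
                        rem = (1.0 - r) * rem
                    elif egg_eq == 5 or egg_eq == 7:
                        excess = rem - u
                        if excess > 0.0:
                            rem = rem - r * excess
                    stock = rem + h0 * g ** day
                    if egg_eq >= 6 and stock > cap:
                        stock = cap
            cum += nd
    return total


NUMBA_AVAILABLE = False
try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _loglik_kernel_jit = njit(cache=True, fastmath=False)(_loglik_kernel)
    NUMBA_AVAILABLE = True
except Exception:  # numba missing or broken: fall back to pure Python
    _loglik_kernel_jit = _loglik_kernel


def loglik_packed(model: ModelSpec, theta: dict, packed) -> float:
    """Dataset log-likelihood from a name->value parameter dict."""
    n, k, logc, starts, lens = packed
    return _loglik_kernel_jit(
        _FR_CODE[model.fr],
        model.egg,
        theta.get("b", 0.0),
        theta.get("a", 0.0),
        theta.get("H", 0.0),
        theta.get("s", 1.0),
        theta.get("e0", 0.0),
        theta.get("h0", 0.0),
        theta.get("g", 1.0),
        theta.get("r", 0.0),
        theta.get("u", 0.0),
        theta.get("cap", math.inf),
        n, k, logc, starts, lens,
    )
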