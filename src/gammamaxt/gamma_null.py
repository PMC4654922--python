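"""Point-mass + shifted-gamma model of the null statistic tail.

Under the global null, MB-MDR statistics over many SNP pairs follow a
semi-continuous mixture: a point mass at zero (pairs whose genotype table
is labelled all-O) and a continuous positive part.  Only the upper tail of
the positive part matters for predicting a permutation's maximum, and that
tail — by assumption the top ``tail_fraction`` (default 10 %) of strictly
positive values — is modelled as a three-parameter (shifted) gamma
distribution with location ``y0``, shape ``k`` and scale ``theta``.

With ``pi = P(X > 0)`` estimated from the zero count during sampling, the
number of statistics that fall in the modelled tail among the ``m - n``
unstored pairs is ``q = (m - n) * pi * tail_fraction``, and the maximum of
``q`` i.i.d. tail draws has CDF ``F_Z(z) = F_Y(z) ** q`` with ``F_Y`` the
regularized lower incomplete gamma.  Sampling from ``F_Z`` by inverse
transform (bisection) replaces the exhaustive maximum computation.

Shape estimation follows the standard closed-form initial guess

    k0 = (3 - s + sqrt((s - 3)^2 + 24 s)) / (12 s),
    s  = ln(mean(v - y0)) - mean(ln(v - y0)),

refined by Newton-Raphson on the gamma log-likelihood score
``ln k - psi(k) - s`` using the digamma and trigamma functions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import special

DEFAULT_S = 1_000_000
DEFAULT_TAIL_FRACTION = 0.10
DEFAULT_PRECISION = 1e-6
DEFAULT_REFIT_INTERVAL = 20
DEFAULT_INITIAL_GUESS = 1000.0

#: A batch statistic source: maps an array of indices in ``[0, m - n)`` —
#: positions within the enumeration of unstored pairs — to statistic values.
StatisticSource = Callable[[np.ndarray], np.ndarray]


@dataclass
class TailSample:
    """Retained tail of a random sample of null statistics.

    ``v`` holds the top ``tail_fraction`` of the ``S`` strictly positive
    values drawn (ascending order); ``z`` counts the zeros encountered
    while collecting them.
    """

    v: np.ndarray
    z: int
    S: int
    tail_fraction: float = DEFAULT_TAIL_FRACTION


@dataclass
class GammaTailFit:
    """Fitted null-tail model: mixture weight and shifted-gamma tail.

    ``q`` is the expected number of unstored statistics falling in the
    modelled tail; the distribution of their maximum is ``F_Y ** q``.
    """

    pi: float
    y0: float
    k: float
    theta: float
    q: float
    refit_interval: int = DEFAULT_REFIT_INTERVAL
    precision: float = DEFAULT_PRECISION


def estimate_pi(z: int, S: int) -> float:
    """Fraction of strictly positive statistics, ``S / (z + S)``."""
    if S <= 0:
        raise ValueError("S must be positive")
    if z < 0:
        raise ValueError("z must be non-negative")
    return S / (z + S)


def estimate_location(v: np.ndarray) -> float:
    """Location (shift) estimate: the minimum of the retained tail values."""
    v = np.asarray(v, dtype=np.float64)
    if v.size == 0:
        raise ValueError("empty tail sample")
    return float(v.min())


def estimate_shape(
    v: np.ndarray, y0: float, tol: float = DEFAULT_PRECISION, max_iter: int = 200
) -> float:
    """Gamma shape MLE of ``v - y0`` via Newton-Raphson.

    Values equal to ``y0`` (whose log-excess is -inf) are excluded from both
    the arithmetic and the logarithmic mean.
    """
    d = np.asarray(v, dtype=np.float64) - y0
    d = d[d > 0]
    if d.size < 2:
        raise ValueError("zero-variance tail: need at least two values above y0")
    s = math.log(d.mean()) - np.log(d).mean()
    if s <= 0:
        raise ValueError("zero-variance tail: all values equal")
    k = (3.0 - s + math.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    for _ in range(max_iter):
        step = (math.log(k) - special.digamma(k) - s) / (1.0 / k - special.polygamma(1, k))
        k_new = k - step
        if k_new <= 0:
            k_new = k / 2.0
        if abs(k_new - k) < tol:
            return float(k_new)
        k = k_new
    raise RuntimeError("shape estimation did not converge")


def initial_shape_guess(v: np.ndarray, y0: float) -> float:
    """Closed-form starting value for the shape (no Newton refinement)."""
    d = np.asarray(v, dtype=np.float64) - y0
    d = d[d > 0]
    s = math.log(d.mean()) - np.log(d).mean()
    return (3.0 - s + math.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)


def estimate_scale(v: np.ndarray, y0: float, k: float) -> float:
    """Scale estimate ``mean(v - y0) / k``."""
    if k <= 0:
        raise ValueError("shape must be positive")
    return float((np.asarray(v, dtype=np.float64) - y0).mean() / k)


def cdf_tail_max(zval, fit: GammaTailFit):
    """CDF of the maximum of ``q`` tail draws, ``[F_Y(z)] ** q``.

    ``q = 0`` returns 1 for any argument (maximum over an empty set).
    Accepts scalars or arrays.
    """
    zval = np.asarray(zval, dtype=np.float64)
    if fit.q == 0:
        out = np.ones_like(zval)
        return float(out) if out.ndim == 0 else out
    x = np.maximum(zval - fit.y0, 0.0) / fit.theta
    out = special.gammainc(fit.k, x) ** fit.q
    return float(out) if out.ndim == 0 else out


def sample_max(
    fit: GammaTailFit,
    rng: np.random.Generator,
    initial_guess: float = DEFAULT_INITIAL_GUESS,
    precision: float | None = None,
    u: float | None = None,
) -> float:
    """Draw one maximum from ``F_Z`` by inverse transform.

    A uniform ``r`` is drawn (or supplied via ``u``, for diagnostics) and
    ``F_Z^{-1}(r)`` located by bisection: starting from ``initial_guess``
    with step half of it, the step is halved each iteration until it falls
    below ``precision``.  If the initial guess is not above the target
    quantile it is doubled until it is.
    """
    if precision is None:
        precision = fit.precision
    r = float(rng.uniform()) if u is None else float(u)
    guess = float(initial_guess)
    while cdf_tail_max(guess, fit) < r:
        guess *= 2.0
    m = guess
    b = guess / 2.0
    while b >= precision:
        if cdf_tail_max(m, fit) < r:
            m += b
        else:
            m -= b
        b /= 2.0
    return m


def sample_tail(
    statistic_source: StatisticSource,
    m: int,
    n: int,
    S: int = DEFAULT_S,
    rng: np.random.Generator | None = None,
    tail_fraction: float = DEFAULT_TAIL_FRACTION,
    max_draw_factor: int = 1000,
    chunk: int = 8192,
) -> TailSample:
    """Collect ``S`` strictly positive statistics from the unstored pairs.

    Pair positions are drawn uniformly with replacement from the ``m - n``
    unstored pairs; zeros are counted in ``z``, positives accumulated until
    ``S`` of them are in hand, then sorted and trimmed to the top
    ``tail_fraction``.  ``S`` is automatically capped at
    ``max(100, m - n)`` so small problems remain tractable.
    """
    if m <= n:
        raise ValueError("need m > n unstored pairs to sample from")
    if rng is None:
        rng = np.random.default_rng()
    s_eff = min(S, max(100, m - n))
    if s_eff < 1:
        raise ValueError("S must be at least 1")
    pool = m - n
    pieces: list[np.ndarray] = []
    have = 0
    z = 0
    drawn = 0
    cap = max_draw_factor * s_eff
    while have < s_eff:
        if drawn >= cap:
            raise ValueError(
                "degenerate null (all zeros): could not collect enough strictly "
                "positive statistics"
            )
        size = min(chunk, cap - drawn)
        idx = rng.integers(0, pool, size=size)
        vals = np.asarray(statistic_source(idx), dtype=np.float64)
        drawn += size
        pos = vals > 0
        npos = int(pos.sum())
        need = s_eff - have
        if npos > need:
            # stop exactly at the S-th positive; later zeros do not count
            cum = np.cumsum(pos)
            stop = int(np.searchsorted(cum, need)) + 1
            vals = vals[:stop]
            pos = pos[:stop]
            npos = need
        pieces.append(vals[pos])
        z += int(pos.size - pos.sum())
        have += npos
    v = np.sort(np.concatenate(pieces))
    n_keep = int(math.ceil(s_eff * tail_fraction))
    return TailSample(v=v[-n_keep:], z=z, S=s_eff, tail_fraction=tail_fraction)


def fit_tail(sample: TailSample, m: int, n: int) -> GammaTailFit:
    """Estimate ``(pi, y0, k, theta)`` from a tail sample and derive ``q``."""
    pi = estimate_pi(sample.z, sample.S)
    y0 = estimate_location(sample.v)
    k = estimate_shape(sample.v, y0)
    theta = estimate_scale(sample.v, y0, k)
    q = (m - n) * pi * sample.tail_fraction
    return GammaTailFit(pi=pi, y0=y0, k=k, theta=theta, q=q)


def synthetic_mixture_source(
    pi: float,
    y0: float,
    k: float,
    theta: float,
    rng: np.random.Generator,
    tail_fraction: float = DEFAULT_TAIL_FRACTION,
) -> StatisticSource:
    """Statistic source drawing from an idealized null mixture.

    With probability ``1 - pi`` the statistic is an exact zero.  Positive
    values place the top ``tail_fraction`` on a shifted gamma
    ``y0 + Gamma(k, theta)`` and the remaining body uniformly below ``y0``,
    so the model's assumptions hold exactly.  Used by parameter-recovery
    tests and diagnostics.
    """

    def source(idx: np.ndarray) -> np.ndarray:
        size = len(idx)
        out = np.zeros(size)
        positive = rng.uniform(size=size) < pi
        npos = int(positive.sum())
        in_tail = rng.uniform(size=npos) < tail_fraction
        vals = rng.uniform(0.0, y0, size=npos)
        vals[in_tail] = y0 + theta * rng.gamma(k, size=int(in_tail.sum()))
        out[positive] = vals
        return out

    return source
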