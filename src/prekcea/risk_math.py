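"""Scalar risk algebra shared by every phase of the model.

All event likelihoods in the model are carried as *odds*; conditional
modifiers are odds ratios composed multiplicatively; conversion to the
probability actually handed to a Bernoulli draw uses ``p = odds / (1 + odds)``.
Cumulative incidences reported over multi-year horizons are back-converted to
constant annual probabilities assuming a uniform rate over the horizon.

The functions accept NumPy arrays as well as scalars (they are used both by
the per-individual reference path and by the vectorized cohort engine).
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "odds_to_prob",
    "prob_to_odds",
    "adjust_odds",
    "annual_prob_from_cumulative",
    "discount_factor",
    "EffectEstimate",
    "PooledResult",
    "pool_estimates",
    "median_fallback",
]


def odds_to_prob(odds):
    """Convert odds to a probability, ``p = odds / (1 + odds)``.

    Parameters
    ----------
    odds : float or ndarray
        Nonnegative, finite odds.

    Returns
    -------
    float or ndarray
        Probability in ``[0, 1)``, strictly increasing in ``odds``.
    """
    arr = np.asarray(odds, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr < 0):
        raise ValueError(f"odds must be finite and nonnegative, got {odds!r}")
    out = arr / (1.0 + arr)
    return float(out) if np.isscalar(odds) or arr.ndim == 0 else out


def prob_to_odds(p):
    """Convert a probability in ``[0, 1)`` to odds, ``p / (1 - p)``."""
    arr = np.asarray(p, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr < 0) or np.any(arr >= 1):
        raise ValueError(f"probability must lie in [0, 1), got {p!r}")
    out = arr / (1.0 - arr)
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def adjust_odds(base_odds, odds_ratios: Iterable[float]):
    """Apply odds ratios to base odds: ``base * prod(ORs)``.

    Order-independent by construction; every OR must be strictly positive.
    """
    base = np.asarray(base_odds, dtype=float)
    if np.any(base < 0):
        raise ValueError("base odds must be nonnegative")
    out = base.copy() if base.ndim else float(base)
    for ratio in odds_ratios:
        r = np.asarray(ratio, dtype=float)
        if np.any(r <= 0) or np.any(~np.isfinite(r)):
            raise ValueError(f"odds ratios must be positive and finite, got {ratio!r}")
        out = out * r
    return float(out) if np.ndim(out) == 0 else out


def annual_prob_from_cumulative(cumulative: float, horizon_years: int) -> float:
    """Annual probability consistent with a cumulative incidence over a horizon.

    Assumes a uniform (constant) rate: ``1 - (1 - cumulative)**(1/T)``.
    Compounding the result back over ``horizon_years`` recovers ``cumulative``.
    """
    if not 0 <= cumulative < 1:
        raise ValueError("cumulative incidence must lie in [0, 1)")
    if horizon_years < 1 or int(horizon_years) != horizon_years:
        raise ValueError("horizon_years must be a positive integer")
    return 1.0 - (1.0 - cumulative) ** (1.0 / horizon_years)


def discount_factor(rate: float, years_elapsed: int):
    """Present-value factor ``(1 + rate)**(-years)``; 1 at ``years == 0``."""
    years = np.asarray(years_elapsed)
    if rate < 0:
        raise ValueError("discount rate must be nonnegative")
    if np.any(years < 0):
        raise ValueError("years_elapsed must be nonnegative")
    out = (1.0 + rate) ** (-np.asarray(years_elapsed, dtype=float))
    return float(out) if np.ndim(out) == 0 else out


@dataclass(frozen=True)
class EffectEstimate:
    """One study's effect on the log-odds-ratio scale with its variance."""

    value: float
    variance: float

    def __post_init__(self) -> None:
        if not self.variance > 0:
            raise ValueError("variance must be strictly positive")


@dataclass(frozen=True)
class PooledResult:
    """DerSimonian–Laird random-effects pooling summary."""

    pooled: float
    tau2: float
    Q: float
    I2: float  # percent, in [0, 100]
    homogeneous: bool


def pool_estimates(
    estimates: Sequence[EffectEstimate],
    *,
    p_threshold: float = 0.10,
    i2_threshold: float = 25.0,
) -> PooledResult:
    """Pool study effects with the DerSimonian–Laird random-effects method.

    Fixed-effect weights ``w_i = 1/v_i`` give the Q statistic
    ``Q = sum w_i (theta_i - theta_FE)^2``; the between-study variance is
    ``tau2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w))`` and the pooled
    effect re-weights by ``1 / (v_i + tau2)``.

    The ``homogeneous`` flag is true when the Q-test p-value exceeds
    ``p_threshold`` *and* ``I2`` is below ``i2_threshold`` (both configurable;
    the defaults encode the usual reading of a "Q-statistic of > 0.10" as the
    Q-test's p-value).
    """
    if len(estimates) < 2:
        raise ValueError("pooling requires at least 2 estimates")
    theta = np.array([e.value for e in estimates], dtype=float)
    v = np.array([e.variance for e in estimates], dtype=float)
    k = len(estimates)
    w = 1.0 / v
    theta_fe = float(np.sum(w * theta) / np.sum(w))
    Q = float(np.sum(w * (theta - theta_fe) ** 2))
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (Q - (k - 1)) / denom) if denom > 0 else 0.0
    w_re = 1.0 / (v + tau2)
    pooled = float(np.sum(w_re * theta) / np.sum(w_re))
    I2 = max(0.0, 100.0 * (Q - (k - 1)) / Q) if Q > 0 else 0.0
    p_value = _chi2_sf(Q, k - 1)
    homogeneous = (p_value > p_threshold) and (I2 < i2_threshold)
    return PooledResult(pooled=pooled, tau2=tau2, Q=Q, I2=I2, homogeneous=homogeneous)


def _chi2_sf(x: float, df: int) -> float:
    """Chi-square survival function (Q-test p-value)."""
    from scipy.stats import chi2

    return float(chi2.sf(x, df))


def median_fallback(
    estimates: Sequence[EffectEstimate],
    ranges: Sequence[tuple[float, float]],
) -> tuple[float, float, float]:
    """Median-of-studies fallback used when pooling is rejected.

    Returns the median study value with the envelope of the reported ranges
    (lowest low, highest high).
    """
    if len(estimates) == 0:
        raise ValueError("median_fallback requires at least one estimate")
    if len(ranges) != len(estimates):
        raise ValueError("ranges must pair one-to-one with estimates")
    value = median(e.value for e in estimates)
    low = min(r[0] for r in ranges)
    high = max(r[1] for r in ranges)
    return float(value), float(low), float(high)
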