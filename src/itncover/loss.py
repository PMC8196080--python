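"""Compact-support net-loss (retention) curve and quarterly stock bookkeeping.

Household bed nets are discarded over time. Durability studies describe net
attrition with an S-shaped "smooth compact" survival curve: every net is
present at age 0, retention declines smoothly, and no net survives past a
finite maximum lifespan ``L``. The curve is

    f(t) = exp(k - k / (1 - (t/L)^2))   for 0 <= t < L,   f(t) = 0 for t >= L

with dimensionless steepness ``k > 0``. Its median crossing gives the median
retention time

    tau = L * sqrt(ln 2 / (k + ln 2)),

the headline "how long do households keep a net" quantity.

This module also provides the deterministic bookkeeping used by the national
stock-and-flow model: convolving quarterly distribution counts with the loss
curve to get net *crop* (nets currently in households), and running the
delivery-minus-distribution *stock* balance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LossCurve",
    "loss_fraction",
    "median_retention",
    "curve_from_retention",
    "quarterly_crop",
    "stock_series",
    "StockViolation",
    "QUARTER_YEARS",
]

#: length of one model time step, in years
QUARTER_YEARS = 0.25


@dataclass(frozen=True)
class LossCurve:
    """Parameters of the smooth compact retention curve.

    Parameters
    ----------
    k : float
        Dimensionless steepness, > 0. Larger ``k`` pulls the median crossing
        toward ``t = 0`` at fixed ``L``.
    L : float
        Maximum attainable lifespan in years, > 0. ``f(t) = 0`` for
        ``t >= L`` exactly.
    """

    k: float
    L: float

    def __post_init__(self) -> None:
        if not (self.k > 0):
            raise ValueError(f"steepness k must be > 0, got {self.k}")
        if not (self.L > 0):
            raise ValueError(f"lifespan L must be > 0, got {self.L}")

    @property
    def median_retention(self) -> float:
        """Median retention time tau in years (closed form)."""
        return median_retention(self)


def loss_fraction(t, curve: LossCurve):
    """Fraction of nets retained ``t`` years after distribution.

    Vectorized over ``t``. Exactly 1 at ``t = 0`` and exactly 0 for
    ``t >= L``; continuous and non-increasing in between.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("age t must be >= 0")
    out = np.zeros_like(t)
    inside = t < curve.L
    x2 = (t[inside] / curve.L) ** 2
    out[inside] = np.exp(curve.k - curve.k / (1.0 - x2))
    if out.ndim == 0 or t.ndim == 0:
        return float(np.exp(curve.k - curve.k / (1.0 - (float(t) / curve.L) ** 2))) if t < curve.L else 0.0
    return out


def median_retention(curve: LossCurve) -> float:
    """Median retention time: the unique ``t`` with ``f(t) = 1/2``.

    Closed form ``tau = L * sqrt(ln 2 / (k + ln 2))``, obtained by solving
    ``k - k/(1 - x^2) = -ln 2`` for ``x = t/L``.
    """
    ln2 = np.log(2.0)
    return curve.L * float(np.sqrt(ln2 / (curve.k + ln2)))


def curve_from_retention(tau: float, k: float = 20.0) -> LossCurve:
    """Build the loss curve with a given median retention ``tau`` at fixed ``k``.

    Inverts the closed form: ``L = tau / sqrt(ln 2 / (k + ln 2))``. With ``k``
    fixed this makes tau the single free retention parameter, which is what
    sparse survey data can identify.
    """
    if not (tau > 0):
        raise ValueError(f"median retention tau must be > 0, got {tau}")
    ln2 = np.log(2.0)
    return LossCurve(k=k, L=tau / float(np.sqrt(ln2 / (k + ln2))))


def quarterly_crop(distributed: np.ndarray, curve: LossCurve) -> np.ndarray:
    """Net crop per quarter from quarterly distribution counts.

    ``C(q) = sum_{q' <= q} D(q') * f((q - q') * 0.25)``: each past cohort of
    distributed nets decays along the loss curve. By construction
    ``D(q) <= C(q) <= cumsum(D)(q)`` — the "discard immediately" and "never
    discard" envelope.
    """
    distributed = np.asarray(distributed, dtype=float)
    if np.any(distributed < 0):
        raise ValueError("distributed counts must be >= 0")
    n = distributed.shape[0]
    ages = np.arange(n) * QUARTER_YEARS
    kernel = loss_fraction(ages, curve)
    # full convolution truncated to the observed horizon
    return np.convolve(distributed, kernel)[:n]


class StockViolation(ValueError):
    """Distribution exceeded available stock; carries the offending quarter."""

    def __init__(self, quarter: int, stock: float):
        self.quarter = quarter
        self.stock = stock
        super().__init__(
            f"negative stock {stock:.1f} at quarter {quarter}: "
            "distributed nets exceed cumulative deliveries"
        )


def stock_series(deliveries: np.ndarray, distributed: np.ndarray) -> np.ndarray:
    """Quarterly stock balance ``S(q) = S(q-1) + deliveries(q) - distributed(q)``.

    Stock is the warehouse: nets delivered by manufacturers but not yet
    handed to households. Raises :class:`StockViolation` (with the first
    offending quarter) if any balance goes negative, i.e. if more nets were
    distributed than had ever been delivered.
    """
    deliveries = np.asarray(deliveries, dtype=float)
    distributed = np.asarray(distributed, dtype=float)
    if deliveries.shape != distributed.shape:
        raise ValueError("deliveries and distributed must have equal length")
    stock = np.cumsum(deliveries - distributed)
    bad = np.nonzero(stock < -1e-9)[0]
    if bad.size:
        q = int(bad[0])
        raise StockViolation(q, float(stock[q]))
    return np.maximum(stock, 0.0)
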