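"""Variance-stabilising transforms for deviation metrics.

Access deviation and use gap live on [-1, 1]; NPC deviation is unbounded but
heavy-tailed near zero. Before Gaussian-process regression the bounded
metrics are mapped through the empirical logit (domain map [-1, 1] -> R) and
then, like all response metrics, through the inverse hyperbolic sine, so a
Gaussian likelihood is reasonable on the transformed scale. The inverse chain
is applied in reverse after prediction.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "emplogit", "inv_emplogit", "asinh_transform", "inv_asinh",
    "forward_chain", "inverse_chain", "epsilon_for",
]


def emplogit(x, eps: float = 1e-3):
    """Empirical logit on [-1, 1]: ``ln((x + 1 + eps) / (1 - x + eps))``.

    Strictly increasing and odd; ``eps > 0`` keeps the endpoints finite.
    """
    x = np.asarray(x, dtype=float)
    if eps <= 0:
        raise ValueError("eps must be > 0")
    if np.any((x < -1) | (x > 1)):
        raise ValueError("emplogit input outside [-1, 1]")
    return np.log((x + 1.0 + eps) / (1.0 - x + eps))


def inv_emplogit(y, eps: float = 1e-3):
    """Exact algebraic inverse of :func:`emplogit`."""
    y = np.asarray(y, dtype=float)
    e = np.exp(y)
    return ((1.0 + eps) * e - (1.0 + eps)) / (e + 1.0)


def asinh_transform(x):
    """Inverse hyperbolic sine, ``ln(x + sqrt(x^2 + 1))``; inverse is sinh."""
    return np.arcsinh(np.asarray(x, dtype=float))


def inv_asinh(y):
    return np.sinh(np.asarray(y, dtype=float))


def epsilon_for(effective_sample_size) -> np.ndarray:
    """Per-aggregate emplogit epsilon: 1 / (2 n_eff), floored at 1e-3."""
    n = np.asarray(effective_sample_size, dtype=float)
    return np.maximum(1.0 / (2.0 * np.maximum(n, 1.0)), 1e-3)


def forward_chain(x, bounded: bool, eps: float = 1e-3):
    """emplogit (bounded metrics only) then asinh."""
    if bounded:
        return asinh_transform(emplogit(x, eps))
    return asinh_transform(x)


def inverse_chain(y, bounded: bool, eps: float = 1e-3):
    """Inverse of :func:`forward_chain`: sinh, then inverse emplogit."""
    if bounded:
        return inv_emplogit(inv_asinh(y), eps)
    return inv_asinh(y)
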