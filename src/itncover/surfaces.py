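"""Composition of national series and deviation surfaces into coverage maps,
plus the relative-gain counterfactuals and uncertainty displays.

A final pixel map is the national value plus the local deviation, per
posterior draw:

    access = clamp(national_access + access_deviation, 0, 1)
    use    = clamp(access + use_gap_signed, 0, 1)
    npc    = max(national_npc + npc_deviation, 0)
    use_rate = use / access   (flagged NaN where access = 0)

The relative-gain counterfactuals quantify the policy question "raise access
or raise the use rate?": gain_from_use_rate is the extra use if everyone with
access used their net (use rate -> 100%, access unchanged); gain_from_access
is the extra use if access were universal at the current use rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CoverageRaster", "compose_maps", "relative_gain",
    "uncertainty_classify", "exceedance",
]


@dataclass
class CoverageRaster:
    """Per-metric summary grids: mean and central 95% interval."""

    metric: str
    time_index: int
    mean: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    mask: np.ndarray  # True where population at risk

    def __post_init__(self) -> None:
        m = self.mask
        ok = np.isfinite(self.mean[m])
        if not np.all((self.lo[m][ok] <= self.mean[m][ok] + 1e-9)
                      & (self.mean[m][ok] <= self.hi[m][ok] + 1e-9)):
            raise ValueError("interval bounds not ordered around the mean")


def _summarise(draws: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return (draws.mean(axis=0),
            np.quantile(draws, 0.025, axis=0),
            np.quantile(draws, 0.975, axis=0))


def compose_maps(national_draws: dict, deviation_draws: dict, mask: np.ndarray,
                 time_index: int = 0) -> dict:
    """Compose final coverage maps from aligned posterior draws.

    Parameters
    ----------
    national_draws : dict with 1-D arrays ``access`` and ``npc`` of national
        values, one entry per draw.
    deviation_draws : dict with arrays of shape (n_draws, rows, cols) for
        ``access_deviation``, ``use_gap_signed`` and ``npc_deviation``.
    mask : boolean population-at-risk grid; cells outside are NaN in output.

    Returns a dict with per-draw grids (``*_draws``) and
    :class:`CoverageRaster` summaries for access, use, use_rate and npc.
    The pre-clamp identity use - access = use_gap_signed holds exactly in
    the returned ``use_preclamp_draws``.
    """
    dA = np.asarray(deviation_draws["access_deviation"], float)
    gS = np.asarray(deviation_draws["use_gap_signed"], float)
    dN = np.asarray(deviation_draws["npc_deviation"], float)
    n_draws = dA.shape[0]
    nat_a = np.asarray(national_draws["access"], float).reshape(n_draws, 1, 1)
    nat_n = np.asarray(national_draws["npc"], float).reshape(n_draws, 1, 1)
    if not (dA.shape == gS.shape == dN.shape):
        raise ValueError("deviation draw stacks misaligned")

    access_pre = nat_a + dA
    access = np.clip(access_pre, 0.0, 1.0)
    use_pre = access + gS
    use = np.clip(use_pre, 0.0, 1.0)
    npc_map = np.maximum(nat_n + dN, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        use_rate = np.where(access > 0, use / access, np.nan)

    out = {"use_preclamp_draws": use_pre, "access_preclamp_draws": access_pre}
    for name, draws in [("access", access), ("use", use),
                        ("use_rate", use_rate), ("npc", npc_map)]:
        d = np.where(mask[None, :, :], draws, np.nan)
        mean, lo, hi = _summarise(d)
        out[f"{name}_draws"] = d
        out[name] = CoverageRaster(name, time_index, mean, lo, hi, mask)
    return out


def relative_gain(access: np.ndarray, use: np.ndarray):
    """Counterfactual gains in use. Returns (gain_from_use_rate, gain_from_access).

    * use rate -> 100%, access unchanged: gain = max(access - use, 0)
    * access -> 100%, use rate unchanged: gain = max(use/access - use, 0),
      with the counterfactual use rate capped at 1.

    Cells with access = 0 are flagged NaN (no use rate defined).
    """
    access = np.asarray(access, float)
    use = np.asarray(use, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(access > 0, use / access, np.nan)
    gain_use_rate = np.maximum(access - use, 0.0)
    gain_access = np.maximum(np.minimum(rate, 1.0) - use, 0.0)
    gain_use_rate = np.where(access > 0, gain_use_rate, np.nan)
    return gain_use_rate, gain_access


def uncertainty_classify(mean: np.ndarray, ci_width: np.ndarray,
                         population: np.ndarray, mask: np.ndarray,
                         n_bins: int = 4) -> np.ndarray:
    """Bivariate (mean-bin, CI-width-bin) classification for uncertainty maps.

    Bins are population-weighted quantile bins over unmasked cells; each cell
    gets an integer pair coded as ``mean_bin * n_bins + width_bin`` (masked
    cells are -1). Degenerate (constant) rasters collapse to a single bin.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    out = np.full(mean.shape, -1, dtype=int)
    m = mask & np.isfinite(mean) & np.isfinite(ci_width)
    mb = _weighted_quantile_bin(mean[m], population[m], n_bins)
    wb = _weighted_quantile_bin(ci_width[m], population[m], n_bins)
    out[m] = mb * n_bins + wb
    return out


def _weighted_quantile_bin(values: np.ndarray, weights: np.ndarray,
                           n_bins: int) -> np.ndarray:
    if np.ptp(values) == 0:
        import warnings
        warnings.warn("constant raster: single uncertainty bin", stacklevel=3)
        return np.zeros(values.shape, dtype=int)
    order = np.argsort(values, kind="stable")
    cw = np.cumsum(weights[order])
    q = cw / cw[-1]
    bins_sorted = np.minimum((q * n_bins).astype(int), n_bins - 1)
    bins = np.empty_like(bins_sorted)
    bins[order] = bins_sorted
    return bins


def exceedance(draws: np.ndarray, threshold: float, mask: np.ndarray) -> np.ndarray:
    """Per-cell probability that the metric exceeds ``threshold``:
    the fraction of posterior draws above it. Masked cells are NaN."""
    p = np.mean(np.asarray(draws, float) > threshold, axis=0)
    return np.where(mask, p, np.nan)
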