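"""Survey-level ITN coverage indicators.

All indicators are computed from household-survey microdata with the de facto
population (people who slept in the household the night before the survey) as
denominator:

* **access** — proportion of people who could sleep under an ITN assuming two
  people per net, counted at the individual level: a household of ten people
  with three nets contributes six people "with access". This individual-level
  count deliberately avoids the underestimate of the household-level
  definition.
* **household-level access** — proportion of households owning at least one
  ITN for every two people (exact ratio test, no rounding).
* **use** — proportion of people who slept under an ITN the previous night.
* **use rate** — use / access, i.e. use among those with access. It can
  exceed 1 where more than two people share a net.
* **NPC** — nets per capita.
* **deviation metrics** — pixel/cluster-level access deviation, NPC deviation
  and use gap relative to the matching national value; these are the response
  variables of the geostatistical stage.

A ``weight`` column is honoured wherever present (survey sampling weights)
and defaults to 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from sklearn.isotonic import IsotonicRegression

__all__ = [
    "individual_access_count",
    "population_access",
    "household_level_access",
    "use_and_rate",
    "npc",
    "crop_to_access",
    "AccessCurve",
    "cluster_aggregates",
    "deviation_metrics",
]

SURVEY_COLUMNS = [
    "survey_id", "cluster_id", "lon", "lat", "year", "month",
    "hh_id", "defacto_size", "n_citn", "n_llin", "sleepers_under_nets",
]


def _weights(households: pd.DataFrame) -> np.ndarray:
    if "weight" in households.columns:
        return households["weight"].to_numpy(dtype=float)
    return np.ones(len(households))


def _total_nets(households: pd.DataFrame) -> np.ndarray:
    return (households["n_citn"] + households["n_llin"]).to_numpy(dtype=float)


def individual_access_count(defacto_size, total_nets):
    """People with access in one household: ``min(2 * nets, size)``.

    Vectorized. A household of 10 with 3 nets yields 6.
    """
    size = np.asarray(defacto_size)
    nets = np.asarray(total_nets)
    if np.any(size < 0) or np.any(nets < 0):
        raise ValueError("household size and net counts must be >= 0")
    return np.minimum(2 * nets, size)


def population_access(households: pd.DataFrame) -> float:
    """Weighted proportion of the de facto population with access."""
    if len(households) == 0:
        raise ValueError("empty household table")
    w = _weights(households)
    size = households["defacto_size"].to_numpy(dtype=float)
    if (w * size).sum() <= 0:
        raise ValueError("total de facto population is zero")
    covered = individual_access_count(size, _total_nets(households))
    return float((w * covered).sum() / (w * size).sum())


def household_level_access(households: pd.DataFrame) -> float:
    """Weighted fraction of households with ``nets >= size / 2``."""
    if len(households) == 0:
        raise ValueError("empty household table")
    w = _weights(households)
    ok = _total_nets(households) >= households["defacto_size"].to_numpy(dtype=float) / 2.0
    return float((w * ok).sum() / w.sum())


def use_and_rate(households: pd.DataFrame) -> tuple[float, float]:
    """(use, use_rate). ``use_rate`` is NaN-flagged when access is zero."""
    if len(households) == 0:
        raise ValueError("empty household table")
    w = _weights(households)
    size = households["defacto_size"].to_numpy(dtype=float)
    sleepers = households["sleepers_under_nets"].to_numpy(dtype=float)
    use = float((w * sleepers).sum() / (w * size).sum())
    access = population_access(households)
    rate = use / access if access > 0 else float("nan")
    return use, rate


def npc(households: pd.DataFrame) -> float:
    """Weighted nets per (de facto) capita."""
    w = _weights(households)
    size = households["defacto_size"].to_numpy(dtype=float)
    return float((w * _total_nets(households)).sum() / (w * size).sum())


class AccessCurve:
    """Monotone saturating calibration curve access = g(npc).

    Fitted by isotonic regression on (npc, access) calibration pairs,
    anchored at g(0) = 0 and capped at 1, then smoothed with a monotone
    (PCHIP) spline through the isotonic fit. Evaluations beyond the
    calibrated npc range are flagged via :attr:`extrapolated`.
    """

    def __init__(self, npc_pairs, access_pairs):
        npc_arr = np.asarray(npc_pairs, dtype=float)
        acc_arr = np.asarray(access_pairs, dtype=float)
        if npc_arr.size < 5:
            raise ValueError("need >= 5 calibration pairs")
        if np.any(npc_arr < 0) or np.any((acc_arr < 0) | (acc_arr > 1)):
            raise ValueError("calibration pairs outside metric domains")
        # anchor at the origin: zero nets means zero access
        npc_arr = np.append(npc_arr, 0.0)
        acc_arr = np.append(acc_arr, 0.0)
        iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
        iso.fit(npc_arr, acc_arr)
        # collapse to unique knots for the monotone spline
        knots_x = np.unique(npc_arr)
        knots_y = iso.predict(knots_x)
        self.npc_range = (float(knots_x.min()), float(knots_x.max()))
        if knots_x.size >= 2:
            self._spline = PchipInterpolator(knots_x, knots_y, extrapolate=False)
        else:  # degenerate: single knot
            self._spline = None
            self._const = float(knots_y[0])
        self._hi_val = float(knots_y[-1])
        self.extrapolated = False

    def __call__(self, npc_series):
        x = np.asarray(npc_series, dtype=float)
        lo, hi = self.npc_range
        self.extrapolated = bool(np.any((x < lo) | (x > hi)))
        if self._spline is None:
            out = np.full_like(x, self._const)
        else:
            out = self._spline(np.clip(x, lo, hi))
        out = np.clip(out, 0.0, 1.0)
        return float(out) if np.isscalar(npc_series) else out


def crop_to_access(npc_series, calibration_npc, calibration_access):
    """Convert a national NPC series to national access through a fitted
    monotone calibration curve. Returns (access_series, curve); inspect
    ``curve.extrapolated`` for out-of-range evaluations."""
    curve = AccessCurve(calibration_npc, calibration_access)
    return curve(npc_series), curve


def cluster_aggregates(survey: pd.DataFrame) -> pd.DataFrame:
    """Aggregate household records to cluster level (one row per cluster-month).

    Returns columns: cluster_id, lon, lat, year, month, access, use, npc,
    n_persons (effective sample size).
    """
    if len(survey) == 0:
        raise ValueError("empty survey table")
    rows = []
    for key, grp in survey.groupby(["cluster_id", "year", "month"], sort=True):
        use, _ = use_and_rate(grp)
        rows.append({
            "cluster_id": key[0],
            "lon": grp["lon"].iloc[0],
            "lat": grp["lat"].iloc[0],
            "year": key[1],
            "month": key[2],
            "access": population_access(grp),
            "use": use,
            "npc": npc(grp),
            "n_persons": float(grp["defacto_size"].sum()),
        })
    return pd.DataFrame(rows)


def deviation_metrics(aggregates: pd.DataFrame, national: pd.DataFrame) -> pd.DataFrame:
    """Attach deviation metrics to cluster aggregates.

    ``national`` must carry columns year, month, access, npc covering every
    aggregate month. Adds:

    * ``access_deviation`` = local access - national access,
    * ``npc_deviation``    = local npc - national npc,
    * ``use_gap_signed``   = use - access (stored so that composition
      use = access + use_gap_signed is exactly additive),
    * ``use_gap``          = access - use (the reported convention: positive
      means nets are under-used).
    """
    nat = national.set_index(["year", "month"])
    keys = list(zip(aggregates["year"], aggregates["month"]))
    missing = [k for k in keys if k not in nat.index]
    if missing:
        raise KeyError(f"national series missing months: {sorted(set(missing))[:5]}")
    nat_access = np.array([nat.loc[k, "access"] for k in keys], dtype=float)
    nat_npc = np.array([nat.loc[k, "npc"] for k in keys], dtype=float)
    out = aggregates.copy()
    out["access_deviation"] = out["access"].to_numpy() - nat_access
    out["npc_deviation"] = out["npc"].to_numpy() - nat_npc
    out["use_gap_signed"] = out["use"].to_numpy() - out["access"].to_numpy()
    out["use_gap"] = -out["use_gap_signed"]
    return out
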