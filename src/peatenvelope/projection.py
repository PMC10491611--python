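"""Future-scenario mechanics: unit conversion, anomaly downscaling, change maps.

GCM monthly outputs arrive in model-native units (temperature K,
precipitation flux kg m-2 s-1, cloud cover fraction or percent) and are
converted to the analysis units (degC, mm/month, sunshine fraction = 1 -
cloud fraction).  The change signal is then transferred onto the observed
baseline climatology with the anomaly (delta) method: additive deltas for
temperature and sunshine, a multiplicative ratio for precipitation with a
guard against near-zero GCM baselines.  Re-classifying the envelope under
the perturbed climatology yields per-cell gain/loss categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import GridSpec, MonthlyClimatology, PeatMask, RasterField
from .radiation import DAYS_IN_MONTH

#: default precipitation-ratio clamp and dry-baseline guard (mm/month)
RATIO_MAX = 5.0
DRY_EPS = 1.0


# ---------------------------------------------------------------------------
# Unit conversion
# ---------------------------------------------------------------------------

def kelvin_to_celsius(t_kelvin):
    return np.asarray(t_kelvin, dtype=float) - 273.15


def flux_to_monthly_mm(flux, month_index=None):
    """kg m-2 s-1 -> mm/month using a 365-day no-leap calendar.

    ``flux`` may be (12, ...) monthly stacks (month_index None) or a single
    month's field with ``month_index`` in 0..11.
    """
    flux = np.asarray(flux, dtype=float)
    if np.any(flux[~np.isnan(flux)] < 0):
        raise ValueError("precipitation flux must be non-negative")
    if month_index is None:
        if flux.shape[0] != 12:
            raise ValueError("expected a 12-month stack or a month_index")
        days = DAYS_IN_MONTH.reshape((12,) + (1,) * (flux.ndim - 1))
    else:
        days = DAYS_IN_MONTH[month_index]
    return flux * 86_400.0 * days


def cloud_to_sunshine(cloud, percent: bool = False):
    """Sunshine fraction = 1 - cloud fraction (cloud in percent if flagged)."""
    c = np.asarray(cloud, dtype=float)
    if percent:
        c = c / 100.0
    return np.clip(1.0 - c, 0.0, 1.0)


_CONVERTERS = {
    ("tmp", "K"): kelvin_to_celsius,
    ("tmp", "degC"): lambda x: np.asarray(x, dtype=float),
    ("pre", "kg m-2 s-1"): flux_to_monthly_mm,
    ("pre", "mm/month"): lambda x: np.asarray(x, dtype=float),
    ("sun", "cloud_fraction"): cloud_to_sunshine,
    ("sun", "cloud_percent"): lambda x: cloud_to_sunshine(x, percent=True),
    ("sun", "fraction"): lambda x: np.asarray(x, dtype=float),
}


def convert_units(raw: dict[str, np.ndarray],
                  units: dict[str, str],
                  grid: GridSpec) -> MonthlyClimatology:
    """Convert raw monthly GCM stacks into an analysis-unit climatology.

    ``raw`` maps {'tmp', 'pre', 'sun'} to (12, n_lat, n_lon) arrays;
    ``units`` declares each variable's source unit (no defaults — an
    undeclared unit is an error).
    """
    out = {}
    for var in ("tmp", "pre", "sun"):
        if var not in raw:
            raise ValueError(f"missing variable {var!r}")
        if var not in units:
            raise ValueError(f"units not declared for {var!r}")
        key = (var, units[var])
        if key not in _CONVERTERS:
            raise ValueError(f"unknown unit {units[var]!r} for {var!r}")
        out[var] = _CONVERTERS[key](raw[var])
    return MonthlyClimatology(grid=grid, tmp=out["tmp"], pre=out["pre"],
                              sun=out["sun"])


# ---------------------------------------------------------------------------
# Anomaly downscaling
# ---------------------------------------------------------------------------

def apply_anomalies(baseline: MonthlyClimatology,
                    gcm_baseline: MonthlyClimatology,
                    gcm_future: MonthlyClimatology,
                    r_max: float = RATIO_MAX,
                    eps: float = DRY_EPS,
                    anomaly_mode: str = "delta") -> MonthlyClimatology:
    """Transfer the GCM change signal onto the fine baseline climatology.

    Temperature and sunshine take additive deltas (sunshine clipped to
    [0, 1]); precipitation takes the multiplicative ratio future/baseline,
    clamped to [0, r_max] and defined as 1 where the GCM baseline is drier
    than ``eps`` mm/month.  ``anomaly_mode='off'`` substitutes the raw
    future fields instead (no bias correction).
    """
    for other in (gcm_baseline, gcm_future):
        if other.grid != baseline.grid:
            raise ValueError("GCM fields must be regridded onto the baseline "
                             "grid first")
        if other.tmp.shape[0] != baseline.tmp.shape[0]:
            raise ValueError("month count mismatch")
    if anomaly_mode == "off":
        return MonthlyClimatology(grid=baseline.grid, tmp=gcm_future.tmp,
                                  pre=gcm_future.pre, sun=gcm_future.sun)
    if anomaly_mode != "delta":
        raise ValueError(f"unknown anomaly_mode {anomaly_mode!r}")

    tmp = baseline.tmp + (gcm_future.tmp - gcm_baseline.tmp)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = gcm_future.pre / gcm_baseline.pre
    ratio = np.where(gcm_baseline.pre < eps, 1.0, ratio)
    ratio = np.clip(ratio, 0.0, r_max)
    pre = np.maximum(baseline.pre * ratio, 0.0)
    sun = np.clip(baseline.sun + (gcm_future.sun - gcm_baseline.sun), 0.0, 1.0)
    return MonthlyClimatology(grid=baseline.grid, tmp=tmp, pre=pre, sun=sun)


def ensemble_mean(members: list[MonthlyClimatology]) -> MonthlyClimatology:
    """Cell-wise arithmetic mean over ensemble members, NaN-excluded."""
    if not members:
        raise ValueError("empty ensemble member list")
    grid = members[0].grid
    for m in members[1:]:
        if m.grid != grid:
            raise ValueError("ensemble members on different grids")
    with np.errstate(invalid="ignore"):
        out = {var: np.nanmean(np.stack([getattr(m, var) for m in members]),
                               axis=0)
               for var in ("tmp", "pre", "sun")}
    return MonthlyClimatology(grid=grid, **out)


# ---------------------------------------------------------------------------
# Change maps
# ---------------------------------------------------------------------------

#: integer category codes used when writing change maps to rasters
CHANGE_CODES = {"stable_absent": 0, "gained": 1, "lost": 2,
                "stable_present": 3}


@dataclass
class ChangeMap:
    """Per-cell baseline-vs-future presence transition categories."""

    grid: GridSpec
    categories: np.ndarray  # uint8 codes from CHANGE_CODES
    summary: dict = field(default_factory=dict)


def project_change(baseline: PeatMask, future: PeatMask) -> ChangeMap:
    """Categorise cells into stable_present / lost / gained / stable_absent.

    The summary reports counts per category and the fraction of baseline
    presence retained in the future envelope.
    """
    if baseline.grid != future.grid:
        raise ValueError("baseline and future masks on different grids")
    b, f = baseline.presence, future.presence
    cats = np.zeros(b.shape, dtype=np.uint8)
    cats[b & f] = CHANGE_CODES["stable_present"]
    cats[b & ~f] = CHANGE_CODES["lost"]
    cats[~b & f] = CHANGE_CODES["gained"]
    counts = {name: int((cats == code).sum())
              for name, code in CHANGE_CODES.items()}
    n_base = counts["stable_present"] + counts["lost"]
    summary = dict(counts)
    summary["baseline_present"] = n_base
    summary["future_present"] = counts["stable_present"] + counts["gained"]
    summary["retained_fraction"] = (
        counts["stable_present"] / n_base if n_base else None)
    return ChangeMap(grid=baseline.grid, categories=cats, summary=summary)
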