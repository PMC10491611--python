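"""Environmental-space assembly, envelope thresholds and classification.

The envelope model predicts peat presence wherever a small set of per-cell
predictors — moisture index (MI), mean annual temperature (MAT, deg C),
terrain slope (deg) and permafrost active layer thickness (ALT, m) — all
fall inside calibrated lower/upper bounds.  Bounds may be "ND" (not
determined), imposing no constraint.  Two published presets ship as named
constants: a *narrow* envelope calibrated on the Zoige peatland complex
(MI >= 1.7, MAT 0-2 degC, slope <= 2 deg) and a *wide* one for the whole
Tibetan Plateau (MI >= 0.5, MAT -5-2 degC, slope 0-5 deg, ALT <= 2.3 m).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .grids import GridSpec, MonthlyClimatology, PeatMask, RasterField
from .radiation import MoistureIndexField

logger = logging.getLogger(__name__)

ENVELOPE_VARIABLES = ("MI", "MAT", "slope", "ALT")


@dataclass(frozen=True)
class EnvelopeThresholds:
    """Lower/upper bounds per predictor; ``None`` means "not determined"."""

    bounds: dict[str, tuple[float | None, float | None]]
    name: str = "custom"

    def __post_init__(self) -> None:
        if not any(lo is not None or hi is not None
                   for lo, hi in self.bounds.values()):
            raise ValueError("at least one bound must be defined")
        for var, (lo, hi) in self.bounds.items():
            if lo is not None and hi is not None and lo > hi:
                raise ValueError(f"{var}: lower bound {lo} > upper bound {hi}")

    def constrained_variables(self) -> list[str]:
        return [v for v, (lo, hi) in self.bounds.items()
                if lo is not None or hi is not None]

    def to_dict(self) -> dict:
        return {"name": self.name,
                "bounds": {v: {"lower": lo, "upper": hi}
                           for v, (lo, hi) in self.bounds.items()}}

    @classmethod
    def from_dict(cls, d: dict) -> "EnvelopeThresholds":
        bounds = {v: (b.get("lower"), b.get("upper"))
                  for v, b in d["bounds"].items()}
        return cls(bounds=bounds, name=d.get("name", "custom"))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "EnvelopeThresholds":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


#: narrow envelope: Zoige peatland complex calibration
NARROW = EnvelopeThresholds(
    bounds={"MI": (1.7, None), "MAT": (0.0, 2.0),
            "slope": (None, 2.0), "ALT": (None, None)},
    name="narrow")

#: wide envelope: whole-plateau peat-map calibration
WIDE = EnvelopeThresholds(
    bounds={"MI": (0.5, None), "MAT": (-5.0, 2.0),
            "slope": (0.0, 5.0), "ALT": (None, 2.3)},
    name="wide")

PRESETS = {"narrow": NARROW, "wide": WIDE}


def get_preset(name: str) -> EnvelopeThresholds:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown threshold preset {name!r}; "
                       f"available: {sorted(PRESETS)}") from None


# ---------------------------------------------------------------------------
# Environment table
# ---------------------------------------------------------------------------

def build_environment(clim: MonthlyClimatology,
                      mi: MoistureIndexField,
                      slope: RasterField,
                      alt: RasterField | None = None,
                      elevation: RasterField | None = None) -> pd.DataFrame:
    """Assemble the per-cell predictor table.

    One row per cell with all-defined climate; columns: row, col, lat, lon,
    MI, MAT, slope, ALT, elevation, MAP, PJJA.  ALT is NaN where there is
    no permafrost — that is informative, not an error.  All layers must
    already share the analysis grid (regrid first).
    """
    grid = clim.grid
    for name, layer in (("mi", mi), ("slope", slope),
                        ("alt", alt), ("elevation", elevation)):
        if layer is not None and layer.grid != grid:
            raise ValueError(
                f"{name} layer is on a different grid; regrid it onto the "
                "analysis grid first (grids.regrid_bilinear)")

    defined = clim.defined
    rows, cols = np.nonzero(defined)
    n_excluded = int((~defined).sum())
    if n_excluded:
        logger.info("build_environment: %d cells excluded (missing climate)",
                    n_excluded)
    tbl = pd.DataFrame({
        "row": rows,
        "col": cols,
        "lat": grid.lat_centers[rows],
        "lon": grid.lon_centers[cols],
        "MI": mi.mi[rows, cols],
        "MAT": clim.mat[rows, cols],
        "slope": slope.values[rows, cols],
        "ALT": (alt.values[rows, cols] if alt is not None else np.nan),
        "elevation": (elevation.values[rows, cols]
                      if elevation is not None else np.nan),
        "MAP": clim.map_annual[rows, cols],
        "PJJA": clim.pre[5:8].sum(axis=0)[rows, cols],
    })
    tbl.attrs["n_excluded"] = n_excluded
    return tbl


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify(env: pd.DataFrame, thresholds: EnvelopeThresholds,
             missing_passes: bool = True,
             strict_bounds: bool = False) -> np.ndarray:
    """Apply the envelope rule; returns a boolean presence vector over rows.

    A cell is present when every variable with a defined bound satisfies
    lower <= value <= upper (strict inequalities with ``strict_bounds``).
    ND bounds impose no constraint.  A missing value for a constrained
    variable passes that check when ``missing_passes`` (the default —
    e.g. no-permafrost cells have no ALT yet may host peat), else fails it.
    """
    present = np.ones(len(env), dtype=bool)
    for var in thresholds.constrained_variables():
        if var not in env.columns:
            raise KeyError(f"threshold variable {var!r} absent from the "
                           "environment table")
        vals = env[var].to_numpy(dtype=float)
        lo, hi = thresholds.bounds[var]
        ok = np.ones(len(env), dtype=bool)
        if lo is not None:
            ok &= (vals > lo) if strict_bounds else (vals >= lo)
        if hi is not None:
            ok &= (vals < hi) if strict_bounds else (vals <= hi)
        missing = np.isnan(vals)
        ok[missing] = missing_passes
        present &= ok
    return present


def classify_to_mask(env: pd.DataFrame, thresholds: EnvelopeThresholds,
                     grid: GridSpec, **kw) -> PeatMask:
    """Classify and scatter the result back onto the grid as a PeatMask."""
    pres = classify(env, thresholds, **kw)
    presence = np.zeros(grid.shape, dtype=bool)
    presence[env["row"].to_numpy(), env["col"].to_numpy()] = pres
    return PeatMask(grid=grid, presence=presence, fraction=None, cutoff=0.0)


# ---------------------------------------------------------------------------
# Threshold derivation
# ---------------------------------------------------------------------------

def derive_thresholds(env: pd.DataFrame, presence: np.ndarray,
                      variables=("MI", "MAT", "slope"),
                      method: str = "minmax", q: float = 0.025,
                      nd_variables=(), name: str = "derived"
                      ) -> EnvelopeThresholds:
    """Fit envelope bounds from the presence cells' environmental values.

    ``method='minmax'`` uses the min/max of each variable over presence
    cells; ``method='quantile'`` uses the q and 1-q empirical quantiles
    (q=0 degenerates to minmax).  Variables in ``nd_variables`` are left
    unbounded (ND).
    """
    if method not in ("minmax", "quantile"):
        raise ValueError(f"unknown method {method!r}")
    if method == "quantile" and not 0.0 <= q < 0.5:
        raise ValueError("quantile q must lie in [0, 0.5)")
    presence = np.asarray(presence, dtype=bool)
    bounds: dict[str, tuple[float | None, float | None]] = {}
    for var in variables:
        if var in nd_variables:
            bounds[var] = (None, None)
            continue
        vals = env.loc[presence, var].dropna().to_numpy(dtype=float)
        if vals.size < 5:
            raise ValueError(
                f"{var}: only {vals.size} presence cells with a defined "
                "value; need at least 5 to derive thresholds")
        if method == "minmax" or q == 0.0:
            lo, hi = float(vals.min()), float(vals.max())
        else:
            lo, hi = (float(np.quantile(vals, q)),
                      float(np.quantile(vals, 1.0 - q)))
        bounds[var] = (lo, hi)
    for var in nd_variables:
        bounds.setdefault(var, (None, None))
    return EnvelopeThresholds(bounds=bounds, name=name)


# ---------------------------------------------------------------------------
# Environmental-space histograms
# ---------------------------------------------------------------------------

def env_space_histograms(tables: dict[str, pd.DataFrame],
                         variables=("MI", "MAT", "slope", "elevation"),
                         n_bins: int = 30,
                         edges: dict[str, np.ndarray] | None = None
                         ) -> pd.DataFrame:
    """Shared-edge frequency histograms per labelled dataset and variable.

    Bin edges are shared across datasets per variable; by default they span
    the pooled range of all datasets so every defined value is counted.
    Returns a tidy frame (dataset, variable, bin_left, bin_right, count)
    with per-dataset totals in ``attrs['totals']``.
    """
    records = []
    totals: dict[str, dict[str, int]] = {}
    for var in variables:
        if edges and var in edges:
            e = np.asarray(edges[var], dtype=float)
        else:
            pooled = np.concatenate([
                t[var].dropna().to_numpy(dtype=float)
                for t in tables.values() if var in t.columns]) \
                if tables else np.array([])
            if pooled.size == 0:
                continue
            lo, hi = pooled.min(), pooled.max()
            if lo == hi:
                hi = lo + 1.0
            e = np.linspace(lo, hi, n_bins + 1)
        for label, tbl in tables.items():
            vals = tbl[var].dropna().to_numpy(dtype=float) \
                if var in tbl.columns else np.array([])
            if vals.size == 0:
                logger.warning("env_space_histograms: dataset %r empty for %s",
                               label, var)
            counts, _ = np.histogram(vals, bins=e)
            totals.setdefault(label, {})[var] = int(vals.size)
            for k in range(len(e) - 1):
                records.append({"dataset": label, "variable": var,
                                "bin_left": e[k], "bin_right": e[k + 1],
                                "count": int(counts[k])})
    out = pd.DataFrame.from_records(records)
    out.attrs["totals"] = totals
    return out


# ---------------------------------------------------------------------------
# Agreement maps
# ---------------------------------------------------------------------------

#: integer category codes used when writing agreement maps to rasters
AGREEMENT_CODES = {"neither": 0, "map_only": 1, "model_only": 2,
                   "both": 3, "undefined": 255}


@dataclass
class AgreementMap:
    """Per-cell model-vs-map agreement categories on the analysis grid."""

    grid: GridSpec
    categories: np.ndarray  # uint8 codes from AGREEMENT_CODES
    counts: dict[str, int] = field(default_factory=dict)


def agreement_map(predicted: PeatMask, observed: PeatMask,
                  valid: np.ndarray | None = None) -> AgreementMap:
    """Categorise each cell: both / model_only / map_only / neither.

    Category counts equal the confusion counts of the same comparison
    (both=TP, model_only=FP, map_only=FN, neither=TN).  Cells outside
    ``valid`` (if given) are coded undefined.
    """
    if predicted.grid != observed.grid:
        raise ValueError("predicted and observed masks are on different grids")
    p, o = predicted.presence, observed.presence
    cats = np.full(p.shape, AGREEMENT_CODES["undefined"], dtype=np.uint8)
    if valid is None:
        valid = np.ones(p.shape, dtype=bool)
    cats[valid & p & o] = AGREEMENT_CODES["both"]
    cats[valid & p & ~o] = AGREEMENT_CODES["model_only"]
    cats[valid & ~p & o] = AGREEMENT_CODES["map_only"]
    cats[valid & ~p & ~o] = AGREEMENT_CODES["neither"]
    counts = {name: int((cats == code).sum())
              for name, code in AGREEMENT_CODES.items()}
    return AgreementMap(grid=predicted.grid, categories=cats, counts=counts)
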