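"""Derived environmental variables and the lithology composition table.

From per-cell monthly climate series (mean/max/min temperature, total
precipitation) plus elevation, this module builds the 22 per-ecoregion
variables used by the variable-selection and distance stages: 18 climatic
summaries (codes ``"1"``..``"18"``) and four altitudinal ones
(``"E1"``..``"E4"``).

Conventions, fixed and documented in the methods note:

* ecoregion monthly series are unweighted means over the ecoregion's cells
  (all cells have equal 1-km2 area);
* an "annual quarter" is any 3 consecutive calendar months with December ->
  January wrap-around; ties between windows are broken by the earliest
  starting month;
* every standard deviation uses the n-1 denominator (a single-cell ecoregion
  has elevation SD 0 by convention);
* extreme-month codes (13, 14) are computed from the per-month ecoregion
  means of cell maxima/minima, i.e. mean over cells first, extreme second.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_data import ValidationError

CLIMATIC_CODES = [str(i) for i in range(1, 19)]
ALTITUDINAL_CODES = ["E1", "E2", "E3", "E4"]
ALL_CODES = CLIMATIC_CODES + ALTITUDINAL_CODES

#: human-readable variable names, by code
VARIABLE_NAMES = {
    "1": "Mean of monthly mean temperature",
    "2": "Variation of monthly mean temperature (SD)",
    "3": "Range of monthly temperature",
    "4": "Total monthly precipitation",
    "5": "Variation of monthly precipitation (SD)",
    "6": "Range of monthly precipitation",
    "7": "Mean of monthly maximum temperature",
    "8": "Variation of monthly maximum temperature (SD)",
    "9": "Mean of monthly minimum temperature",
    "10": "Variation of monthly minimum temperature (SD)",
    "11": "Precipitation of the driest month",
    "12": "Precipitation of the wettest month",
    "13": "Maximum temperature of the warmest month",
    "14": "Minimum temperature of the coldest month",
    "15": "Mean precipitation of driest annual quarter",
    "16": "Mean precipitation of wettest annual quarter",
    "17": "Mean temperature of coldest annual quarter",
    "18": "Mean temperature of warmest annual quarter",
    "E1": "Mean elevation",
    "E2": "Maximum elevation",
    "E3": "Minimum elevation",
    "E4": "Variation of elevation (SD)",
}

MONTHS = [f"{m:02d}" for m in range(1, 13)]
MONTHLY_PREFIXES = ("tmean", "tmax", "tmin", "prec")


def monthly_columns(prefix: str) -> list[str]:
    return [f"{prefix}_{m}" for m in MONTHS]


def validate_monthly_cells(cells: pd.DataFrame) -> pd.DataFrame:
    """Check a per-cell monthly table: all 12 months, max >= mean >= min."""
    required = ["ecoregion", "elev_m"]
    for prefix in MONTHLY_PREFIXES:
        required += monthly_columns(prefix)
    missing = [c for c in required if c not in cells.columns]
    if missing:
        raise ValidationError(f"monthly cell table lacks column(s) {missing[:3]} ...")
    tmean = cells[monthly_columns("tmean")].to_numpy()
    tmax = cells[monthly_columns("tmax")].to_numpy()
    tmin = cells[monthly_columns("tmin")].to_numpy()
    if (tmax < tmean - 1e-9).any() or (tmean < tmin - 1e-9).any():
        raise ValidationError("monthly temperatures violate max >= mean >= min")
    return cells


def _sd(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return 0.0 if x.size < 2 else float(np.std(x, ddof=1))


def _quarter_windows(values: np.ndarray) -> np.ndarray:
    """Totals of all 12 wrap-around 3-month windows; row i starts at month i."""
    ext = np.concatenate([values, values[:2]])
    return np.array([ext[i:i + 3].sum() for i in range(12)])


def _quarter_mean(values: np.ndarray, which: str, by: np.ndarray | None = None):
    """Mean of ``values`` over the extreme 3-month window.

    The window is chosen by the totals of ``by`` (default ``values``);
    ``which`` is 'min' or 'max'. Ties break toward the earliest start month.
    """
    by = values if by is None else by
    totals = _quarter_windows(np.asarray(by, dtype=float))
    start = int(np.argmin(totals) if which == "min" else np.argmax(totals))
    ext = np.concatenate([np.asarray(values, dtype=float)] * 2)
    return float(ext[start:start + 3].mean())


def build_env_table(cells: pd.DataFrame) -> pd.DataFrame:
    """Build the 22-variable ecoregion table from per-cell monthly data.

    Monthly series are first averaged over each ecoregion's cells; all codes
    are then computed from the resulting 12-value ecoregion series (elevation
    codes E1-E4 summarize the raw cell elevations directly).
    """
    validate_monthly_cells(cells)
    rows = {}
    for eco, sub in cells.groupby("ecoregion", sort=False):
        tmean = sub[monthly_columns("tmean")].mean(axis=0).to_numpy()
        tmax = sub[monthly_columns("tmax")].mean(axis=0).to_numpy()
        tmin = sub[monthly_columns("tmin")].mean(axis=0).to_numpy()
        prec = sub[monthly_columns("prec")].mean(axis=0).to_numpy()
        elev = sub["elev_m"].to_numpy(dtype=float)
        rows[eco] = {
            "1": float(tmean.mean()),
            "2": _sd(tmean),
            "3": float(tmean.max() - tmean.min()),
            "4": float(prec.sum()),
            "5": _sd(prec),
            "6": float(prec.max() - prec.min()),
            "7": float(tmax.mean()),
            "8": _sd(tmax),
            "9": float(tmin.mean()),
            "10": _sd(tmin),
            "11": float(prec.min()),
            "12": float(prec.max()),
            "13": float(tmax.max()),
            "14": float(tmin.min()),
            "15": _quarter_mean(prec, "min"),
            "16": _quarter_mean(prec, "max"),
            "17": _quarter_mean(tmean, "min"),
            "18": _quarter_mean(tmean, "max"),
            "E1": float(elev.mean()),
            "E2": float(elev.max()),
            "E3": float(elev.min()),
            "E4": _sd(elev),
        }
    env = pd.DataFrame.from_dict(rows, orient="index")[ALL_CODES]
    env.index.name = "ecoregion"
    return env


def build_lithology_table(surfaces: pd.DataFrame) -> pd.DataFrame:
    """Normalize an ecoregion x substrate-category area table to row fractions.

    ``surfaces`` holds surface areas (km2) per substrate category; the output
    holds relative surface fractions, each row summing to 1. Categories absent
    from an ecoregion get fraction 0.
    """
    vals = surfaces.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValidationError("negative surface area in lithology table")
    totals = vals.sum(axis=1)
    if (totals <= 0).any():
        bad = surfaces.index[totals <= 0][0]
        raise ValidationError(f"ecoregion {bad!r} has zero total lithology surface")
    out = surfaces.div(totals, axis=0).fillna(0.0)
    out.index.name = "ecoregion"
    return out


def read_monthly_cells(path, sep: str = "\t") -> pd.DataFrame:
    return validate_monthly_cells(pd.read_csv(path, sep=sep))


def read_env_table(path, sep: str = "\t") -> pd.DataFrame:
    env = pd.read_csv(path, sep=sep, index_col=0)
    env.columns = [str(c) for c in env.columns]
    missing = [c for c in ALL_CODES if c not in env.columns]
    if missing:
        raise ValidationError(f"environment table lacks variable(s) {missing}")
    if env[ALL_CODES].isna().any().any():
        raise ValidationError("missing values in environment table")
    return env[ALL_CODES]


def read_lithology_table(path, sep: str = "\t") -> pd.DataFrame:
    tab = pd.read_csv(path, sep=sep, index_col=0)
    sums = tab.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-9):
        raise ValidationError("lithology fractions must sum to 1 per ecoregion")
    return tab
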