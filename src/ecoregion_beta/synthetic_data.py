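"""Synthetic landscapes and floras with known diversity drivers.

No machine-readable flora exists for the region that motivated this package
(the source floras are printed catalogs), so every downstream stage is
exercised on generated data in which the true drivers of beta diversity are
known by construction:

* a rectangular 1-km2 cell grid partitioned into contiguous block ecoregions;
* a smooth multi-peak elevation field with additive noise ("high mountain
  ranges surrounded by extensive lowlands");
* monthly temperatures that fall with elevation at a fixed lapse rate and
  cycle seasonally; monthly precipitation that increases westward and has a
  summer minimum;
* a categorical lithology mosaic of spatial patches;
* a flora split into *nonendemics* — occupancy set by a logistic
  climate-niche match times an exponential distance decay from a seeded
  origin ecoregion — and narrow *endemics*, present only where the mean
  elevation falls in a narrow window and a required lithology category is
  available, with a fidelity probability.

Every stochastic draw flows from one seeded generator; identical
configurations produce identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_data import (OccurrenceMatrix, ValidationError,
                        validate_ecoregion_info, write_cell_grid,
                        write_ecoregion_info, write_occurrence_matrix)
from .env_features import monthly_columns

logger = logging.getLogger(__name__)


@dataclass
class ScenarioConfig:
    """Knobs of the generator; defaults give a small, fast, realistic scenario."""

    grid_width: int = 40              # cells (= km)
    grid_height: int = 30
    n_ecoregions: int = 12
    n_lithology: int = 5
    n_endemic: int = 120
    n_nonendemic: int = 280
    elevation_sd: float = 250.0       # endemic elevation-window half-width (m)
    climate_sd: float = 1.5           # climate-niche breadth (°C)
    lithology_fidelity: float = 0.9   # presence probability in feasible ecoregions
    distance_decay: float = 0.05      # per km, nonendemic occupancy decay
    occupancy_baseline: float = 0.9   # nonendemic occupancy ceiling
    min_lith_frac: float = 0.05       # category availability threshold
    lith_patches_per_category: int = 3   # mosaic grain (more = finer patches)
    lapse_rate: float = 6.0           # °C per km of elevation
    temp_noise_sd: float = 0.4        # cell-month microclimate noise (°C)
    prec_noise_sd: float = 0.1        # lognormal sigma on precipitation
    seed: int = 0

    def __post_init__(self):
        for name in ("n_ecoregions", "n_lithology", "n_endemic", "n_nonendemic",
                     "grid_width", "grid_height"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("lithology_fidelity", "occupancy_baseline", "min_lith_frac"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        if self.n_ecoregions > self.grid_width * self.grid_height:
            raise ValidationError("more ecoregions than cells")


@dataclass
class GroundTruth:
    """What actually generated the data, for parameter-recovery checks."""

    endemic_driver: str        # geography | elevation | climate | lithology
    nonendemic_driver: str
    species_params: pd.DataFrame = field(default_factory=pd.DataFrame)


@dataclass
class Landscape:
    grid: pd.DataFrame            # x_km, y_km, ecoregion, elev_m
    monthly: pd.DataFrame         # per-cell monthly climate + elevation
    lith_surfaces: pd.DataFrame   # ecoregion x category, km2
    info: pd.DataFrame            # ecoregion metadata


def _block_partition(w: int, h: int, n: int) -> tuple[int, int]:
    """Rows x cols of the block layout, as square-ish as the aspect allows."""
    best = None
    for nr in range(1, n + 1):
        if n % nr:
            continue
        nc = n // nr
        score = abs(nr / nc - h / w)
        if best is None or score < best[0]:
            best = (score, nr, nc)
    return best[1], best[2]


def generate_landscape(cfg: ScenarioConfig) -> Landscape:
    """Generate the cell grid, per-cell monthly climate and lithology surfaces."""
    rng = np.random.default_rng(cfg.seed)
    w, h = cfg.grid_width, cfg.grid_height
    xs, ys = np.meshgrid(np.arange(w) + 0.5, np.arange(h) + 0.5)
    x = xs.ravel()
    y = ys.ravel()

    nr, nc = _block_partition(w, h, cfg.n_ecoregions)
    # irregular band widths so ecoregion areas differ (real ecoregions are
    # far from equal-area); Dirichlet keeps every band comfortably non-empty
    row_edges = np.cumsum(rng.dirichlet(np.full(nr, 8.0)))[:-1] * h
    col_edges = np.cumsum(rng.dirichlet(np.full(nc, 8.0)))[:-1] * w
    row_block = np.digitize(y, row_edges)
    col_block = np.digitize(x, col_edges)
    eco_idx = row_block * nc + col_block
    eco_ids = [f"eco{i + 1:02d}" for i in range(cfg.n_ecoregions)]
    ecoregion = np.array([eco_ids[i] for i in eco_idx], dtype=object)

    # ridge field: a few Gaussian peaks along the grid's midline
    n_peaks = 3
    px = rng.uniform(0.15 * w, 0.85 * w, n_peaks)
    py = rng.uniform(0.3 * h, 0.7 * h, n_peaks)
    amp = rng.uniform(1400, 2400, n_peaks)
    sig = rng.uniform(5.0, 9.0, n_peaks)
    elev = np.full(x.shape, 150.0)
    for k in range(n_peaks):
        elev += amp[k] * np.exp(-((x - px[k]) ** 2 + (y - py[k]) ** 2)
                                / (2 * sig[k] ** 2))
    elev += rng.normal(0, 40, size=elev.shape)
    elev = np.clip(elev, 0.0, None)

    months = np.arange(1, 13)
    season = np.cos(2 * np.pi * (months - 7) / 12)          # +1 in July
    tmean0 = 18.0 + 8.0 * season                            # sea-level cycle
    tmean = tmean0[None, :] - cfg.lapse_rate * elev[:, None] / 1000.0
    # cell-level microclimate noise keeps temperature from being an exact
    # affine function of elevation (aspect, cold-air pooling, ...)
    tmean = tmean + rng.normal(0, cfg.temp_noise_sd, size=tmean.shape)
    tmax = tmean + 6.0
    tmin = tmean - 6.0
    # wetter westward (low x), summer minimum
    pbase = 20.0 + 80.0 * (1.0 - x / w)
    pseason = 0.25 + 0.75 * (1.0 - season)                  # mean 1 over months
    prec = pbase[:, None] * pseason[None, :] \
        * np.exp(rng.normal(0, cfg.prec_noise_sd, size=(len(x), 12)))

    monthly = pd.DataFrame({"ecoregion": ecoregion, "elev_m": elev})
    for prefix, arr in (("tmean", tmean), ("tmax", tmax),
                        ("tmin", tmin), ("prec", prec)):
        for mi, col in enumerate(monthly_columns(prefix)):
            monthly[col] = arr[:, mi]

    # lithology mosaic: nearest-patch-center categories
    n_patches = cfg.lith_patches_per_category * cfg.n_lithology
    cx = rng.uniform(0, w, n_patches)
    cy = rng.uniform(0, h, n_patches)
    patch_cat = np.arange(n_patches) % cfg.n_lithology
    d2 = (x[:, None] - cx[None, :]) ** 2 + (y[:, None] - cy[None, :]) ** 2
    cell_cat = patch_cat[np.argmin(d2, axis=1)]
    cat_ids = [f"substrate{c + 1:02d}" for c in range(cfg.n_lithology)]
    surf = pd.crosstab(pd.Series(ecoregion, name="ecoregion"),
                       pd.Series([cat_ids[c] for c in cell_cat], name="category"))
    surf = surf.reindex(index=eco_ids, columns=cat_ids, fill_value=0).astype(float)

    grid = pd.DataFrame({"x_km": x, "y_km": y, "ecoregion": ecoregion,
                         "elev_m": elev})

    cent_x = grid.groupby("ecoregion")["x_km"].mean()
    info = pd.DataFrame({
        "name": eco_ids,
        "region": ["west" if cent_x[e] < w / 2 else "east" for e in eco_ids],
        "in_hotspot": True,
        "in_baetic": [cent_x[e] < w / 2 for e in eco_ids],
        "area_km2": grid.groupby("ecoregion").size().reindex(eco_ids).astype(float),
    }, index=pd.Index(eco_ids, name="id"))
    validate_ecoregion_info(info)

    return Landscape(grid=grid, monthly=monthly, lith_surfaces=surf, info=info)


def _logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def generate_flora(cfg: ScenarioConfig, landscape: Landscape,
                   max_retries: int = 10):
    """Generate the occurrence matrix and its ground truth.

    Returns ``(OccurrenceMatrix, GroundTruth)``. The flora-generation stream
    is seeded independently of the landscape stream (``cfg.seed + 1``) so a
    landscape can be reused across floras.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    grid = landscape.grid
    eco_ids = list(landscape.info.index)
    n_eco = len(eco_ids)

    mean_elev = grid.groupby("ecoregion")["elev_m"].mean().reindex(eco_ids)
    tmean_cols = monthly_columns("tmean")
    mean_T = (landscape.monthly.groupby("ecoregion")[tmean_cols].mean()
              .mean(axis=1).reindex(eco_ids))
    lith_frac = landscape.lith_surfaces.div(
        landscape.lith_surfaces.sum(axis=1), axis=0)
    cent = grid.groupby("ecoregion")[["x_km", "y_km"]].mean().reindex(eco_ids)
    cd = cent.to_numpy()
    centroid_dist = np.sqrt(((cd[:, None, :] - cd[None, :, :]) ** 2).sum(-1))

    rows, taxa, params = [], [], []

    # --- nonendemic element -------------------------------------------------
    T_lo, T_hi = float(mean_T.min()), float(mean_T.max())
    for i in range(cfg.n_nonendemic):
        opt = rng.uniform(T_lo, T_hi)
        origin = int(rng.integers(n_eco))
        match = (cfg.climate_sd - np.abs(mean_T.to_numpy() - opt)) \
            / (cfg.climate_sd / 2.0)
        p = cfg.occupancy_baseline * _logistic(match) \
            * np.exp(-cfg.distance_decay * centroid_dist[origin])
        present = rng.random(n_eco) < p
        present[origin] = True
        taxa.append(f"ne{i + 1:04d}")
        rows.append(present)
        params.append({"taxon": taxa[-1], "guild": "nonendemic",
                       "climate_optimum": opt, "origin": eco_ids[origin]})

    # --- endemic element ----------------------------------------------------
    cats = list(lith_frac.columns)
    elev_arr = mean_elev.to_numpy()
    kept = 0
    attempts_left = cfg.n_endemic * (max_retries + 1)
    while kept < cfg.n_endemic and attempts_left > 0:
        attempts_left -= 1
        center = float(elev_arr[rng.integers(n_eco)] + rng.normal(0, 50))
        cat = cats[int(rng.integers(len(cats)))]
        feasible = (np.abs(elev_arr - center) <= cfg.elevation_sd) \
            & (lith_frac[cat].to_numpy() >= cfg.min_lith_frac)
        if not feasible.any():
            continue
        present = feasible & (rng.random(n_eco) < cfg.lithology_fidelity)
        if not present.any():
            # fidelity missed everywhere: keep one feasible ecoregion
            keep_one = int(rng.choice(np.flatnonzero(feasible)))
            present = np.zeros(n_eco, dtype=bool)
            present[keep_one] = True
        kept += 1
        taxa.append(f"en{kept:04d}")
        rows.append(present)
        params.append({"taxon": taxa[-1], "guild": "endemic",
                       "elevation_center": center, "lithology_category": cat})
    if kept < cfg.n_endemic:
        logger.warning("only %d of %d endemics had feasible ecoregions",
                       kept, cfg.n_endemic)

    incidence = pd.DataFrame(np.array(rows, dtype=bool), index=taxa,
                             columns=eco_ids)
    flags = pd.Series(["nonendemic"] * cfg.n_nonendemic + ["endemic"] * kept,
                      index=taxa)
    in_baetic = landscape.info["in_baetic"].astype(bool)
    baetic_ids = set(in_baetic.index[in_baetic])
    rc = {}
    for t in taxa:
        if flags[t] != "endemic":
            continue
        occ_ids = set(incidence.columns[incidence.loc[t]])
        in_b = bool(occ_ids & baetic_ids)
        in_r = bool(occ_ids - baetic_ids)
        rc[t] = "both" if in_b and in_r else ("baetic_only" if in_b else "rifan_only")
    range_class = pd.Series(rc).reindex(taxa)

    occ = OccurrenceMatrix(incidence, flags, range_class).drop_empty_taxa()
    truth = GroundTruth(
        endemic_driver="lithology",
        nonendemic_driver="geography" if cfg.distance_decay > 0 else "climate",
        species_params=pd.DataFrame(params).set_index("taxon"),
    )
    return occ, truth


# ---------------------------------------------------------------------------
# Named scenarios used by tests and the worked examples
# ---------------------------------------------------------------------------

def lithology_endemic_scenario(seed: int = 0) -> ScenarioConfig:
    """Endemics strictly tied to a coarse lithology mosaic within elevation
    windows; nonendemics mildly structured. The high availability threshold
    makes endemic occupancy track lithological composition, so lithology (or
    elevation) should emerge as the endemic element's dominant unique
    contribution."""
    return ScenarioConfig(seed=seed, lithology_fidelity=1.0,
                          min_lith_frac=0.3, n_endemic=300, n_lithology=3,
                          lith_patches_per_category=6, elevation_sd=250.0,
                          distance_decay=0.02, temp_noise_sd=1.5)


def distance_decay_scenario(seed: int = 0) -> ScenarioConfig:
    """Nonendemic occupancy dominated by distance decay from the origin;
    broad climate niches. Geography should dominate the nonendemic element."""
    return ScenarioConfig(seed=seed, distance_decay=0.12, climate_sd=6.0,
                          occupancy_baseline=0.95)


def simulate(cfg: ScenarioConfig):
    """Generate landscape + flora in one call."""
    landscape = generate_landscape(cfg)
    occ, truth = generate_flora(cfg, landscape)
    return landscape, occ, truth


def write_scenario(cfg: ScenarioConfig, out_dir) -> dict:
    """Write the generated input files consumed by the I/O layer.

    Produces ``occurrence.tsv``, ``cells_monthly.tsv``,
    ``lithology_surfaces.tsv``, ``cell_grid.tsv`` and ``ecoregion_info.tsv``
    under ``out_dir``; returns the path map.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    landscape, occ, _ = simulate(cfg)
    paths = {
        "occurrence": out / "occurrence.tsv",
        "cells_monthly": out / "cells_monthly.tsv",
        "lithology_surfaces": out / "lithology_surfaces.tsv",
        "cell_grid": out / "cell_grid.tsv",
        "ecoregion_info": out / "ecoregion_info.tsv",
    }
    write_occurrence_matrix(occ, paths["occurrence"])
    landscape.monthly.to_csv(paths["cells_monthly"], sep="\t", index=False)
    landscape.lith_surfaces.to_csv(paths["lithology_surfaces"], sep="\t",
                                   index_label="ecoregion")
    write_cell_grid(landscape.grid, paths["cell_grid"])
    write_ecoregion_info(landscape.info, paths["ecoregion_info"])
    return {k: str(v) for k, v in paths.items()}
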