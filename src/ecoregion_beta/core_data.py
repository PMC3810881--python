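"""Data model and delimited-text I/O for ecoregion floristic datasets.

The analysis unit throughout the package is the *ecoregion*: a territory with
homogeneous climatic, topographic and geological features. Taxa are scored by
presence/absence per ecoregion; every taxon carries a range flag separating the
narrow *endemic* element (range restricted to the hotspot) from the *nonendemic*
element, and endemic taxa additionally carry a range class locating them in one
or both of the hotspot's two mountain systems.

All tabular I/O is plain delimited text (TSV by default) so that datasets and
every intermediate matrix remain diffable and portable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ENDEMIC = "endemic"
NONENDEMIC = "nonendemic"
RANGE_FLAGS = frozenset({ENDEMIC, NONENDEMIC})
RANGE_CLASSES = frozenset({"baetic_only", "rifan_only", "both"})

#: reserved metadata columns in an occurrence table (everything else is an ecoregion)
_META_COLUMNS = ("range_flag", "range_class", "excluded")


class ValidationError(ValueError):
    """A dataset violates a structural invariant."""


# ---------------------------------------------------------------------------
# Occurrence matrix
# ---------------------------------------------------------------------------

@dataclass
class OccurrenceMatrix:
    """Boolean taxon x ecoregion incidence with per-taxon range metadata.

    Parameters
    ----------
    incidence
        Boolean DataFrame, taxa as rows (index) and ecoregions as columns.
    range_flag
        Series indexed by taxon with values ``"endemic"`` / ``"nonendemic"``.
    range_class
        Optional Series indexed by (at least the endemic) taxa with values
        ``"baetic_only"`` / ``"rifan_only"`` / ``"both"``.
    """

    incidence: pd.DataFrame
    range_flag: pd.Series
    range_class: pd.Series | None = None

    def __post_init__(self) -> None:
        inc = self.incidence
        if inc.index.duplicated().any():
            dup = inc.index[inc.index.duplicated()][0]
            raise ValidationError(f"duplicate taxon identifier: {dup!r}")
        if inc.columns.duplicated().any():
            dup = inc.columns[inc.columns.duplicated()][0]
            raise ValidationError(f"duplicate ecoregion identifier: {dup!r}")
        if not all(dt == bool or dt == np.bool_ for dt in inc.dtypes):
            raise ValidationError("incidence must be strictly boolean")
        missing = inc.index.difference(self.range_flag.index)
        if len(missing):
            raise ValidationError(f"missing range_flag for taxon {missing[0]!r}")
        self.range_flag = self.range_flag.reindex(inc.index)
        bad = set(self.range_flag.unique()) - RANGE_FLAGS
        if bad:
            raise ValidationError(f"unknown range_flag value(s): {sorted(bad)}")
        if self.range_class is not None:
            self.range_class = self.range_class.reindex(inc.index)
            end = self.range_flag == ENDEMIC
            missing_rc = self.range_class[end].isna()
            if missing_rc.any():
                t = missing_rc.index[missing_rc][0]
                raise ValidationError(f"endemic taxon {t!r} has no range_class")
            vals = set(self.range_class.dropna().unique()) - RANGE_CLASSES
            if vals:
                raise ValidationError(f"unknown range_class value(s): {sorted(vals)}")

    # -- basic accessors ----------------------------------------------------
    @property
    def taxa(self) -> list:
        return list(self.incidence.index)

    @property
    def ecoregions(self) -> list:
        return list(self.incidence.columns)

    @property
    def n_taxa(self) -> int:
        return self.incidence.shape[0]

    @property
    def n_ecoregions(self) -> int:
        return self.incidence.shape[1]

    # -- manipulations ------------------------------------------------------
    def drop_empty_taxa(self) -> "OccurrenceMatrix":
        """Drop taxa with no presence anywhere, logging how many were removed.

        Taxa without occurrences are legal only in raw input; every analysis
        stage works on a matrix that has been through this step.
        """
        present = self.incidence.any(axis=1)
        n_drop = int((~present).sum())
        if n_drop:
            logger.warning("dropping %d taxa with zero presences", n_drop)
        return self._take_taxa(self.incidence.index[present])

    def subset_ecoregions(self, ids) -> "OccurrenceMatrix":
        """Restrict to the given ecoregions (order preserved), dropping taxa
        left without any presence."""
        ids = list(ids)
        unknown = [i for i in ids if i not in self.incidence.columns]
        if unknown:
            raise ValidationError(f"unknown ecoregion id: {unknown[0]!r}")
        sub = OccurrenceMatrix(self.incidence[ids], self.range_flag,
                               self.range_class)
        return sub.drop_empty_taxa()

    def _take_taxa(self, taxa) -> "OccurrenceMatrix":
        rc = self.range_class.loc[taxa] if self.range_class is not None else None
        return OccurrenceMatrix(self.incidence.loc[taxa], self.range_flag.loc[taxa], rc)


def read_occurrence_matrix(path, sep: str = "\t") -> OccurrenceMatrix:
    """Read a taxon x ecoregion occurrence table from delimited text.

    Layout: header row of ecoregion ids, one row per taxon (first column =
    taxon id), cells in {0,1}; metadata columns ``range_flag`` (required),
    ``range_class`` and ``excluded`` (optional). Rows with a truthy
    ``excluded`` value are dropped before validation (upstream curation flag);
    taxa with no presence anywhere are dropped with a logged warning.
    """
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise ValidationError(f"duplicate taxon identifier: {dup!r}")
    if "range_flag" not in raw.columns:
        raise ValidationError("occurrence table lacks a 'range_flag' column")

    if "excluded" in raw.columns:
        excl = raw["excluded"].fillna("0").isin(["1", "true", "True", "yes"])
        if excl.any():
            logger.info("dropping %d taxa flagged as excluded", int(excl.sum()))
        raw = raw.loc[~excl]

    eco_cols = [c for c in raw.columns if c not in _META_COLUMNS]
    cells = raw[eco_cols]
    bad = ~cells.isin(["0", "1"])
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"non-binary cell at taxon {cells.index[r]!r}, ecoregion {eco_cols[c]!r}: "
            f"{cells.iloc[r, c]!r}")
    incidence = cells.astype(int).astype(bool)

    rc = raw["range_class"] if "range_class" in raw.columns else None
    occ = OccurrenceMatrix(incidence, raw["range_flag"], rc)
    return occ.drop_empty_taxa()


def write_occurrence_matrix(occ: OccurrenceMatrix, path, sep: str = "\t") -> None:
    out = occ.incidence.astype(int).copy()
    out["range_flag"] = occ.range_flag
    if occ.range_class is not None:
        out["range_class"] = occ.range_class
    out.to_csv(path, sep=sep, index_label="taxon")


# ---------------------------------------------------------------------------
# Ecoregion metadata and cell grid
# ---------------------------------------------------------------------------

ECOREGION_INFO_COLUMNS = ["id", "name", "region", "in_hotspot", "in_baetic", "area_km2"]
CELL_GRID_COLUMNS = ["x_km", "y_km", "ecoregion", "elev_m"]


def validate_ecoregion_info(info: pd.DataFrame) -> pd.DataFrame:
    """Validate an ecoregion metadata table (indexed by ecoregion id)."""
    for col in ("name", "region", "in_hotspot", "in_baetic", "area_km2"):
        if col not in info.columns:
            raise ValidationError(f"ecoregion info lacks column {col!r}")
    if info.index.duplicated().any():
        raise ValidationError("duplicate ecoregion id in info table")
    if (info["area_km2"] <= 0).any():
        bad = info.index[info["area_km2"] <= 0][0]
        raise ValidationError(f"ecoregion {bad!r} has non-positive area")
    violat = info["in_baetic"].astype(bool) & ~info["in_hotspot"].astype(bool)
    if violat.any():
        bad = info.index[violat][0]
        raise ValidationError(f"ecoregion {bad!r} is in_baetic but not in_hotspot")
    return info


def read_ecoregion_info(path, sep: str = "\t") -> pd.DataFrame:
    info = pd.read_csv(path, sep=sep, index_col="id")
    info["in_hotspot"] = info["in_hotspot"].astype(bool)
    info["in_baetic"] = info["in_baetic"].astype(bool)
    return validate_ecoregion_info(info)


def write_ecoregion_info(info: pd.DataFrame, path, sep: str = "\t") -> None:
    out = info.copy()
    out["in_hotspot"] = out["in_hotspot"].astype(int)
    out["in_baetic"] = out["in_baetic"].astype(int)
    out.to_csv(path, sep=sep, index_label="id")


def read_cell_grid(path, sep: str = "\t") -> pd.DataFrame:
    """Read a cell-grid table (1-km2 cell centers with ecoregion membership)."""
    grid = pd.read_csv(path, sep=sep)
    missing = [c for c in CELL_GRID_COLUMNS if c not in grid.columns]
    if missing:
        raise ValidationError(f"cell grid lacks column(s) {missing}")
    return grid


def write_cell_grid(grid: pd.DataFrame, path, sep: str = "\t") -> None:
    grid[CELL_GRID_COLUMNS].to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Distance matrix — the universal currency between stages
# ---------------------------------------------------------------------------

class DistanceMatrix:
    """Labeled symmetric zero-diagonal matrix of non-negative dissimilarities."""

    __slots__ = ("labels", "values")

    def __init__(self, values, labels):
        values = np.asarray(values, dtype=float)
        labels = list(labels)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValidationError("distance matrix must be square")
        if values.shape[0] != len(labels):
            raise ValidationError("dimension/label mismatch")
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate labels in distance matrix")
        if np.isnan(values).any():
            raise ValidationError("NaN in distance matrix")
        if not np.allclose(values, values.T, atol=1e-12, rtol=0):
            raise ValidationError("distance matrix not symmetric within 1e-12")
        if not np.allclose(np.diag(values), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal not zero")
        if (values < -1e-12).any():
            raise ValidationError("negative distance")
        values = (values + values.T) / 2.0
        np.fill_diagonal(values, 0.0)
        self.values = np.clip(values, 0.0, None)
        self.labels = labels

    # -- construction helpers -----------------------------------------------
    @classmethod
    def from_condensed(cls, condensed, labels) -> "DistanceMatrix":
        from scipy.spatial.distance import squareform
        return cls(squareform(np.asarray(condensed, dtype=float)), labels)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DistanceMatrix":
        if list(frame.index) != list(frame.columns):
            raise ValidationError("row/column labels differ")
        return cls(frame.to_numpy(dtype=float), list(frame.index))

    # -- views --------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def condensed(self) -> np.ndarray:
        """Strictly-upper-triangle entries in row-major (pdist) order."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def subset(self, labels) -> "DistanceMatrix":
        labels = list(labels)
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(self.values[np.ix_(idx, idx)], labels)

    def __len__(self) -> int:
        return len(self.labels)

    def __repr__(self) -> str:
        return f"DistanceMatrix(n={len(self.labels)})"


def read_distance_matrix(path, sep: str = "\t") -> DistanceMatrix:
    return DistanceMatrix.from_frame(pd.read_csv(path, sep=sep, index_col=0))


def write_distance_matrix(dm: DistanceMatrix, path, sep: str = "\t") -> None:
    dm.to_frame().to_csv(path, sep=sep, index_label="")


# ---------------------------------------------------------------------------
# Dataset manipulations
# ---------------------------------------------------------------------------

def merge_ecoregions(occ: OccurrenceMatrix, ids, new_id,
                     info: pd.DataFrame | None = None,
                     grid: pd.DataFrame | None = None):
    """Merge ecoregions into one: incidence ORs, areas sum, cells relabel.

    Merging a single id acts as a rename. Returns the merged occurrence
    matrix, or a ``(occ, info, grid)`` tuple when metadata tables are given.
    """
    ids = list(ids)
    if not ids:
        raise ValidationError("no ecoregion ids to merge")
    for i in ids:
        if i not in occ.incidence.columns:
            raise ValidationError(f"unknown ecoregion id: {i!r}")
    remaining = [c for c in occ.incidence.columns if c not in ids]
    if new_id in remaining:
        raise ValidationError(f"target id {new_id!r} already present")

    merged_col = occ.incidence[ids].any(axis=1)
    pos = list(occ.incidence.columns).index(ids[0])
    cols = list(occ.incidence.columns)
    keep = [c for c in cols if c not in ids]
    inc = occ.incidence[keep].copy()
    inc.insert(min(pos, len(keep)), new_id, merged_col)
    out = OccurrenceMatrix(inc, occ.range_flag, occ.range_class)

    if info is None and grid is None:
        return out

    new_info = None
    if info is not None:
        new_info = info.drop(index=ids)
        rows = info.loc[ids]
        merged_row = {
            "name": "+".join(str(n) for n in rows["name"]),
            "region": rows["region"].iloc[0],
            "in_hotspot": bool(rows["in_hotspot"].any()),
            "in_baetic": bool(rows["in_baetic"].any()),
            "area_km2": float(rows["area_km2"].sum()),
        }
        new_info = pd.concat([new_info,
                              pd.DataFrame([merged_row], index=[new_id])])
        new_info = validate_ecoregion_info(new_info)

    new_grid = None
    if grid is not None:
        new_grid = grid.copy()
        new_grid.loc[new_grid["ecoregion"].isin(ids), "ecoregion"] = new_id

    return out, new_info, new_grid


def split_by_endemism(occ: OccurrenceMatrix):
    """Partition into the (endemic, nonendemic) floristic elements.

    The partition is exhaustive and disjoint; ecoregion order is preserved in
    both outputs.
    """
    if occ.range_flag.isna().any():
        t = occ.range_flag.index[occ.range_flag.isna()][0]
        raise ValidationError(f"taxon {t!r} has no range_flag")
    end_mask = occ.range_flag == ENDEMIC
    endemic = occ._take_taxa(occ.incidence.index[end_mask])
    nonendemic = occ._take_taxa(occ.incidence.index[~end_mask])
    return endemic, nonendemic


def filter_high_elevation(grid: pd.DataFrame, upper_m: float = 1500.0,
                          lower_m: float = 500.0, min_frac_above: float = 0.05,
                          max_frac_below: float = 0.5,
                          ecoregions=None) -> list:
    """Ecoregion ids retaining a high-elevation character.

    An ecoregion is retained when the fraction of its cells above ``upper_m``
    is at least ``min_frac_above`` AND the fraction below ``lower_m`` is at
    most ``max_frac_below``. Defaults quantify "a significant fraction over
    1500 m" as >=5% and "most of the surface below 500 m" as >50%.
    """
    if upper_m <= 0 or lower_m <= 0:
        raise ValidationError("elevation thresholds must be positive")
    for f in (min_frac_above, max_frac_below):
        if not 0.0 <= f <= 1.0:
            raise ValidationError("fractions must lie in [0, 1]")
    if ecoregions is not None:
        missing = set(ecoregions) - set(grid["ecoregion"].unique())
        if missing:
            raise ValidationError(f"ecoregion {sorted(missing)[0]!r} has no cells")
    retained = []
    for eco, cells in grid.groupby("ecoregion", sort=False):
        if ecoregions is not None and eco not in set(ecoregions):
            continue
        elev = cells["elev_m"].to_numpy()
        frac_above = float((elev > upper_m).mean())
        frac_below = float((elev < lower_m).mean())
        if frac_above >= min_frac_above and frac_below <= max_frac_below:
            retained.append(eco)
    return retained


@dataclass
class PoolSummary:
    """Counts and percentages describing a regional species pool."""

    total_taxa: int
    hotspot_taxa: int
    hotspot_percent: int              # nearest integer
    endemic_taxa: int
    endemic_percent: float            # of hotspot pool, one decimal
    nonendemic_taxa: int
    range_class_counts: dict = field(default_factory=dict)


def summarize_pool(occ: OccurrenceMatrix, info: pd.DataFrame) -> PoolSummary:
    """Summarize the pool: hotspot membership, endemism rates, range classes.

    ``hotspot_taxa`` counts taxa present in at least one ecoregion flagged
    ``in_hotspot``; endemism counts and range-class tallies refer to that
    hotspot pool.
    """
    validate_ecoregion_info(info)
    hotspot_ids = [e for e in occ.ecoregions if bool(info.loc[e, "in_hotspot"])]
    in_hot = occ.incidence[hotspot_ids].any(axis=1)
    hotspot_pool = occ.incidence.index[in_hot]
    flags = occ.range_flag.loc[hotspot_pool]
    n_end = int((flags == ENDEMIC).sum())
    n_non = int((flags == NONENDEMIC).sum())
    n_hot = len(hotspot_pool)
    rc_counts: dict = {}
    if occ.range_class is not None:
        endemic_pool = hotspot_pool[flags == ENDEMIC]
        rc_counts = occ.range_class.loc[endemic_pool].dropna() \
            .value_counts().to_dict()
    return PoolSummary(
        total_taxa=occ.n_taxa,
        hotspot_taxa=n_hot,
        hotspot_percent=int(round(100.0 * n_hot / occ.n_taxa)),
        endemic_taxa=n_end,
        endemic_percent=round(100.0 * n_end / n_hot, 1) if n_hot else 0.0,
        nonendemic_taxa=n_non,
        range_class_counts=rc_counts,
    )
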