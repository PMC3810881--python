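"""Distance-matrix construction: floristic, lithological, climatic, geographic.

Four kinds of pairwise ecoregion distances feed the downstream analyses:

* **Sørensen dissimilarity** ``1 - 2a/(2a+b+c)`` on presence/absence
  assemblages (``a`` shared taxa, ``b``/``c`` taxa unique to either side);
* **Bray–Curtis dissimilarity** on lithology surface-fraction compositions;
* **standardized Euclidean distance** on a chosen subset of environmental
  variables (each variable z-scored over the ecoregions in the analysis);
* **geographic distance**: the mean planar Euclidean distance over all
  cross pairs of 1-km2 cells of the two ecoregions (irregular ecoregion
  shapes make single centroid locations misleading).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .core_data import DistanceMatrix, OccurrenceMatrix, ValidationError


def sorensen_matrix(occ: OccurrenceMatrix) -> DistanceMatrix:
    """Pairwise Sørensen dissimilarity between ecoregion assemblages."""
    counts = occ.incidence.sum(axis=0)
    empty = counts.index[counts == 0]
    if len(empty):
        raise ValidationError(f"ecoregion {empty[0]!r} has an empty assemblage")
    X = occ.incidence.to_numpy().T  # ecoregions x taxa
    # scipy's 'dice' dissimilarity is exactly (b+c)/(2a+b+c)
    return DistanceMatrix.from_condensed(pdist(X, metric="dice"), occ.ecoregions)


def braycurtis_matrix(tab) -> DistanceMatrix:
    """Pairwise Bray–Curtis dissimilarity between composition rows.

    Rows must be non-negative and sum to 1 (see ``build_lithology_table``).
    """
    X = tab.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValidationError("negative composition fraction")
    if not np.allclose(X.sum(axis=1), 1.0, atol=1e-9):
        raise ValidationError("composition rows must sum to 1")
    return DistanceMatrix.from_condensed(pdist(X, metric="braycurtis"),
                                         list(tab.index))


def euclidean_env_matrix(env, subset) -> DistanceMatrix:
    """Euclidean distance on z-scored environmental variables.

    Each variable in ``subset`` is standardized to zero mean and unit SD
    (n-1 denominator) across exactly the ecoregions present in ``env`` —
    analyses on different ecoregion subsets therefore standardize separately.
    """
    subset = [str(c) for c in subset]
    if not subset:
        raise ValidationError("empty variable subset")
    missing = [c for c in subset if c not in env.columns]
    if missing:
        raise ValidationError(f"unknown variable code(s): {missing}")
    X = env[subset].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValidationError(f"zero-variance variable in subset: {subset[zero[0]]!r}")
    Z = (X - X.mean(axis=0)) / sd
    return DistanceMatrix.from_condensed(pdist(Z, metric="euclidean"),
                                         list(env.index))


@dataclass
class GeoDistanceOptions:
    """Options for the cell-pair geographic distance.

    ``method='subsample'`` draws a seeded without-replacement subset of up to
    ``subsample_size`` cells per ecoregion before enumerating cross pairs; a
    subsample at least as large as every ecoregion reproduces the exact mode.
    """

    method: str = "exact"           # 'exact' | 'subsample'
    subsample_size: int = 500
    seed: int | None = None
    statistic: str = "mean"         # 'mean' | 'median'

    def __post_init__(self):
        if self.method not in ("exact", "subsample"):
            raise ValidationError(f"unknown method {self.method!r}")
        if self.statistic not in ("mean", "median"):
            raise ValidationError(f"unknown statistic {self.statistic!r}")
        if self.method == "subsample" and self.subsample_size < 1:
            raise ValidationError("subsample size must be >= 1")


def geographic_distance_matrix(grid, opts: GeoDistanceOptions | None = None,
                               ecoregions=None) -> DistanceMatrix:
    """Mean (or median) cell-pair Euclidean distance between ecoregions.

    For each ecoregion pair the planar distances between all cross pairs of
    cell centers form an empirical distribution; its mean is the geographic
    distance. The diagonal is fixed at 0 and never used downstream.
    """
    opts = opts or GeoDistanceOptions()
    if ecoregions is None:
        ecoregions = list(dict.fromkeys(grid["ecoregion"]))
    coords = {}
    rng = np.random.default_rng(opts.seed)
    for eco in ecoregions:
        pts = grid.loc[grid["ecoregion"] == eco, ["x_km", "y_km"]].to_numpy(float)
        if pts.shape[0] == 0:
            raise ValidationError(f"ecoregion {eco!r} has no cells")
        if opts.method == "subsample" and pts.shape[0] > opts.subsample_size:
            idx = rng.choice(pts.shape[0], size=opts.subsample_size, replace=False)
            pts = pts[np.sort(idx)]
        coords[eco] = pts
    n = len(ecoregions)
    out = np.zeros((n, n))
    stat = np.mean if opts.statistic == "mean" else np.median
    for i in range(n):
        for j in range(i + 1, n):
            d = cdist(coords[ecoregions[i]], coords[ecoregions[j]])
            out[i, j] = out[j, i] = float(stat(d))
    return DistanceMatrix(out, ecoregions)
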