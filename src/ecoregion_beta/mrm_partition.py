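"""Multiple regression on distance matrices, variance partitioning, and
alpha-diversity linear models.

MRM unfolds the strictly-upper triangles of the response and predictor
distance matrices into vectors and fits ordinary least squares. Because the
pairwise entries are not independent, no parametric p-values are reported:
significance comes from a matrix permutation test — the response matrix's
rows and columns are permuted by a common random relabeling, re-unfolded and
refit; the two-sided coefficient p-value is ``(#{|b_perm| >= |b_obs|} + 1) /
(nperm + 1)`` and the model R² is tested one-sided the same way.

The explained variance is decomposed into *unique* (semi-partial)
contributions — full-model R² minus the leave-one-out model's R² — a single
*joint* covariation term absorbing everything shared, and the *unexplained*
remainder ``1 - R²``; the three always sum to one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import statsmodels.api as sm
from scipy.spatial.distance import pdist

from .core_data import DistanceMatrix, OccurrenceMatrix, ValidationError
from .dissimilarity import sorensen_matrix

logger = logging.getLogger(__name__)

_COND_LIMIT = 1e8


# ---------------------------------------------------------------------------
# Alpha-diversity linear models
# ---------------------------------------------------------------------------

@dataclass
class LMResult:
    slope: float
    intercept: float
    r2: float
    adj_r2: float
    p_value: float
    n: int


def alpha_regression(alpha, x) -> LMResult:
    """OLS of per-ecoregion richness on a single predictor.

    Adjusted R² follows ``1 - (1 - R²)(n - 1)/(n - p - 1)`` and may be
    negative for uninformative predictors.
    """
    y = np.asarray(alpha, dtype=float)
    xv = np.asarray(x, dtype=float)
    if y.shape != xv.shape or y.ndim != 1:
        raise ValidationError("alpha and predictor must be equal-length vectors")
    if len(y) < 4:
        raise ValidationError("need at least 4 ecoregions")
    if np.ptp(xv) == 0:
        raise ValidationError("constant predictor")
    res = sm.OLS(y, sm.add_constant(xv)).fit()
    return LMResult(slope=float(res.params[1]), intercept=float(res.params[0]),
                    r2=float(res.rsquared), adj_r2=float(res.rsquared_adj),
                    p_value=float(res.f_pvalue), n=len(y))


# ---------------------------------------------------------------------------
# MRM core
# ---------------------------------------------------------------------------

@dataclass
class MRMResult:
    coefficients: dict            # name -> coefficient
    coef_p: dict                  # name -> permutation p-value
    intercept: float
    r2: float
    r2_p: float
    nperm: int
    seed: int | None
    n_labels: int


@dataclass
class PartitionResult:
    """R² decomposition: per-predictor unique, joint covariation, unexplained."""

    unique: dict
    joint: float
    unexplained: float
    r2_full: float
    leave_one_out_r2: dict = field(default_factory=dict)

    def components_sum(self) -> float:
        return sum(self.unique.values()) + self.joint + self.unexplained

    def unique_shares(self) -> dict:
        """Unique contributions rescaled as shares of their own total."""
        tot = sum(self.unique.values())
        if tot <= 0:
            return {k: float("nan") for k in self.unique}
        return {k: v / tot for k, v in self.unique.items()}


def _aligned_vectors(response: DistanceMatrix, predictors):
    """Unfold response and predictors to vectors on the response label order."""
    names, mats = zip(*predictors.items()) if isinstance(predictors, dict) \
        else zip(*predictors)
    labels = response.labels
    for name, m in zip(names, mats):
        if set(m.labels) != set(labels):
            raise ValidationError(f"predictor {name!r} labels do not match response")
    y = response.condensed()
    cols = []
    for name, m in zip(names, mats):
        v = m.subset(labels).condensed()
        if np.ptp(v) == 0:
            raise ValidationError(f"zero-variance predictor matrix: {name!r}")
        cols.append(v)
    X = np.column_stack(cols)
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    if len(names) > 1 and np.linalg.cond(Z) > _COND_LIMIT:
        raise ValidationError("collinear predictor matrices (condition number guard)")
    return y, X, list(names)


def _ols_r2(y: np.ndarray, X: np.ndarray):
    Xd = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ beta
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / sst if sst > 0 else 0.0
    return beta, r2


def mrm(response: DistanceMatrix, predictors, nperm: int = 999,
        seed: int | None = None) -> MRMResult:
    """Multiple regression on distance matrices with permutation inference."""
    if nperm < 99:
        raise ValidationError("need at least 99 permutations")
    y, X, names = _aligned_vectors(response, predictors)
    beta, r2 = _ols_r2(y, X)

    n = len(response.labels)
    iu = np.triu_indices(n, k=1)
    V = response.values
    rng = np.random.default_rng(seed)
    Y = np.empty((nperm, len(y)))
    for b in range(nperm):
        p = rng.permutation(n)
        Y[b] = V[np.ix_(p, p)][iu]

    Xd = np.column_stack([np.ones(len(y)), X])
    pinv = np.linalg.pinv(Xd)
    B = Y @ pinv.T                           # nperm x (k+1)
    fitted = B @ Xd.T
    sse = ((Y - fitted) ** 2).sum(axis=1)
    sst = float(((y - y.mean()) ** 2).sum())  # invariant under permutation
    r2_perm = 1.0 - sse / sst

    coef_p = {}
    for j, name in enumerate(names):
        exceed = int((np.abs(B[:, j + 1]) >= abs(beta[j + 1]) - 1e-12).sum())
        coef_p[name] = (exceed + 1) / (nperm + 1)
    r2_p = (int((r2_perm >= r2 - 1e-12).sum()) + 1) / (nperm + 1)

    return MRMResult(coefficients={n_: float(beta[j + 1]) for j, n_ in enumerate(names)},
                     coef_p=coef_p, intercept=float(beta[0]), r2=r2,
                     r2_p=r2_p, nperm=nperm, seed=seed, n_labels=n)


def variance_partition(response: DistanceMatrix, predictors) -> PartitionResult:
    """Decompose MRM R² into unique, joint and unexplained components."""
    y, X, names = _aligned_vectors(response, predictors)
    _, r2_full = _ols_r2(y, X)
    unique, loo = {}, {}
    for j, name in enumerate(names):
        keep = [k for k in range(len(names)) if k != j]
        if keep:
            _, r2_wo = _ols_r2(y, X[:, keep])
        else:
            r2_wo = 0.0
        loo[name] = r2_wo
        unique[name] = r2_full - r2_wo
    joint = r2_full - sum(unique.values())
    return PartitionResult(unique=unique, joint=joint,
                           unexplained=1.0 - r2_full, r2_full=r2_full,
                           leave_one_out_r2=loo)


def commonality(response: DistanceMatrix, predictors) -> dict:
    """All-subsets R² table (commonality analysis raw material)."""
    y, X, names = _aligned_vectors(response, predictors)
    out = {}
    for k in range(1, len(names) + 1):
        for combo in combinations(range(len(names)), k):
            _, r2 = _ols_r2(y, X[:, list(combo)])
            out[tuple(names[j] for j in combo)] = r2
    return out


# ---------------------------------------------------------------------------
# Taxon-resampling robustness
# ---------------------------------------------------------------------------

@dataclass
class ResamplingSummary:
    mean_adj_r2: float
    sd_adj_r2: float
    mean_p: float
    n_iterations: int
    n_discarded: int
    k: int


def _adj_r2(r2: float, n: int, p: int) -> float:
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def resampling_robustness(pool: OccurrenceMatrix, k: int, n_iter: int = 100,
                          nperm: int = 199, seed: int | None = None) -> ResamplingSummary:
    """Does assemblage structure survive resampling to a smaller taxon pool?

    Each iteration draws ``k`` taxa with replacement, rebuilds the Sørensen
    matrix of the resampled assemblage (ecoregions emptied by the draw are
    dropped for that iteration) and regresses it on the original pool matrix
    restricted to the shared ecoregions; iterations with fewer than three
    surviving ecoregions are discarded and counted.
    """
    if n_iter < 2:
        raise ValidationError("need at least 2 iterations")
    rng = np.random.default_rng(seed)
    D0 = sorensen_matrix(pool)
    inc = pool.incidence.to_numpy()
    cols = np.array(pool.ecoregions, dtype=object)
    adj, pvals, discarded = [], [], 0
    for _ in range(n_iter):
        idx = rng.integers(0, pool.n_taxa, size=k)
        sub = inc[idx]
        keep = np.flatnonzero(sub.any(axis=0))
        if keep.size < 3:
            discarded += 1
            continue
        labels = list(cols[keep])
        Di = DistanceMatrix.from_condensed(pdist(sub[:, keep].T, "dice"), labels)
        res = mrm(Di, [("pool", D0.subset(labels))], nperm=nperm,
                  seed=int(rng.integers(0, 2 ** 31)))
        npairs = len(Di.condensed())
        adj.append(_adj_r2(res.r2, npairs, 1))
        pvals.append(res.coef_p["pool"])
    if not adj:
        raise ValidationError("every resampling iteration was discarded")
    return ResamplingSummary(mean_adj_r2=float(np.mean(adj)),
                             sd_adj_r2=float(np.std(adj, ddof=1)),
                             mean_p=float(np.mean(pvals)),
                             n_iterations=len(adj), n_discarded=discarded, k=k)


# ---------------------------------------------------------------------------
# End-to-end beta-diversity analysis for one set of ecoregions
# ---------------------------------------------------------------------------

@dataclass
class BetaAnalysisResult:
    """Per floristic element: BIO-ENV selections, MRM fit and partition."""

    element: str
    bioenv_climatic: object
    bioenv_altitudinal: object
    mrm: MRMResult
    partition: PartitionResult


def run_beta_analysis(occ: OccurrenceMatrix, env, grid, lith=None, *,
                      climatic_codes=None, altitudinal_codes=None,
                      max_k: int | None = 4, nperm: int = 999,
                      seed: int | None = None, geo_opts=None) -> dict:
    """Full beta-diversity correlate analysis per floristic element.

    For each of the endemic and nonendemic elements: Sørensen matrix ->
    BIO-ENV selection of climatic and altitudinal variable subsets ->
    standardized Euclidean matrices on the winners -> geographic (and
    optionally lithological) distances -> MRM + variance partition.
    """
    from .bioenv import bioenv_search
    from .dissimilarity import euclidean_env_matrix, braycurtis_matrix, \
        geographic_distance_matrix
    from .core_data import split_by_endemism
    from .env_features import CLIMATIC_CODES, ALTITUDINAL_CODES

    climatic_codes = climatic_codes or CLIMATIC_CODES
    altitudinal_codes = altitudinal_codes or ALTITUDINAL_CODES
    env = env.loc[occ.ecoregions]
    geo = geographic_distance_matrix(grid, geo_opts, ecoregions=occ.ecoregions)
    lith_dm = None
    if lith is not None:
        lith_dm = braycurtis_matrix(lith.loc[occ.ecoregions])

    results = {}
    rng = np.random.default_rng(seed)
    for element, sub in zip(("endemic", "nonendemic"), split_by_endemism(occ)):
        if sub.n_taxa == 0:
            logger.warning("element %r is empty; skipped", element)
            continue
        occupied = [e for e in sub.ecoregions if sub.incidence[e].any()]
        if len(occupied) < 4:
            logger.warning("element %r occupies only %d ecoregions; skipped",
                           element, len(occupied))
            continue
        if len(occupied) < len(sub.ecoregions):
            logger.warning("element %r: %d ecoregions hold none of its taxa "
                           "and are dropped for this element", element,
                           len(sub.ecoregions) - len(occupied))
            sub = sub.subset_ecoregions(occupied)
        env_el = env.loc[occupied]
        community = sorensen_matrix(sub)
        be_clim = bioenv_search(community, env_el, climatic_codes, max_k=max_k)
        be_alt = bioenv_search(community, env_el, altitudinal_codes, max_k=max_k)
        predictors = [
            ("climatic", euclidean_env_matrix(env_el, be_clim.best_subset)),
            ("altitudinal", euclidean_env_matrix(env_el, be_alt.best_subset)),
            ("geographic", geo.subset(occupied)),
        ]
        if lith_dm is not None:
            predictors.append(("lithological", lith_dm.subset(occupied)))
        stage_seed = int(rng.integers(0, 2 ** 31))
        fit = mrm(community, predictors, nperm=nperm, seed=stage_seed)
        part = variance_partition(community, predictors)
        logger.info("element %s: BIO-ENV climatic=%s altitudinal=%s seed=%d",
                    element, be_clim.best_subset, be_alt.best_subset, stage_seed)
        results[element] = BetaAnalysisResult(
            element=element, bioenv_climatic=be_clim, bioenv_altitudinal=be_alt,
            mrm=fit, partition=part)
    return results
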