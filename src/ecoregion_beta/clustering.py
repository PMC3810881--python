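"""UPGMA dendrograms with multiscale-bootstrap AU support.

UPGMA repeatedly merges the pair of clusters with the minimal average
inter-cluster distance, yielding an ultrametric rooted tree whose node height
is the merge distance. Cluster support is assessed by multiscale bootstrap:
the taxon rows are resampled with replacement at several sample-size scales
``r`` (``round(r * T)`` taxa), the tree is rebuilt per replicate, and each
reference cluster's per-scale recovery frequency ``BP_r`` is recorded. From a
weighted least-squares fit of ``z_r = Phi^-1(1 - BP_r)`` to the signed
distance / curvature model ``z_r = v*sqrt(r) + c/sqrt(r)`` one obtains the
approximately unbiased p-value ``AU = 1 - Phi(v - c)`` and the fitted
ordinary bootstrap probability ``BP = 1 - Phi(v + c)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist
from scipy.stats import norm

from .core_data import DistanceMatrix, OccurrenceMatrix, ValidationError
from .dissimilarity import sorensen_matrix

logger = logging.getLogger(__name__)

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.45, 0.1), 2))


@dataclass
class DendroNode:
    """A node of a rooted binary merge tree."""

    leaves: frozenset
    height: float = 0.0
    left: "DendroNode | None" = None
    right: "DendroNode | None" = None
    bp: float | None = None       # bootstrap probability at scale 1 (fitted)
    au: float | None = None       # approximately unbiased p-value
    au_fallback: bool = False     # True when AU could not be fit and equals BP
    signed_distance: float | None = None   # fitted v
    curvature: float | None = None         # fitted c

    @property
    def is_leaf(self) -> bool:
        return self.left is None


@dataclass
class Dendrogram:
    """UPGMA merge tree over ecoregion leaves."""

    root: DendroNode
    leaf_names: list = field(default_factory=list)

    def internal_nodes(self) -> list[DendroNode]:
        out = []

        def walk(node):
            if not node.is_leaf:
                out.append(node)
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return out

    def clusters(self) -> set[frozenset]:
        """Leaf sets of all internal nodes (including the root)."""
        return {n.leaves for n in self.internal_nodes()}

    def cophenetic_matrix(self) -> DistanceMatrix:
        names = sorted(self.leaf_names)
        idx = {n: i for i, n in enumerate(names)}
        out = np.zeros((len(names), len(names)))

        def walk(node):
            if node.is_leaf:
                return
            for a in node.left.leaves:
                for b in node.right.leaves:
                    out[idx[a], idx[b]] = out[idx[b], idx[a]] = node.height
            walk(node.left)
            walk(node.right)

        walk(self.root)
        return DistanceMatrix(out, names)

    def to_newick(self, support: str = "au_bp") -> str:
        """Newick string; internal node labels are 'AU|BP' in percent."""

        def label(node):
            if support == "au_bp" and node.au is not None:
                return f"{100 * node.au:.0f}|{100 * node.bp:.0f}"
            return ""

        def walk(node):
            if node.is_leaf:
                return str(next(iter(node.leaves)))
            return (f"({walk(node.left)},{walk(node.right)})"
                    f"{label(node)}:{node.height:.6g}")

        return walk(self.root) + ";"


def upgma(D: DistanceMatrix) -> Dendrogram:
    """Average-linkage agglomerative clustering of a distance matrix.

    Ties in the minimal average distance break toward the lexicographically
    smallest pair of cluster representatives (a cluster is represented by its
    smallest leaf label), making the topology fully deterministic.
    """
    if len(D) < 2:
        raise ValidationError("need at least two labels to cluster")
    if np.isnan(D.values).any():
        raise ValidationError("NaN in distance matrix")

    nodes = {lab: DendroNode(leaves=frozenset([lab])) for lab in D.labels}
    sizes = {lab: 1 for lab in D.labels}
    reps = {lab: lab for lab in D.labels}  # representative = min leaf label
    dist = {}
    labs = list(D.labels)
    for i in range(len(labs)):
        for j in range(i + 1, len(labs)):
            dist[frozenset((labs[i], labs[j]))] = D.values[i, j]

    active = set(labs)
    counter = 0
    while len(active) > 1:
        best = None
        for key, d in dist.items():
            a, b = sorted(key, key=lambda k: str(reps[k]))
            cand = (d, str(reps[a]), str(reps[b]))
            if best is None or cand < best[0]:
                best = (cand, a, b)
        (d, _, _), a, b = best
        counter += 1
        new_key = f"@{counter}"
        merged = DendroNode(leaves=nodes[a].leaves | nodes[b].leaves,
                            height=float(d), left=nodes[a], right=nodes[b])
        na, nb = sizes[a], sizes[b]
        for other in list(active - {a, b}):
            da = dist.pop(frozenset((a, other)))
            db = dist.pop(frozenset((b, other)))
            dist[frozenset((new_key, other))] = (na * da + nb * db) / (na + nb)
        dist.pop(frozenset((a, b)))
        for k in (a, b):
            active.remove(k)
            del nodes[k], sizes[k], reps[k]
        active.add(new_key)
        nodes[new_key] = merged
        sizes[new_key] = na + nb
        reps[new_key] = min(merged.leaves, key=str)

    root = nodes[active.pop()]
    return Dendrogram(root=root, leaf_names=list(D.labels))


# ---------------------------------------------------------------------------
# Multiscale bootstrap
# ---------------------------------------------------------------------------

def _fit_au(scales: np.ndarray, counts: np.ndarray, B: int):
    """Fit the signed-distance/curvature model to per-scale recovery counts.

    Returns ``(au, bp_fit, fallback)``. Counts are clipped to [0.5, B-0.5]
    before the probit transform; edges whose counts are clipped at every
    scale carry no information for the two-parameter fit and fall back to
    AU = BP (the clipped scale-1 proportion), flagged.
    """
    counts = np.asarray(counts, dtype=float)
    all_clipped = bool(((counts <= 0) | (counts >= B)).all())
    clipped = np.clip(counts, 0.5, B - 0.5)
    bp_r = clipped / B

    i1 = int(np.argmin(np.abs(scales - 1.0)))
    bp_obs = float(bp_r[i1])

    if len(scales) < 2 or all_clipped:
        return bp_obs, bp_obs, True, None, None

    z = norm.ppf(1.0 - bp_r)
    w = B / (bp_r * (1.0 - bp_r))
    X = np.column_stack([np.sqrt(scales), 1.0 / np.sqrt(scales)])
    WX = X * w[:, None]
    try:
        beta = np.linalg.solve(X.T @ WX, WX.T @ z)
    except np.linalg.LinAlgError:
        return bp_obs, bp_obs, True, None, None
    v, c = float(beta[0]), float(beta[1])
    au = float(1.0 - norm.cdf(v - c))
    bp_fit = float(1.0 - norm.cdf(v + c))
    return au, bp_fit, False, v, c


def multiscale_bootstrap(occ: OccurrenceMatrix, scales=DEFAULT_SCALES,
                         B: int = 1000, seed: int | None = None) -> Dendrogram:
    """UPGMA tree of the Sørensen matrix with AU/BP support per cluster.

    ``B`` replicates are drawn per scale. In a replicate, ecoregions left
    empty by the taxon resample are dropped from that replicate's tree; a
    reference cluster involving a dropped leaf cannot be recovered there
    (missing leaves count as non-support).
    """
    scales = np.asarray(sorted(scales), dtype=float)
    if len(scales) > 1 and not (scales.min() < 1.0 < scales.max()
                                or np.any(scales == 1.0)):
        raise ValidationError("scales must straddle (or include) 1.0")
    if B < 100:
        raise ValidationError("need at least 100 replicates per scale")
    if len(scales) == 1:
        logger.warning("single bootstrap scale: AU falls back to BP "
                       "(two-parameter fit not identifiable)")

    ref = upgma(sorensen_matrix(occ))
    edges = [n for n in ref.internal_nodes()]
    edge_sets = [n.leaves for n in edges]
    counts = np.zeros((len(edges), len(scales)), dtype=int)

    rng = np.random.default_rng(seed)
    T = occ.n_taxa
    inc = occ.incidence.to_numpy()
    cols = np.array(occ.ecoregions, dtype=object)
    n_dropped = 0
    for si, r in enumerate(scales):
        m = max(2, int(round(r * T)))
        for _ in range(B):
            idx = rng.integers(0, T, size=m)
            sub = inc[idx]
            present = sub.any(axis=0)
            if not present.all():
                n_dropped += 1
            keep = np.flatnonzero(present)
            if keep.size < 2:
                continue
            labels = list(cols[keep])
            X = sub[:, keep].T
            dm = DistanceMatrix.from_condensed(pdist(X, "dice"), labels)
            rep_clusters = upgma(dm).clusters()
            for ei, es in enumerate(edge_sets):
                if es in rep_clusters:
                    counts[ei, si] += 1
    if n_dropped:
        logger.info("%d replicates had ecoregions emptied by the resample "
                    "(treated as non-support for clusters involving them)",
                    n_dropped)

    for ei, node in enumerate(edges):
        au, bp, fallback, v, c = _fit_au(scales, counts[ei], B)
        node.au, node.bp, node.au_fallback = au, bp, fallback
        node.signed_distance, node.curvature = v, c
    return ref
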