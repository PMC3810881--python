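"""BIO-ENV: exhaustive environmental variable-subset selection.

For every non-empty subset of candidate variables (up to ``max_k``), a
standardized Euclidean distance matrix is built and its strictly-upper-
triangle entries are rank-correlated (Spearman by default, Kendall as an
option) with those of a community dissimilarity matrix. The subset with the
highest correlation — per size and overall — is reported.

The search is exhaustive, as in the classical method; a cap on the number of
candidates guards against combinatorial blow-up, and ties between subsets
break toward the one earliest in lexicographic (candidate-order) enumeration.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist
from scipy.stats import kendalltau, rankdata

from .core_data import DistanceMatrix, ValidationError

MAX_CANDIDATES = 20


@dataclass
class BioEnvResult:
    """Best subsets per size and overall, with their rank correlations."""

    by_size: dict = field(default_factory=dict)   # k -> (subset tuple, rho)
    best_subset: tuple = ()
    best_correlation: float = float("nan")
    method: str = "spearman"
    n_subsets_evaluated: int = 0

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "best_subset": list(self.best_subset),
            "best_correlation": self.best_correlation,
            "by_size": {k: {"subset": list(s), "correlation": r}
                        for k, (s, r) in self.by_size.items()},
            "n_subsets_evaluated": self.n_subsets_evaluated,
        }


def _spearman(rank_x: np.ndarray, y: np.ndarray) -> float:
    # Pearson correlation of average ranks; rank_x precomputed by the caller.
    ry = rankdata(y)
    rx = rank_x - rank_x.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    return float(rx @ ry / denom) if denom > 0 else float("nan")


def bioenv_search(community: DistanceMatrix, env, codes=None,
                  max_k: int | None = None, method: str = "spearman",
                  allow_large: bool = False) -> BioEnvResult:
    """Exhaustively search variable subsets maximizing rank correlation.

    Parameters
    ----------
    community
        Community dissimilarity matrix (e.g. Sørensen).
    env
        Ecoregion x variable table; rows must cover the community labels.
    codes
        Candidate variable codes (default: all columns of ``env``).
    max_k
        Largest subset size searched (default: all candidates).
    method
        ``"spearman"`` (average ranks for ties) or ``"kendall"``.
    """
    codes = [str(c) for c in (codes if codes is not None else env.columns)]
    if method not in ("spearman", "kendall"):
        raise ValidationError(f"unknown correlation method {method!r}")
    missing = [c for c in codes if c not in env.columns]
    if missing:
        raise ValidationError(f"unknown variable code(s): {missing}")
    if len(codes) > MAX_CANDIDATES and not allow_large:
        raise ValidationError(
            f"{len(codes)} candidate variables exceed the exhaustive-search "
            f"guard ({MAX_CANDIDATES}); reduce candidates or cap max_k and "
            f"pass allow_large=True")
    lab_missing = [l for l in community.labels if l not in env.index]
    if lab_missing:
        raise ValidationError(f"ecoregion {lab_missing[0]!r} missing from env table")
    sub_env = env.loc[community.labels, codes]
    X = sub_env.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValidationError(f"zero-variance candidate: {codes[zero[0]]!r}")
    Z = (X - X.mean(axis=0)) / sd

    # Squared per-variable pair distances; a subset's Euclidean distances are
    # the square root of the subset sum, a strictly monotone transform — but
    # we take the root anyway so reported matrices match euclidean_env_matrix.
    sq = np.stack([pdist(Z[:, [j]], "sqeuclidean") for j in range(len(codes))])

    y = community.condensed()
    rank_y = rankdata(y)
    max_k = len(codes) if max_k is None else min(max_k, len(codes))
    if max_k < 1:
        raise ValidationError("max_k must be >= 1")

    by_size: dict = {}
    n_eval = 0
    for k in range(1, max_k + 1):
        best = None
        for combo in itertools.combinations(range(len(codes)), k):
            d = np.sqrt(sq[list(combo)].sum(axis=0))
            if method == "spearman":
                rho = _spearman(rank_y, d)
            else:
                rho = float(kendalltau(y, d).statistic)
            n_eval += 1
            if best is None or rho > best[1]:
                best = (combo, rho)
        subset = tuple(codes[j] for j in best[0])
        by_size[k] = (subset, best[1])

    best_k = max(by_size, key=lambda k: (by_size[k][1], -k))
    return BioEnvResult(by_size=by_size, best_subset=by_size[best_k][0],
                        best_correlation=by_size[best_k][1], method=method,
                        n_subsets_evaluated=n_eval)
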