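"""Ordination: correspondence analysis, detrended CA, and correlation PCA.

CA decomposes the chi-square-standardized incidence table by SVD; site
(ecoregion) scores are reported in principal coordinates. DCA keeps CA axis 1
and re-derives axis 2 by reciprocal averaging with detrending-by-segments:
within each of ``segments`` equal-width bins of the axis-1 site scores, the
axis-2 scores are centered to zero mean inside every iteration, which removes
the arch artifact. Hill's nonlinear axis rescaling is deliberately not
implemented — the site scatter, not gradient lengths, is the target here.

PCA operates on the correlation matrix (variables are z-scored) because the
environmental variables mix units (mm, °C, m); the loading of largest
magnitude on each axis is made positive for a reproducible sign convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import OccurrenceMatrix, ValidationError


@dataclass
class OrdinationResult:
    """Site scores, eigenvalues, and (for PCA) loadings and variance shares."""

    method: str
    site_scores: pd.DataFrame            # sites x axes
    eigenvalues: np.ndarray
    loadings: pd.DataFrame | None = None  # variables x axes (PCA only)
    variance_fraction: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    def cumulative_variance(self) -> np.ndarray:
        if self.variance_fraction is None:
            raise ValidationError("variance fractions only defined for PCA")
        return np.cumsum(self.variance_fraction)


def _ca_decomposition(N: np.ndarray):
    total = N.sum()
    P = N / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, s, Vt = np.linalg.svd(S, full_matrices=False)
    return r, c, U, s, Vt


def correspondence_analysis(occ: OccurrenceMatrix, n_axes: int = 4) -> OrdinationResult:
    """CA of the incidence table; sites are ecoregions (columns)."""
    N = occ.incidence.to_numpy(dtype=float)
    if N.shape[1] < 2:
        raise ValidationError("need at least two ecoregions for ordination")
    if (N.sum(axis=1) == 0).any() or (N.sum(axis=0) == 0).any():
        raise ValidationError("empty row or column in incidence table")
    r, c, U, s, Vt = _ca_decomposition(N)
    n_axes = min(n_axes, len(s) - 1) if len(s) > 1 else 1
    # drop the trivial axis only if present (s ~ 0 always comes last from SVD
    # of the centered matrix, so the leading axes are the real ones)
    eig = s[:n_axes] ** 2
    site = (Vt[:n_axes].T / np.sqrt(c)[:, None]) * s[:n_axes]
    species = (U[:, :n_axes] / np.sqrt(r)[:, None]) * s[:n_axes]
    cols = [f"CA{i + 1}" for i in range(n_axes)]
    return OrdinationResult(
        method="CA",
        site_scores=pd.DataFrame(site, index=occ.ecoregions, columns=cols),
        eigenvalues=eig,
        extras={"species_scores": pd.DataFrame(species, index=occ.taxa,
                                               columns=cols)},
    )


def _detrend(y: np.ndarray, axis1: np.ndarray, segments: int) -> np.ndarray:
    lo, hi = axis1.min(), axis1.max()
    if hi <= lo:
        return y - y.mean()
    edges = np.linspace(lo, hi, segments + 1)
    which = np.clip(np.digitize(axis1, edges[1:-1]), 0, segments - 1)
    out = y.copy()
    for s in range(segments):
        m = which == s
        if m.any():
            out[m] -= out[m].mean()
    return out


def dca(occ: OccurrenceMatrix, segments: int | None = 26,
        tol: float = 1e-10, max_iter: int = 999) -> OrdinationResult:
    """Detrended correspondence analysis (detrending by segments only).

    ``segments=None`` disables detrending and returns plain CA. Axis 1 is the
    CA first axis; axis 2 is found by reciprocal averaging with within-segment
    centering applied inside every iteration until the site scores converge.
    """
    ca = correspondence_analysis(occ, n_axes=2)
    if segments is None:
        return ca
    if segments < 2:
        raise ValidationError("segments must be >= 2 (or None to disable)")

    N = occ.incidence.to_numpy(dtype=float)
    row_tot = N.sum(axis=1)
    col_tot = N.sum(axis=0)
    axis1 = ca.site_scores["CA1"].to_numpy()

    y = ca.site_scores["CA2"].to_numpy().copy()
    if np.allclose(y, 0):
        y = np.linspace(-1, 1, len(y))
    y = y / np.linalg.norm(y)
    lam = 0.0
    for _ in range(max_iter):
        u = (N @ y) / row_tot          # species scores: weighted averages
        y_new = (N.T @ u) / col_tot    # site scores
        y_new = _detrend(y_new, axis1, segments)
        nrm = np.linalg.norm(y_new)
        if nrm == 0:
            y_new = np.zeros_like(y)
            lam = 0.0
            break
        lam = nrm
        y_new = y_new / nrm
        if np.linalg.norm(y_new - y) < tol or np.linalg.norm(y_new + y) < tol:
            y = y_new
            break
        y = y_new

    scores = pd.DataFrame({"DCA1": axis1, "DCA2": y * np.sqrt(max(lam, 0.0))},
                          index=occ.ecoregions)
    return OrdinationResult(method="DCA", site_scores=scores,
                            eigenvalues=np.array([ca.eigenvalues[0], lam]),
                            extras={"segments": segments})


def pca(env: pd.DataFrame, codes=None, n_axes: int | None = None) -> OrdinationResult:
    """Correlation-matrix PCA of environmental variables."""
    codes = [str(c) for c in (codes if codes is not None else env.columns)]
    X = env[codes].to_numpy(dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValidationError("need at least two variables for PCA")
    sd = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValidationError(f"zero-variance variable: {codes[zero[0]]!r}")
    Z = (X - X.mean(axis=0)) / sd
    cov = (Z.T @ Z) / (n - 1)          # correlation matrix
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # sign convention: largest-|loading| entry positive per axis
    for j in range(p):
        k = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[k, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    n_axes = p if n_axes is None else min(n_axes, p)
    scores = Z @ eigvec[:, :n_axes]
    cols = [f"PC{i + 1}" for i in range(n_axes)]
    return OrdinationResult(
        method="PCA",
        site_scores=pd.DataFrame(scores, index=env.index, columns=cols),
        eigenvalues=eigval[:n_axes],
        loadings=pd.DataFrame(eigvec[:, :n_axes], index=codes, columns=cols),
        variance_fraction=eigval[:n_axes] / eigval.sum(),
    )
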