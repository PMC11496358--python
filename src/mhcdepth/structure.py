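"""Ordination and isolation-by-distance: genetic distances, principal
coordinates analysis (classical metric MDS) and the Mantel permutation
test.

Individuals are encoded as feature vectors — SNP allele dosage (0/1/2),
per-gene allele counts, or supertype counts — missing entries are imputed
by the feature mean, and pairwise Euclidean distance feeds the PCoA.
Geographic distance is great-circle (haversine) on latitude/longitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .formats_io import Genotype, GenotypeMatrix

EARTH_RADIUS_KM = 6371.0


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(self.d)) > 1e-10):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < -1e-12):
            raise ValueError("distances must be non-negative")
        np.fill_diagonal(self.d, 0.0)

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        """Lower-triangle entries, row-major."""
        i, j = np.tril_indices(self.n, k=-1)
        return self.d[i, j]


def dosage_matrix(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Individuals x sites ALT-dosage matrix (0/1/2, NaN for missing)."""
    dos = matrix.calls.astype(float).T
    dos[dos == Genotype.MISSING] = np.nan
    cols = [f"{s.chrom}:{s.pos}" for s in matrix.sites]
    return pd.DataFrame(dos, index=matrix.individuals, columns=cols)


def genetic_distance(
    encoding: pd.DataFrame,
    method: str = "euclidean",
    scale: bool = False,
) -> DistanceMatrix:
    """Pairwise distance between individuals from a feature encoding.

    Missing entries are imputed with the feature mean; ``scale=True``
    standardizes features to unit variance first. ``method`` is
    ``"euclidean"`` (default) or ``"allele_sharing"`` (1 - proportion of
    shared dosage over pairwise-complete features).
    """
    X = np.asarray(encoding, dtype=float)
    ids = [str(i) for i in encoding.index]
    if np.isnan(X).all(axis=1).any():
        raise ValueError("individual with all features missing")

    if method == "euclidean":
        col_mean = np.nanmean(X, axis=0)
        Xi = np.where(np.isnan(X), col_mean[None, :], X)
        if scale:
            sd = Xi.std(axis=0)
            sd[sd == 0] = 1.0
            Xi = (Xi - Xi.mean(axis=0)) / sd
        sq = (Xi**2).sum(axis=1)
        d2 = sq[:, None] + sq[None, :] - 2 * Xi @ Xi.T
        d = np.sqrt(np.maximum(d2, 0.0))
    elif method == "allele_sharing":
        n = X.shape[0]
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                ok = ~np.isnan(X[i]) & ~np.isnan(X[j])
                if not ok.any():
                    raise ValueError("no pairwise-complete features")
                share = 1.0 - np.abs(X[i, ok] - X[j, ok]) / 2.0
                d[i, j] = d[j, i] = 1.0 - share.mean()
    else:
        raise ValueError(f"unknown method {method!r}")
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(ids=ids, d=d, metric=method)


def pcoa(dm: DistanceMatrix, k: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Principal coordinates analysis by double-centering.

    ``B = -1/2 J D^2 J`` with the centering matrix ``J``; coordinates are
    eigenvectors scaled by the square root of the (positive) eigenvalues,
    sorted descending. Sign convention: the first non-zero loading of each
    axis is positive. Returns ``(coordinates, eigenvalues)`` with
    eigenvalues for all retained (positive) axes.
    """
    n = dm.n
    D2 = dm.d**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(1e-10, 1e-10 * abs(vals[0]) if n else 0)
    n_pos = int(pos.sum())
    if k > n_pos:
        warnings.warn(
            f"requested {k} axes but only {n_pos} positive eigenvalues; truncating"
        )
        k = n_pos
    coords = vecs[:, :k] * np.sqrt(vals[:k])[None, :]
    for a in range(k):
        col = coords[:, a]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            coords[:, a] = -col
    return coords, vals[:n_pos]


def haversine_distance(coords: np.ndarray, ids: Sequence[str]) -> DistanceMatrix:
    """Great-circle distance matrix (km) from (lat, lon) degree pairs."""
    c = np.radians(np.asarray(coords, dtype=float))
    lat, lon = c[:, 0], c[:, 1]
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = (
        np.sin(dlat / 2) ** 2
        + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    )
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids=list(ids), d=d, metric="haversine")


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
    alternative: str = "greater",
) -> dict:
    """Mantel permutation test between two distance matrices.

    ``r`` is the Pearson correlation of lower-triangle entries; ``p`` is
    the add-one permutation p-value, permuting rows and columns of ``d2``
    jointly. One-sided (greater) by default.
    """
    if d1.ids != d2.ids:
        raise ValueError("distance matrices must share ids and order")
    if n_perm < 99:
        raise ValueError("need at least 99 permutations")
    x = d1.condensed()
    if x.std() == 0 or d2.condensed().std() == 0:
        raise ValueError("Mantel r undefined for a constant distance matrix")

    tri = np.tril_indices(d1.n, k=-1)

    def corr(mat: np.ndarray) -> float:
        y = mat[tri]
        return float(np.corrcoef(x, y)[0, 1])

    r_obs = corr(d2.d)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(d1.n)
        r_p = corr(d2.d[np.ix_(perm, perm)])
        if alternative == "greater":
            extreme = r_p >= r_obs
        elif alternative == "less":
            extreme = r_p <= r_obs
        else:
            extreme = abs(r_p) >= abs(r_obs)
        count += extreme
    p = (1 + count) / (1 + n_perm)
    return {"r": r_obs, "p": float(p), "n_perm": n_perm, "alternative": alternative}
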