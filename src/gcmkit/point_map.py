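"""Two-dimensional nonmetric MDS point maps with Kruskal stress-1.

The point map places statements in the plane so that the rank order of
inter-point distances matches, as well as possible, the rank order of the
co-sort dissimilarities.  Fit quality is Kruskal's stress-1,

    stress = sqrt( sum_{i<j} (dhat_ij - d_ij)^2 / sum_{i<j} d_ij^2 )

where d are configuration distances and dhat the isotonic (monotone
nondecreasing in the dissimilarities) disparities.  Ties in the
dissimilarities are handled by the primary (weak) approach: tied
dissimilarities may map to different disparities.

Optimization uses SMACOF stress majorization with multiple random
restarts; the returned configuration is the restart with the lowest
stress-1, canonicalized (centered, principal-axis aligned, axis signs
fixed) so that runs are directly comparable.  MDS solutions are defined
only up to isometry, and stress-1 is additionally invariant to uniform
scaling, so canonicalization changes presentation, never fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform

from .similarity import DissimilarityMatrix


@dataclass(frozen=True)
class PointMap:
    """2-D (or dims-D) statement coordinates with the achieved stress-1."""

    coordinates: np.ndarray  # S x dims, row order follows ids
    ids: tuple[int, ...]
    stress: float
    seed: int
    n_restarts: int
    iterations: int
    converged: bool

    @property
    def dims(self) -> int:
        return self.coordinates.shape[1]

    def distances(self) -> np.ndarray:
        """Euclidean distance matrix of the configuration."""
        return squareform(pdist(self.coordinates))


def _pair_order(D: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Order of the off-diagonal pairs: by dissimilarity, then by distance.

    The secondary key implements the weak-tie rule: within a block of tied
    dissimilarities the distances are already nondecreasing, so isotonic
    regression leaves them untouched and ties carry no stress penalty.
    """
    return np.lexsort((d, D))


def kruskal_stress(coordinates: np.ndarray, D: DissimilarityMatrix) -> float:
    """Kruskal stress-1 of a configuration against a dissimilarity matrix."""
    X = np.asarray(coordinates, dtype=float)
    if X.shape[0] != len(D.ids):
        raise ValueError("configuration and dissimilarity index sets differ")
    iu = np.triu_indices(X.shape[0], k=1)
    dvec = squareform(pdist(X))[iu]
    denom = float(np.sum(dvec**2))
    if denom == 0.0:
        raise ValueError("degenerate configuration: all points coincide")
    Dvec = D.matrix[iu]
    order = _pair_order(Dvec, dvec)
    disparities = isotonic_regression(dvec[order]).x
    resid = float(np.sum((disparities - dvec[order]) ** 2))
    return float(np.sqrt(resid / denom))


def _smacof_single(
    Dvec: np.ndarray,
    n: int,
    dims: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, float, int]:
    """One SMACOF run from a random start; returns (X, stress-1, iterations).

    Each majorization step refits weak-tie isotonic disparities to the
    current distances, rescales them to fixed norm (which pins the overall
    scale and prevents the degenerate collapse), and applies the Guttman
    transform.  Stops when stress-1 improves by less than ``tol``.
    """
    iu = np.triu_indices(n, k=1)
    X = rng.uniform(size=(n, dims))
    stress = np.inf
    n_iter = max_iter
    for it in range(1, max_iter + 1):
        dvec = pdist(X)
        dvec[dvec == 0] = 1e-12
        order = _pair_order(Dvec, dvec)
        disp = np.empty_like(dvec)
        disp[order] = isotonic_regression(dvec[order]).x
        disp *= np.sqrt(len(dvec) / np.sum(disp**2))
        new_stress = float(
            np.sqrt(np.sum((disp - dvec) ** 2) / np.sum(dvec**2))
        )
        # Guttman transform with unit weights
        ratio = np.zeros((n, n))
        ratio[iu] = disp / dvec
        ratio += ratio.T
        B = -ratio
        np.fill_diagonal(B, ratio.sum(axis=1))
        X = B @ X / n
        if stress - new_stress < tol:
            stress = new_stress
            n_iter = it
            break
        stress = new_stress
    return X, stress, n_iter


def _canonicalize(X: np.ndarray) -> np.ndarray:
    """Center, rotate to principal axes, and fix axis signs.

    Sign rule: along each axis, the first statement (lowest row index) with
    a non-negligible coordinate gets a nonnegative value.
    """
    X = X - X.mean(axis=0)
    # principal axes via SVD; columns of V are orthonormal directions
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    X = X @ vt.T
    for axis in range(X.shape[1]):
        col = X[:, axis]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if nz.size and col[nz[0]] < 0:
            X[:, axis] = -col
    return X


def fit_point_map(
    D: DissimilarityMatrix,
    dims: int = 2,
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> PointMap:
    """Fit nonmetric MDS by SMACOF over seeded random restarts.

    Restart seeds are drawn from a single stream derived from ``seed``, so
    raising ``n_restarts`` extends (never reshuffles) the set of starts and
    the best stress is nonincreasing in the number of restarts.  The best
    restart is selected by stress-1 recomputed with :func:`kruskal_stress`,
    which is also the stress stored on the returned map.
    """
    M = D.matrix
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if np.any(~np.isfinite(M)):
        raise ValueError("dissimilarity matrix contains non-finite entries")
    if not np.array_equal(M, M.T):
        raise ValueError("dissimilarity matrix must be symmetric")
    if dims < 1:
        raise ValueError("dims must be >= 1")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")

    n = M.shape[0]
    iu = np.triu_indices(n, k=1)
    Dvec = M[iu]
    restart_seeds = np.random.SeedSequence(seed).generate_state(n_restarts) % (2**31)
    best: tuple[float, np.ndarray, int] | None = None
    for rs in restart_seeds:
        X, _, n_iter = _smacof_single(
            Dvec, n, dims, np.random.default_rng(int(rs)), max_iter, tol
        )
        s = kruskal_stress(X, D)
        if best is None or s < best[0]:
            best = (s, X, n_iter)

    _, X, n_iter = best
    X = _canonicalize(X)
    stress = kruskal_stress(X, D)  # unchanged by the isometry, stored exactly
    return PointMap(
        coordinates=X,
        ids=D.ids,
        stress=stress,
        seed=seed,
        n_restarts=n_restarts,
        iterations=int(n_iter),
        converged=bool(n_iter < max_iter),
    )


def write_point_map(pm: PointMap, path: str | Path) -> None:
    cols = {"statement_id": pm.ids}
    for k, name in enumerate("xyz"[: pm.dims] or [f"c{i}" for i in range(pm.dims)]):
        cols[name] = pm.coordinates[:, k]
    pd.DataFrame(cols).to_csv(path, index=False, encoding="utf-8")


def point_map_manifest(pm: PointMap) -> dict:
    return {
        "stress": pm.stress,
        "seed": pm.seed,
        "n_restarts": pm.n_restarts,
        "iterations": pm.iterations,
        "converged": pm.converged,
        "dims": pm.dims,
    }
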