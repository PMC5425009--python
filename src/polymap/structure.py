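"""Population-structure summaries: identity-by-state similarity and classical
(Torgerson) multidimensional scaling used to build association covariates.

Distance is taken as ``1 - IBS``. Eigenvector signs are fixed (largest
magnitude entry made positive) so coordinates are stable across runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .gio import MISSING, GenotypeMatrix


@dataclass
class MdsResult:
    """Sample coordinates (n x k, columns centered) and the k eigenvalues."""

    coordinates: np.ndarray
    eigenvalues: np.ndarray


def ibs_matrix(matrix: GenotypeMatrix) -> np.ndarray:
    """Pairwise identity-by-state similarity in [0, 1].

    Per site the similarity of two dosage codes g_i, g_j is
    ``1 - |g_i - g_j| / 2``; the matrix entry is the average over sites where
    both calls are non-missing. Raises if some pair shares no called site.
    """
    if matrix.n_samples < 2:
        raise ValueError("IBS needs at least two samples")
    codes = matrix.codes
    ind = [(codes == v).astype(np.float64) for v in (0, 1, 2)]
    called = (codes != MISSING).astype(np.float64)
    shared = called @ called.T
    # |g_i - g_j| summed over shared sites, via dosage-class cross products
    diff1 = (ind[0] @ ind[1].T + ind[1] @ ind[0].T
             + ind[1] @ ind[2].T + ind[2] @ ind[1].T)
    diff2 = ind[0] @ ind[2].T + ind[2] @ ind[0].T
    off = ~np.eye(matrix.n_samples, dtype=bool)
    if np.any(shared[off] == 0):
        i, j = np.argwhere((shared == 0) & off)[0]
        raise ValueError(
            f"samples {matrix.samples[i]!r} and {matrix.samples[j]!r} share "
            "no non-missing site")
    with np.errstate(invalid="ignore"):
        sim = (shared - 0.5 * diff1 - diff2) / shared
    sim = (sim + sim.T) / 2.0
    np.fill_diagonal(sim, 1.0)
    return sim


def classical_mds(similarity: np.ndarray, k: int = 2) -> MdsResult:
    """Classical MDS of the distance ``d = 1 - similarity``.

    Double-centers ``-d^2 / 2``, takes the top-k eigenpairs and scales
    eigenvectors by the square root of their eigenvalues. Components with
    non-positive eigenvalues are zero-filled with a warning.
    """
    s = np.asarray(similarity, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError("similarity must be square")
    if not np.allclose(s, s.T, atol=1e-8):
        raise ValueError("similarity must be symmetric")
    n = s.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    d = 1.0 - s
    d2 = d ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    b = (b + b.T) / 2.0
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1][:k]
    evals = evals[order]
    evecs = evecs[:, order]
    coords = np.zeros((n, k))
    tol = 1e-12 * max(1.0, float(np.abs(evals).max(initial=0.0)))
    n_bad = 0
    for c in range(k):
        if evals[c] > tol:
            v = evecs[:, c]
            if v[np.argmax(np.abs(v))] < 0:  # deterministic sign convention
                v = -v
            coords[:, c] = v * np.sqrt(evals[c])
        else:
            n_bad += 1
    if n_bad:
        warnings.warn(f"{n_bad} of {k} MDS components have non-positive "
                      "eigenvalues; zero-filled")
    return MdsResult(coordinates=coords, eigenvalues=evals)
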