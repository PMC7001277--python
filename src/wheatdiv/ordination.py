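"""Genetic distances and principal coordinates analysis (classical MDS).

The distance is Euclidean on per-marker mean-imputed calls, scaled by
``1/sqrt(L)`` so that two accessions differing at every one of L markers are
exactly distance 1 apart.  Mean imputation keeps the distance a proper metric
and matches common genlight-style practice for SNP ordinations.

PCoA is classical scaling: double-center ``-D^2/2``, eigendecompose, scale
eigenvectors by the square roots of their eigenvalues.  Negative eigenvalues
(non-Euclidean input) are truncated, not corrected; their number and summed
magnitude are reported so the truncation is visible in the output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .io_formats import MISSING

DEFAULT_N_AXES = 10


def genetic_distance(matrix) -> np.ndarray:
    """Symmetric accession x accession distance grid from a QC'd matrix."""
    calls = matrix.calls
    if (calls == 2).any():
        raise ValueError("genetic_distance expects a recoded matrix (no 2s)")
    all_missing_rows = np.flatnonzero((calls == MISSING).all(axis=1))
    if all_missing_rows.size:
        raise ValueError(
            f"accession {matrix.accession_ids[all_missing_rows[0]]!r} has no scored calls"
        )
    x = calls.astype(float)
    x[calls == MISSING] = np.nan
    col_means = np.nanmean(x, axis=0)
    col_means = np.where(np.isnan(col_means), 0.0, col_means)  # all-missing marker
    idx = np.where(np.isnan(x))
    x[idx] = col_means[idx[1]]
    d = squareform(pdist(x, metric="euclidean")) / np.sqrt(matrix.n_markers)
    return d


@dataclass(eq=False)
class PcoaResult:
    """Ordination coordinates with eigenvalue bookkeeping.

    ``variance_explained`` covers the retained axes only, as proportions of
    the summed positive eigenvalues; axes are ordered by decreasing
    eigenvalue.
    """

    coordinates: np.ndarray        # (n, m) retained axes
    eigenvalues: np.ndarray        # all n, descending
    variance_explained: np.ndarray  # (m,) proportions over positive eigenvalues
    accession_ids: list | None = None
    n_negative_eigenvalues: int = 0
    negative_eigenvalue_sum: float = 0.0


def pcoa(distances: np.ndarray, n_axes: int = DEFAULT_N_AXES,
         accession_ids=None) -> PcoaResult:
    """Classical metric scaling of a symmetric distance matrix."""
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance grid must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance grid must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError("distance grid must have a zero diagonal")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    tol = max(abs(eigvals[0]), 1.0) * 1e-12
    positive = eigvals > tol
    n_keep = min(n_axes, int(positive.sum()))
    coords = eigvecs[:, :n_keep] * np.sqrt(eigvals[:n_keep])
    pos_sum = float(eigvals[positive].sum())
    var = eigvals[:n_keep] / pos_sum if pos_sum > 0 else np.zeros(n_keep)
    negative = eigvals < -tol
    return PcoaResult(
        coordinates=coords,
        eigenvalues=eigvals,
        variance_explained=var,
        accession_ids=list(accession_ids) if accession_ids is not None else None,
        n_negative_eigenvalues=int(negative.sum()),
        negative_eigenvalue_sum=float(eigvals[negative].sum()),
    )
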