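"""SVD-based descriptor reduction and pair-descriptor assembly.

Per-protein 400-d descriptors are centred and projected onto the top-k
right singular directions of the training descriptor matrix (k = 300 by
default), then the two reduced descriptors of a pair are concatenated
into a 2k-d (600-d) pair descriptor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .transforms import ProteinDescriptor


@dataclass
class SVDProjector:
    """A fitted centring vector plus top-k right singular directions."""

    mean: np.ndarray
    basis: np.ndarray  # d x k, orthonormal columns
    explained: np.ndarray  # k singular values, non-increasing

    @property
    def k(self) -> int:
        return self.basis.shape[1]


@dataclass
class PairDescriptor:
    """Concatenated reduced descriptors of an ordered protein pair."""

    values: np.ndarray
    id_a: str = ""
    id_b: str = ""


def fit_projector(X: np.ndarray, k: int = 300) -> SVDProjector:
    """Fit the SVD projector on an n x d descriptor matrix.

    The matrix is column-centred before decomposition; ``k`` is capped
    at min(n, d) with a warning.  Basis-column signs are canonicalised
    (largest-magnitude entry made positive) so the fit is deterministic
    across linear-algebra backends.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D descriptor matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite entries")
    n, d = X.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    cap = min(n, d)
    if k > cap:
        warnings.warn(f"requested k={k} exceeds min(n, d)={cap}; capping")
        k = cap
    mean = X.mean(axis=0)
    _, s, vt = np.linalg.svd(X - mean, full_matrices=False)
    basis = vt[:k].T.copy()
    for j in range(k):
        col = basis[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            basis[:, j] = -col
    return SVDProjector(mean=mean, basis=basis, explained=s[:k].copy())


def project(p: SVDProjector, d: ProteinDescriptor | np.ndarray) -> np.ndarray:
    """Project a descriptor: basis^T (d - mean)."""
    values = d.values if isinstance(d, ProteinDescriptor) else np.asarray(d, dtype=float)
    values = values.ravel()
    if values.size != p.mean.size:
        raise ValueError(
            f"descriptor has {values.size} entries, projector expects {p.mean.size}"
        )
    return p.basis.T @ (values - p.mean)


def pair_descriptor(
    a: np.ndarray, b: np.ndarray, id_a: str = "", id_b: str = ""
) -> PairDescriptor:
    """Concatenate two equal-length reduced descriptors, pair order kept."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    return PairDescriptor(values=np.concatenate([a, b]), id_a=id_a, id_b=id_b)
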