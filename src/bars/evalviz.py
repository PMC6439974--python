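"""Decoy-set evaluation and low-dimensional landscape views.

Standard decoy bookkeeping: the good-decoy ratio (fraction of decoys with
RMSD to the native strictly below a cutoff, conventionally 6 A for small
proteins), largest-cluster centroid selection as the final prediction, the
all-pairs RMSD matrix, and a 2-D embedding of that matrix for landscape
plots (classical multidimensional scaling of the distance matrix, the usual
reading of "PCA of an RMSD matrix").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .toymodel import Conformation, kabsch_rmsd

__all__ = [
    "DecoySet",
    "good_decoy_ratio",
    "select_prediction",
    "rmsd_matrix",
    "landscape_embedding",
]


def _as_coords(obj) -> np.ndarray:
    if isinstance(obj, Conformation):
        return obj.coords
    return np.asarray(obj, dtype=float)


@dataclass
class DecoySet:
    """A set of candidate conformations plus the native they target.

    Decoys may be Conformation objects or bare N x 3 coordinate arrays; all
    must share the native's residue count.  RMSDs to the native are computed
    lazily and cached.
    """

    decoys: list
    native: object
    _rmsds: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        native = _as_coords(self.native)
        for i, d in enumerate(self.decoys):
            if _as_coords(d).shape != native.shape:
                raise ValueError(
                    f"decoy {i} has {_as_coords(d).shape[0]} residues, "
                    f"native has {native.shape[0]}"
                )

    def __len__(self) -> int:
        return len(self.decoys)

    def coords(self, i: int) -> np.ndarray:
        return _as_coords(self.decoys[i])

    @property
    def native_coords(self) -> np.ndarray:
        return _as_coords(self.native)

    @property
    def rmsds(self) -> np.ndarray:
        if self._rmsds is None:
            nat = self.native_coords
            self._rmsds = np.array(
                [kabsch_rmsd(nat, self.coords(i)) for i in range(len(self))]
            )
        return self._rmsds


def good_decoy_ratio(ds: DecoySet, cutoff: float = 6.0) -> float:
    """Fraction of decoys with RMSD to the native strictly below *cutoff*."""
    if len(ds) == 0:
        raise ValueError("empty decoy set")
    return float((ds.rmsds < cutoff).mean())


def rmsd_matrix(ds: DecoySet) -> np.ndarray:
    """Symmetric all-pairs RMSD matrix with a zero diagonal."""
    n = len(ds)
    if n < 2:
        raise ValueError("need at least 2 decoys")
    mat = np.zeros((n, n))
    for i in range(n):
        ci = ds.coords(i)
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = kabsch_rmsd(ci, ds.coords(j))
    return mat


def select_prediction(
    ds: DecoySet,
    cluster_cutoff: float = 4.0,
    matrix: np.ndarray | None = None,
) -> int:
    """Index of the largest cluster's centroid, the final prediction.

    Greedy neighbor-count clustering on the pairwise RMSD matrix: the decoy
    with the most neighbors within *cluster_cutoff* is the centroid of the
    largest cluster.  Ties break toward the lower index.  A precomputed
    matrix may be supplied to avoid recomputation.
    """
    if len(ds) == 0:
        raise ValueError("empty decoy set")
    if len(ds) == 1:
        return 0
    mat = rmsd_matrix(ds) if matrix is None else np.asarray(matrix, float)
    neighbor_counts = (mat < cluster_cutoff).sum(axis=1) - 1  # exclude self
    return int(np.argmax(neighbor_counts))


def landscape_embedding(
    m: np.ndarray,
    method: Literal["cmds", "pca"] = "cmds",
) -> np.ndarray:
    """Embed a pairwise-distance matrix into 2-D for landscape plots.

    method="cmds" (default): classical multidimensional scaling — double-
    center -0.5 * M^2, take the top-2 eigenvectors scaled by the square
    roots of their eigenvalues.  For a matrix of Euclidean distances of a
    planar configuration this recovers the configuration up to rigid
    motion.  method="pca" treats the raw matrix rows as features and
    projects onto their top-2 principal components (a literal reading,
    kept for comparison).

    Output is centered at the origin; axes are ordered by decreasing
    explained variance.
    """
    mat = np.asarray(m, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    n = mat.shape[0]
    if method == "cmds":
        j = np.eye(n) - np.full((n, n), 1.0 / n)
        b = -0.5 * j @ (mat**2) @ j
        evals, evecs = np.linalg.eigh(b)
        order = np.argsort(evals)[::-1][:2]
        lam = np.clip(evals[order], 0.0, None)
        return evecs[:, order] * np.sqrt(lam)
    if method == "pca":
        x = mat - mat.mean(axis=0)
        _, s, vt = np.linalg.svd(x, full_matrices=False)
        return x @ vt[:2].T
    raise ValueError(f"unknown method {method!r}")
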