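"""Principal coordinate analysis (classical metric MDS).

Gower double-centering of the squared dissimilarities,

    B = −(1/2) J D∘D J,   J = I − (1/n) 11ᵀ,

followed by a symmetric eigendecomposition. Coordinates are eigenvectors
scaled by the square root of their (positive) eigenvalues; negative
eigenvalues — which arise when the dissimilarity is non-Euclidean — are
reported but their axes excluded, and variance explained is taken over the
positive part of the spectrum. An optional Lingoes correction adds the
constant that makes the matrix Euclidean.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from skbio import DistanceMatrix
from sklearn.base import BaseEstimator

logger = logging.getLogger("bulkpop")

__all__ = ["PCoA", "pcoa"]


class PCoA(BaseEstimator):
    """Principal coordinate analysis of a dissimilarity matrix.

    Parameters
    ----------
    n_axes : int or None
        Number of axes to retain (None keeps every positive-eigenvalue axis).
    lingoes : bool
        Apply the Lingoes additive correction when negative eigenvalues
        occur (default off; raw Gower centering of D²).

    Attributes (after ``fit``)
    --------------------------
    coordinates_ : DataFrame, populations × axes, centered per axis.
    eigenvalues_ : ndarray of retained (positive) eigenvalues, descending.
    proportion_explained_ : ndarray, eigenvalues over the positive-spectrum sum.
    negative_eigenvalues_ : ndarray of any negative eigenvalues found.
    """

    def __init__(self, n_axes: int | None = None, lingoes: bool = False) -> None:
        self.n_axes = n_axes
        self.lingoes = lingoes

    def fit(self, dm: DistanceMatrix) -> "PCoA":
        d = dm.data.astype(float)
        n = d.shape[0]
        if n < 3:
            raise ValueError("PCoA needs at least 3 points")
        sq = d**2
        evals = self._decompose(sq, n)
        if self.lingoes and evals.min() < -1e-10:
            c = -evals.min()
            sq = sq + 2 * c * (1 - np.eye(n))
            logger.info("Lingoes correction applied, c = %.6g", c)
            evals = self._decompose(sq, n)
        pos = evals > max(1e-10, 1e-12 * abs(evals).max())
        if not pos.any():
            raise ValueError("degenerate input: no positive eigenvalues")
        neg = evals < -max(1e-10, 1e-12 * abs(evals).max())
        if neg.sum() and abs(evals[neg]).sum() > 0.05 * evals[pos].sum():
            logger.warning(
                "negative eigenvalues exceed 5%% of the positive trace "
                "(%.3g vs %.3g); consider lingoes=True",
                abs(evals[neg]).sum(),
                evals[pos].sum(),
            )
        lam = self._evals[pos][::-1]
        vec = self._evecs[:, pos][:, ::-1]
        coords = vec * np.sqrt(lam)
        if self.n_axes is not None:
            lam, coords = lam[: self.n_axes], coords[:, : self.n_axes]
        self.eigenvalues_ = lam
        self.negative_eigenvalues_ = np.sort(evals[neg])
        self.proportion_explained_ = lam / evals[evals > 0].sum()
        self.coordinates_ = pd.DataFrame(
            coords,
            index=list(dm.ids),
            columns=[f"axis{i + 1}" for i in range(coords.shape[1])],
        )
        return self

    def _decompose(self, sq: np.ndarray, n: int) -> np.ndarray:
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ sq @ j
        evals, evecs = eigh((b + b.T) / 2)
        self._evals, self._evecs = evals, evecs
        return evals

    def fit_transform(self, dm: DistanceMatrix) -> np.ndarray:
        return self.fit(dm).coordinates_.to_numpy()


def pcoa(dm: DistanceMatrix, n_axes: int | None = None, lingoes: bool = False) -> PCoA:
    """Functional wrapper: fit a :class:`PCoA` and return it."""
    return PCoA(n_axes=n_axes, lingoes=lingoes).fit(dm)
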