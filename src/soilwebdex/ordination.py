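"""Bray-Curtis dissimilarity and classical principal coordinate analysis.

Shared by the enzyme-composition index and the per-group community
composition indices. PCoA axis signs are arbitrary in general; here each
axis is oriented so that its largest-magnitude coordinate is positive
(ties broken by earliest sample_id), making downstream averages and
correlations reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io_tables import ValidationError


@dataclass
class OrdinationResult:
    """PCoA output: coordinates on axes with positive eigenvalue.

    ``eigenvalues`` retains the full spectrum (negative eigenvalues of a
    non-Euclidean dissimilarity included, for inspection); ``coordinates``
    only spans the positive axes, ordered by decreasing eigenvalue.
    """

    labels: list[str]
    coordinates: pd.DataFrame
    eigenvalues: np.ndarray

    @property
    def pco1(self) -> pd.Series:
        if self.coordinates.shape[1] == 0:
            return pd.Series(0.0, index=self.labels, name="PCo1")
        return self.coordinates.iloc[:, 0].rename("PCo1")


def bray_curtis(table: pd.DataFrame, relative: bool = False) -> pd.DataFrame:
    """Bray-Curtis dissimilarity matrix between rows of ``table``.

    BC(i, j) = sum |x_i - x_j| / sum (x_i + x_j) over features. With
    ``relative=True`` rows are first normalized to proportions (the usual
    choice for count tables).
    """
    if table.shape[0] < 2:
        raise ValidationError("Bray-Curtis needs at least 2 samples")
    x = table.to_numpy(dtype=float)
    if np.any(x < 0):
        raise ValidationError("Bray-Curtis input must be nonnegative")
    sums = x.sum(axis=1)
    if np.any(sums == 0):
        bad = table.index[np.argmax(sums == 0)]
        raise ValidationError(f"sample {bad!r} has zero total; cannot compute BC")
    if relative:
        x = x / sums[:, None]
    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=table.index, columns=table.index)


def _fix_axis_signs(coords: np.ndarray) -> np.ndarray:
    # orient each axis so the largest-|value| coordinate is positive;
    # np.argmax takes the earliest index on ties
    for j in range(coords.shape[1]):
        col = coords[:, j]
        k = int(np.argmax(np.abs(col)))
        if col[k] < 0:
            coords[:, j] = -col
    return coords


def pcoa(d: pd.DataFrame, eig_tol: float = 1e-10) -> OrdinationResult:
    """Classical (metric) PCoA by double-centering and eigendecomposition.

    Axes with eigenvalue <= ``eig_tol * max(eig)`` are dropped from the
    coordinates; no Lingoes/Cailliez correction is applied.
    """
    labels = list(d.index)
    n = len(labels)
    if n < 2:
        raise ValidationError("PCoA needs at least 2 samples")
    dm = d.to_numpy(dtype=float)
    if not np.allclose(dm, dm.T) or not np.allclose(np.diag(dm), 0.0):
        raise ValidationError("distance matrix must be symmetric with zero diagonal")
    a = -0.5 * dm**2
    row = a.mean(axis=1, keepdims=True)
    g = a - row - row.T + a.mean()
    eigvals, eigvecs = np.linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    cutoff = eig_tol * max(eigvals.max(), 1.0) if eigvals.size else 0.0
    keep = eigvals > cutoff
    coords = eigvecs[:, keep] * np.sqrt(eigvals[keep])
    coords = _fix_axis_signs(coords)
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        labels=labels,
        coordinates=pd.DataFrame(coords, index=labels, columns=cols),
        eigenvalues=eigvals,
    )


def average_pco1(results: dict[str, OrdinationResult]) -> pd.Series:
    """Mean of PCo1 scores across ordinations sharing one sample set.

    Used as the whole-community composition index (one PCoA per
    microbiota group, averaged per sample).
    """
    if not results:
        raise ValidationError("no ordination results supplied")
    items = list(results.values())
    ref = set(items[0].labels)
    for r in items[1:]:
        if set(r.labels) != ref:
            raise ValidationError("ordination results have mismatched sample sets")
    stacked = pd.concat([r.pco1 for r in items], axis=1)
    return stacked.mean(axis=1).rename("avg_pco1")
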