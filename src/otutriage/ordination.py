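"""Jaccard distances between abundance profiles and principal-coordinate embedding.

The between-sample distance is the Jaccard family on abundance vectors:
quantitative (Ruzicka) form ``1 - sum(min) / sum(max)`` by default, or the
classic binary Jaccard on presence calls at a configurable threshold.  The
embedding is classical metric multidimensional scaling (principal
coordinates, PCoA): square the distances, double-center, eigendecompose, and
scale each eigenvector by the square root of its eigenvalue.  Non-Euclidean
distance matrices yield negative eigenvalues; these are reported unchanged
and excluded from the explained-fraction denominator, with no Cailliez or
Lingoes correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .abundance import AbundanceTable

_EIG_TOL = 1e-10


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances with zero diagonal, labelled by sample."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if d.shape != (n, n):
            raise ValueError(f"distance matrix shape {d.shape} != ({n}, {n})")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if (d < 0).any():
            raise ValueError("negative distances")
        object.__setattr__(self, "values", d)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))


@dataclass(frozen=True)
class OrdinationResult:
    """Principal-coordinate axis scores with eigenvalues and explained fractions."""

    coordinates: pd.DataFrame  # samples x k, columns PC1..PCk
    eigenvalues: np.ndarray  # all n eigenvalues, sorted descending
    explained: np.ndarray  # length k, fraction of positive eigenvalue mass


def jaccard_distance(
    x: Sequence[float],
    y: Sequence[float],
    mode: str = "quantitative",
    presence_threshold: float = 0.5,
) -> float:
    """Jaccard distance between two abundance vectors.

    ``quantitative`` (Ruzicka): 1 - sum(min(x, y)) / sum(max(x, y)); two
    all-zero vectors are at distance 0.  ``binary``: classic Jaccard on
    presence calls ``value > presence_threshold``.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError(f"length mismatch: {xa.shape} vs {ya.shape}")
    if (xa < 0).any() or (ya < 0).any():
        raise ValueError("abundance vectors must be non-negative")
    if mode == "quantitative":
        denom = np.maximum(xa, ya).sum()
        if denom == 0:
            return 0.0
        return float(1.0 - np.minimum(xa, ya).sum() / denom)
    if mode == "binary":
        px = xa > presence_threshold
        py = ya > presence_threshold
        union = np.logical_or(px, py).sum()
        if union == 0:
            return 0.0
        return float(1.0 - np.logical_and(px, py).sum() / union)
    raise ValueError(f"unknown mode {mode!r}")


def distance_matrix(
    table: AbundanceTable, mode: str = "quantitative", presence_threshold: float = 0.5
) -> DistanceMatrix:
    """All pairwise Jaccard distances between the table's samples."""
    v = table.data.to_numpy(dtype=float)
    n = v.shape[0]
    if mode == "quantitative":
        # vectorized Ruzicka over all pairs
        mins = np.minimum(v[:, None, :], v[None, :, :]).sum(axis=2)
        maxs = np.maximum(v[:, None, :], v[None, :, :]).sum(axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = 1.0 - np.where(maxs > 0, mins / np.where(maxs > 0, maxs, 1.0), 1.0)
    elif mode == "binary":
        p = v > presence_threshold
        inter = (p[:, None, :] & p[None, :, :]).sum(axis=2)
        union = (p[:, None, :] | p[None, :, :]).sum(axis=2)
        d = 1.0 - np.where(union > 0, inter / np.where(union > 0, union, 1.0), 1.0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # exact symmetry against float noise
    return DistanceMatrix(tuple(table.sample_ids), d)


def pcoa(dm: DistanceMatrix, k: int = 2) -> OrdinationResult:
    """Classical metric MDS of a distance matrix onto ``k`` axes.

    Double-centers -D^2 / 2, eigendecomposes, and returns the top-``k`` axes
    scaled by sqrt(eigenvalue).  Axes whose eigenvalue is not positive get
    zero coordinates.  ``explained`` divides each retained positive
    eigenvalue by the total positive eigenvalue mass.
    """
    d = dm.values
    n = d.shape[0]
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must lie in [1, {n - 1}], got {k}")
    a = -0.5 * d**2
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = j @ a @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    eigvals[np.abs(eigvals) < _EIG_TOL] = 0.0
    coords = np.zeros((n, k))
    pos = eigvals[:k] > 0
    coords[:, pos] = eigvecs[:, :k][:, pos] * np.sqrt(eigvals[:k][pos])
    pos_mass = eigvals[eigvals > 0].sum()
    explained = np.where(
        eigvals[:k] > 0, eigvals[:k] / pos_mass if pos_mass > 0 else 0.0, 0.0
    )
    frame = pd.DataFrame(
        coords, index=list(dm.labels), columns=[f"PC{i + 1}" for i in range(k)]
    )
    frame.index.name = "sample_id"
    return OrdinationResult(coordinates=frame, eigenvalues=eigvals, explained=explained)


def ordinate(
    table: AbundanceTable,
    k: int = 2,
    mode: str = "quantitative",
    presence_threshold: float = 0.5,
) -> OrdinationResult:
    """Distance matrix plus PCoA in one call."""
    return pcoa(distance_matrix(table, mode, presence_threshold), k)


def plot_ordination(result: OrdinationResult, groups: pd.Series | None = None, path=None):
    """Scatter the first two axes, optionally colored by group (needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    coords = result.coordinates
    if groups is None:
        ax.scatter(coords.iloc[:, 0], coords.iloc[:, 1], s=25)
    else:
        for label, idx in groups.groupby(groups).groups.items():
            sub = coords.loc[idx]
            ax.scatter(sub.iloc[:, 0], sub.iloc[:, 1], s=25, label=str(label))
        ax.legend(fontsize=7)
    ax.set_xlabel(f"PC1 ({result.explained[0]:.0%})")
    if coords.shape[1] > 1:
        ax.set_ylabel(f"PC2 ({result.explained[1]:.0%})")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
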