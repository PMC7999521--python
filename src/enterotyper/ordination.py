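"""Principal coordinates analysis (classical MDS) of a distance matrix.

Gower double-centering of -1/2 D^2 followed by an eigendecomposition;
coordinates are eigenvectors scaled by the square root of their
eigenvalues, so Euclidean distances among coordinates reproduce any
Euclidean-embeddable input exactly.  Root-JSD is a metric but not always
Euclidean-embeddable: negative eigenvalues can appear and are dropped
(no Lingoes/Cailliez correction), with their magnitudes reported.
Proportion explained uses the sum of positive eigenvalues as the
denominator.  Each axis's sign is fixed by making its largest-magnitude
coordinate positive, so results are bit-stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio.stats.distance import DistanceMatrix


@dataclass
class OrdinationResult:
    sample_ids: list[str]
    coordinates: np.ndarray  # n x m
    eigenvalues: np.ndarray  # m positive values, descending
    proportion_explained: np.ndarray
    negative_eigenvalues: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PCo{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(
            self.coordinates, index=pd.Index(self.sample_ids, name="sample_id"), columns=cols
        )


def pcoa(dist, n_axes: int | None = None) -> OrdinationResult:
    """Embed a symmetric zero-diagonal distance matrix into coordinates."""
    if isinstance(dist, DistanceMatrix):
        d, ids = dist.data, list(dist.ids)
    else:
        d = np.asarray(dist, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        ids = [str(i) for i in range(d.shape[0])]
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d * d) @ j
    b = 0.5 * (b + b.T)  # guard symmetry against rounding
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals[0]), 1.0) * 1e-10 if n else 0.0
    positive = eigvals > tol
    negative = eigvals[eigvals < -tol]
    lam = eigvals[positive]
    coords = eigvecs[:, positive] * np.sqrt(lam)
    # sign convention: largest-magnitude loading on each axis is positive
    for a in range(coords.shape[1]):
        idx = int(np.argmax(np.abs(coords[:, a])))
        if coords[idx, a] < 0:
            coords[:, a] = -coords[:, a]
    if n_axes is not None:
        coords = coords[:, :n_axes]
        lam = lam[:n_axes]
    total = eigvals[positive].sum()
    prop = lam / total if total > 0 else np.zeros_like(lam)
    return OrdinationResult(
        sample_ids=ids,
        coordinates=coords,
        eigenvalues=lam,
        proportion_explained=prop,
        negative_eigenvalues=np.abs(negative),
    )


def plot_pcoa(result: OrdinationResult, labels=None, path=None, ax=None):
    """Scatter of the first two axes, optionally colored by enterotype.

    Requires matplotlib (optional dependency)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    xy = result.coordinates[:, :2]
    if labels is None:
        ax.scatter(xy[:, 0], xy[:, 1], s=18)
    else:
        lab = np.asarray(getattr(labels, "labels", labels))
        for c in np.unique(lab):
            m = lab == c
            ax.scatter(xy[m, 0], xy[m, 1], s=18, label=f"ET{c}")
        ax.legend(frameon=False)
    pe = result.proportion_explained
    ax.set_xlabel(f"PCo1 ({pe[0] * 100:.1f}%)")
    if len(pe) > 1:
        ax.set_ylabel(f"PCo2 ({pe[1] * 100:.1f}%)")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
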