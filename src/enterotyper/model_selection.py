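"""Choosing the number of enterotypes, and alpha diversity.

Two complementary criteria judge a candidate K:

* **Silhouette index (SI)** — mean over samples of
  ``s(i) = (b(i) - a(i)) / max(a(i), b(i))`` where ``a`` is the mean
  distance to the sample's own cluster (excluding itself) and ``b`` the
  smallest mean distance to any other cluster.  Samples in singleton
  clusters score 0 (the usual convention).
* **Prediction strength (PS)** — a cross-validation stability measure:
  split the cohort 50/50, cluster both halves independently, classify the
  test half onto the training medoids, and take the minimum over test
  clusters of the fraction of within-cluster pairs that land in the same
  training cluster.  PS(1) = 1 by definition.

The chosen K is the one with maximal SI among those whose mean PS clears
a threshold (default 0.8, the published guidance range being 0.8-0.9);
if no K clears it, the SI maximum is returned with a warning flag.

Alpha diversity is summarized per sample as the number of observed taxa
(OTU/genus richness) and the Shannon index ``H = -sum p log p``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import entropy
from skbio.stats.distance import DistanceMatrix

from .clustering import assign_to_medoids, pam
from .distance import jsd_matrix
from .io_tables import RELATIVE, AbundanceTable, EnterotypeLabels, normalize_relative


@dataclass
class KSelectionReport:
    k_values: list[int]
    silhouette: dict[int, float]
    prediction_strength: dict[int, float]
    ps_repeats: dict[int, np.ndarray]
    chosen_k: int
    ps_threshold: float
    below_threshold_warning: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "K": self.k_values,
                "silhouette": [self.silhouette[k] for k in self.k_values],
                "prediction_strength": [self.prediction_strength[k] for k in self.k_values],
                "chosen": [k == self.chosen_k for k in self.k_values],
            }
        ).set_index("K")


def silhouette_samples_from_distance(dist, labels: np.ndarray) -> np.ndarray:
    """Per-sample silhouette widths from a precomputed distance matrix."""
    d = dist.data if isinstance(dist, DistanceMatrix) else np.asarray(dist, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette undefined for a single cluster")
    n = d.shape[0]
    masks = {c: labels == c for c in uniq}
    sizes = {c: int(m.sum()) for c, m in masks.items()}
    s = np.zeros(n)
    for i in range(n):
        own = labels[i]
        if sizes[own] == 1:
            continue  # singleton -> 0
        a = d[i, masks[own]].sum() / (sizes[own] - 1)
        b = min(d[i, masks[c]].mean() for c in uniq if c != own)
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return s


def silhouette_index(dist, labels) -> float:
    """Mean silhouette width of a labeling over a distance matrix."""
    if isinstance(labels, EnterotypeLabels):
        labels = labels.labels
    return float(silhouette_samples_from_distance(dist, labels).mean())


def _pairs_same_fraction(members_assign: np.ndarray) -> float:
    """Fraction of pairs within one test cluster co-assigned by training."""
    m = len(members_assign)
    total = m * (m - 1) // 2
    same = sum(c * (c - 1) // 2 for c in np.bincount(members_assign))
    return same / total


def _ps_one_split(d: np.ndarray, k: int, rng: np.random.Generator) -> float:
    n = d.shape[0]
    perm = rng.permutation(n)
    train, test = np.sort(perm[: n // 2]), np.sort(perm[n // 2 :])
    res_train = pam(d[np.ix_(train, train)], k)
    res_test = pam(d[np.ix_(test, test)], k)
    # classify test samples by the training medoids (global indices)
    train_medoids_global = train[res_train.medoid_indices]
    train_assign = assign_to_medoids(d[np.ix_(test, train_medoids_global)])
    test_labels = res_test.labels.labels
    fractions = []
    for j in np.unique(test_labels):
        members = train_assign[test_labels == j]
        if len(members) >= 2:
            fractions.append(_pairs_same_fraction(members))
    return min(fractions) if fractions else np.nan


def prediction_strength(
    table_or_dist,
    k: int,
    n_repeats: int = 20,
    seed: int | None = None,
    return_repeats: bool = False,
):
    """Mean prediction strength of K clusters over random 50/50 splits."""
    d = _distance_array(table_or_dist)
    n = d.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        reps = np.ones(n_repeats)
        return (1.0, reps) if return_repeats else 1.0
    if k > n // 2:
        raise ValueError(f"k={k} exceeds n/2={n // 2}; halves cannot hold k clusters")
    rng = np.random.default_rng(seed)
    reps = np.array([_ps_one_split(d, k, rng) for _ in range(n_repeats)])
    mean = float(np.nanmean(reps))
    return (mean, reps) if return_repeats else mean


def _distance_array(table_or_dist) -> np.ndarray:
    if isinstance(table_or_dist, AbundanceTable):
        t = table_or_dist
        if t.unit != RELATIVE:
            t = normalize_relative(t)
        return jsd_matrix(t).data
    if isinstance(table_or_dist, DistanceMatrix):
        return table_or_dist.data
    return np.asarray(table_or_dist, dtype=float)


def choose_k(
    table_or_dist,
    k_range=range(2, 7),
    ps_threshold: float = 0.8,
    n_repeats: int = 20,
    seed: int | None = None,
) -> KSelectionReport:
    """Evaluate silhouette and prediction strength over ``k_range``.

    chosen_K maximizes SI among K with mean PS >= ``ps_threshold``; if no
    K passes, the SI argmax is chosen and the warning flag set.  Ties go
    to the smaller K.
    """
    k_values = sorted(set(int(k) for k in k_range))
    if not k_values:
        raise ValueError("empty k_range")
    d = _distance_array(table_or_dist)
    n = d.shape[0]
    if k_values[0] < 2 or k_values[-1] > n // 2:
        raise ValueError(f"k_range must lie within [2, {n // 2}]")
    sil: dict[int, float] = {}
    ps_mean: dict[int, float] = {}
    ps_reps: dict[int, np.ndarray] = {}
    rng = np.random.default_rng(seed)
    for k in k_values:
        res = pam(d, k)
        sil[k] = silhouette_index(d, res.labels)
        ps_mean[k], ps_reps[k] = prediction_strength(
            d, k, n_repeats=n_repeats, seed=int(rng.integers(2**31)), return_repeats=True
        )
    passing = [k for k in k_values if ps_mean[k] >= ps_threshold]
    warning = not passing
    pool = passing if passing else k_values
    chosen = min(pool, key=lambda k: (-sil[k], k))
    return KSelectionReport(
        k_values=k_values,
        silhouette=sil,
        prediction_strength=ps_mean,
        ps_repeats=ps_reps,
        chosen_k=chosen,
        ps_threshold=ps_threshold,
        below_threshold_warning=warning,
    )


@dataclass
class AlphaDiversity:
    """Per-sample richness (observed taxa) and Shannon diversity."""

    data: pd.DataFrame  # columns: observed_units, shannon
    base: str = "e"

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    def to_frame(self) -> pd.DataFrame:
        return self.data


def alpha_diversity(table: AbundanceTable, base: str = "e") -> AlphaDiversity:
    """Observed-taxon count and Shannon index for every sample.

    Works on counts or relative abundances (Shannon is scale-invariant).
    ``base`` is "e" (nats) or "2" (bits); recorded alongside the values
    because the convention differs between toolchains.
    """
    if base not in ("e", "2"):
        raise ValueError("base must be 'e' or '2'")
    logbase = None if base == "e" else 2.0
    values = table.values
    if (values.sum(axis=1) <= 0).any():
        bad = table.data.index[int(np.argmin(values.sum(axis=1)))]
        raise ValueError(f"sample {bad!r} has zero total abundance")
    observed = (values > 0).sum(axis=1)
    shannon = np.array([entropy(row[row > 0], base=logbase) for row in values])
    df = pd.DataFrame(
        {"observed_units": observed, "shannon": shannon},
        index=pd.Index(table.sample_ids, name="sample_id"),
    )
    return AlphaDiversity(df, base=base)
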