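"""Root Jensen-Shannon divergence between per-sample genus profiles.

Enterotyping clusters samples on a probability-distribution distance.
Here that distance is the square root of the Jensen-Shannon divergence

    D(p, q) = sqrt( 1/2 KL(p || m) + 1/2 KL(q || m) ),   m = (p + q) / 2

with natural logarithms, so D is a metric bounded by sqrt(ln 2) ~ 0.8326.
Zero entries are replaced by a small pseudo-abundance (applied per profile,
followed by re-normalization) before the KL terms are evaluated, which
keeps identical profiles at distance exactly 0.  Plain (squared) JSD is
available behind ``root=False``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import rel_entr
from skbio.stats.distance import DistanceMatrix

from .io_tables import RELATIVE, AbundanceTable, TableError

#: upper bound of root-JSD in nats
MAX_ROOT_JSD = float(np.sqrt(np.log(2.0)))

DEFAULT_ZERO_REPLACEMENT = 1e-9


def _prepare(v: np.ndarray, zero_replacement: float) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.ndim != 1:
        raise ValueError("probability vector must be 1-D")
    if (v < 0).any():
        raise ValueError("probability vector has negative entries")
    total = v.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("probability vector is not normalizable")
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"probability vector sums to {total:.12g}, not 1")
    w = np.where(v == 0, zero_replacement, v)
    return w / w.sum()


def jsd(
    p: np.ndarray,
    q: np.ndarray,
    zero_replacement: float = DEFAULT_ZERO_REPLACEMENT,
    root: bool = True,
) -> float:
    """Jensen-Shannon distance (or divergence if ``root=False``) in nats."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {q.shape}")
    pw = _prepare(p, zero_replacement)
    qw = _prepare(q, zero_replacement)
    m = 0.5 * (pw + qw)
    div = 0.5 * rel_entr(pw, m).sum() + 0.5 * rel_entr(qw, m).sum()
    div = max(float(div), 0.0)  # clip -eps from rounding
    return float(np.sqrt(div)) if root else div


def jsd_matrix(
    table: AbundanceTable,
    zero_replacement: float = DEFAULT_ZERO_REPLACEMENT,
    root: bool = True,
) -> DistanceMatrix:
    """All-pairs Jensen-Shannon distances of a relative abundance table.

    Returns a validated symmetric, zero-diagonal ``skbio`` DistanceMatrix
    keyed by sample id.
    """
    if table.unit != RELATIVE:
        raise TableError("jsd_matrix expects a relative table; normalize first")
    n = table.n_samples
    if n < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    profiles = np.stack(
        [_prepare(row, zero_replacement) for row in table.values]
    )
    # entropy identity: JSD(p, q) = H(m) - (H(p) + H(q)) / 2
    plogp = np.where(profiles > 0, profiles * np.log(profiles), 0.0)
    h = -plogp.sum(axis=1)
    out = np.zeros((n, n))
    for i in range(n - 1):
        m = 0.5 * (profiles[i + 1 :] + profiles[i])
        hm = -(m * np.log(m)).sum(axis=1)
        div = hm - 0.5 * (h[i + 1 :] + h[i])
        np.maximum(div, 0.0, out=div)
        out[i, i + 1 :] = np.sqrt(div) if root else div
    out += out.T
    return DistanceMatrix(out, ids=table.sample_ids)


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    dm.write(str(path))


def read_distance_matrix(path) -> DistanceMatrix:
    return DistanceMatrix.read(str(path))
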