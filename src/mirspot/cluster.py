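"""Hierarchical clustering as configured in Cluster 3.0.

Rows (probes) are median-centered, the similarity between two rows is the
centered (Pearson) correlation over pairwise-complete positions, and
clusters are joined by unweighted average linkage: the similarity between
two clusters is the plain mean of all cross-pair leaf similarities, which
is UPGMA on the distance d = 1 - r.  Ties are broken deterministically by
the smallest pair of cluster indices, and each internal node lists the
older cluster first, which fixes the leaf order the same way Cluster 3.0
does.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConsistencyError
from .tables import IntensityMatrix


@dataclass
class LinkageTree:
    """Agglomerative merge history.

    ``merges`` holds ``(node_id, left, right, similarity)`` with leaves
    labelled ``0..n-1`` and internal nodes ``n..2n-2`` in merge order;
    ``leaf_order`` is the display order of the leaves (left subtree first).
    """

    merges: list
    leaf_order: list

    def __post_init__(self):
        n = len(self.leaf_order)
        if len(self.merges) != n - 1:
            raise ConsistencyError("a tree over n leaves must contain n-1 joins")
        sims = [m[3] for m in self.merges]
        if any(b > a + 1e-9 for a, b in zip(sims, sims[1:])):
            raise ConsistencyError("join similarities must be non-increasing")


def median_center(matrix: IntensityMatrix) -> IntensityMatrix:
    """Subtract each row's median (over non-missing values)."""
    data = matrix.data
    if data.notna().sum(axis=1).eq(0).any():
        bad = list(data.index[data.notna().sum(axis=1) == 0])
        raise ConsistencyError(f"rows with no values cannot be centered: {bad}")
    centered = data.sub(data.median(axis=1), axis=0)
    return IntensityMatrix(centered, matrix.stage)


def centered_correlation(x, y) -> float:
    """Pearson correlation over positions where both vectors are present.

    Returns NaN (with a warning) when fewer than two complete positions
    exist or either vector is constant over them.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    mask = ~(np.isnan(x) | np.isnan(y))
    if mask.sum() < 2:
        warnings.warn("fewer than two complete positions; similarity undefined")
        return float("nan")
    xs, ys = x[mask], y[mask]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        warnings.warn("zero variance over complete positions; similarity undefined")
        return float("nan")
    xc = xs - xs.mean()
    yc = ys - ys.mean()
    return float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))


def similarity_matrix(matrix: IntensityMatrix) -> pd.DataFrame:
    """All-pairs centered correlation between matrix rows."""
    data = matrix.data.to_numpy(float)
    n = data.shape[0]
    sim = np.eye(n)
    complete = ~np.isnan(data).any(axis=1)
    idx = np.flatnonzero(complete)
    if idx.size >= 2:
        # fast path: complete rows in one vectorized correlation
        with np.errstate(invalid="ignore", divide="ignore"):
            block = np.corrcoef(data[idx])
        sim[np.ix_(idx, idx)] = block
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in np.flatnonzero(~complete):
            for j in range(n):
                if j == i:
                    continue
                sim[i, j] = sim[j, i] = centered_correlation(data[i], data[j])
    np.fill_diagonal(sim, 1.0)
    return pd.DataFrame(sim, index=matrix.data.index, columns=matrix.data.index)


def average_linkage(similarity: pd.DataFrame) -> LinkageTree:
    """Unweighted average-linkage (UPGMA) tree from a similarity matrix.

    Cluster-cluster similarity is the mean over all cross pairs of leaf
    similarities; each step joins the most similar pair, breaking ties by
    the smallest (row, column) cluster index.  Undefined (NaN) pair
    similarities are excluded from the averages.
    """
    sim = similarity.to_numpy(float)
    n = sim.shape[0]
    if n < 2:
        raise ConsistencyError("clustering needs at least two items")
    if not np.allclose(np.nan_to_num(sim), np.nan_to_num(sim.T)):
        raise ConsistencyError("similarity matrix must be symmetric")
    sim = (sim + sim.T) / 2.0  # make symmetry exact for tie detection

    # Running sums / counts of *defined* cross-pair similarities let the
    # cluster-cluster mean be updated in O(n) per merge (Lance-Williams with
    # NaN pairs simply left out of the average).
    defined = ~np.isnan(sim)
    sums = np.where(defined, sim, 0.0).astype(float)
    counts = defined.astype(float)
    np.fill_diagonal(sums, 0.0)
    np.fill_diagonal(counts, 0.0)

    active = np.ones(n, bool)
    slot_id = list(range(n))       # matrix slot -> current cluster id
    order = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    for _ in range(n - 1):
        idx = np.flatnonzero(active)
        sub_sums = sums[np.ix_(idx, idx)]
        sub_counts = counts[np.ix_(idx, idx)]
        mean = np.where(sub_counts > 0, sub_sums / np.maximum(sub_counts, 1), -np.inf)
        np.fill_diagonal(mean, -np.inf)
        s = mean.max()
        ta, tb = np.nonzero(mean == s)
        upper = ta < tb
        ta, tb = ta[upper], tb[upper]
        # smallest (older id, newer id) pair wins
        ids = np.fromiter((slot_id[k] for k in idx), int, len(idx))
        id_lo = np.minimum(ids[ta], ids[tb])
        id_hi = np.maximum(ids[ta], ids[tb])
        w = np.lexsort((id_hi, id_lo))[0]
        id_a, id_b = int(id_lo[w]), int(id_hi[w])
        i, j = int(idx[ta[w]]), int(idx[tb[w]])
        if slot_id[i] != id_a:
            i, j = j, i
        order[next_id] = order.pop(id_a) + order.pop(id_b)
        merges.append((next_id, id_a, id_b, float(s)))
        # merged cluster occupies slot i
        sums[i, :] += sums[j, :]
        sums[:, i] = sums[i, :]
        counts[i, :] += counts[j, :]
        counts[:, i] = counts[i, :]
        sums[i, i] = counts[i, i] = 0.0
        active[j] = False
        slot_id[i] = next_id
        next_id += 1
    (root,) = order
    return LinkageTree(merges=merges, leaf_order=order[root])


def cluster_matrix(matrix: IntensityMatrix, center: bool = True):
    """Median-center, build similarities and cluster; returns (tree, matrix used)."""
    work = median_center(matrix) if center else matrix
    tree = average_linkage(similarity_matrix(work))
    return tree, work
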