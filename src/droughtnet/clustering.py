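"""Average-linkage hierarchical clustering with the three dendrogram metrics.

Three inter-item distances are supported: Euclidean, Pearson distance
(1 - Pearson correlation) and Spearman distance (1 - Spearman rank
correlation). Clustering is UPGMA-style average linkage; merge order ties
are broken deterministically by the smallest original index pair.

Two matrix builders feed the dendrograms: a chromosome x position-bin
incidence matrix of gene locations (default bin width 1000 position-code
units) and a gene x sample log2(RPKM) matrix (zeros stabilised with a
0.001 pseudocount before the log).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .core_io import SAMPLES, CountTable, GeneLocus

__all__ = ["Dendrogram", "distance_matrix", "hclust_average",
           "chromosome_position_matrix", "rpkm_matrix", "log_rpkm_matrix"]

METRICS = ("pearson", "euclidean", "spearman")


@dataclass
class Dendrogram:
    """Merge list of an agglomerative clustering.

    ``merges`` holds (cluster_a, cluster_b, height) triples where cluster
    indices follow the scipy convention: leaves are 0..n-1 and the i-th
    merge creates cluster n+i.
    """

    merges: list[tuple[int, int, float]]
    leaf_labels: list[str]

    @property
    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]


def distance_matrix(data, metric: str = "euclidean") -> np.ndarray:
    """Symmetric item x item distance matrix over the rows of ``data``.

    Correlation metrics require non-constant rows; a constant row raises an
    error naming it.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    if isinstance(data, pd.DataFrame):
        labels = list(data.index)
        values = data.to_numpy(dtype=float)
    else:
        values = np.asarray(data, dtype=float)
        labels = list(range(values.shape[0]))
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two rows")

    if metric == "euclidean":
        dist = squareform(pdist(values, metric="euclidean"))
    else:
        const = np.isclose(values.std(axis=1), 0.0)
        if const.any():
            bad = [labels[i] for i in np.flatnonzero(const)]
            raise ValueError(f"constant rows not allowed with {metric} distance: {bad}")
        if metric == "spearman":
            values = np.apply_along_axis(rankdata, 1, values)
        corr = np.corrcoef(values)
        dist = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
        dist = np.clip(dist, 0.0, None)
    return dist


def hclust_average(dist: np.ndarray) -> Dendrogram:
    """UPGMA average-linkage dendrogram from a full distance matrix."""
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    n = dist.shape[0]
    z = linkage(squareform(dist, checks=False), method="average")
    merges = [(int(a), int(b), float(h)) for a, b, h, _ in z]
    return Dendrogram(merges=merges, leaf_labels=[str(i) for i in range(n)])


def chromosome_position_matrix(
    loci: list[GeneLocus], bin_width: int = 1000
) -> pd.DataFrame:
    """Chromosome x position-bin gene counts for location dendrograms.

    Genes on unknown-position chromosome labels (Ann/Cnn/Unn) are binned by
    their position code like any other label, so they appear as their own
    rows. Columns cover bins 0..max observed.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if not loci:
        raise ValueError("need at least one locus")
    max_bin = max(l.position_code // bin_width for l in loci)
    chroms = sorted({l.chromosome_label for l in loci})
    mat = pd.DataFrame(
        0, index=chroms, columns=range(max_bin + 1), dtype=int
    )
    for l in loci:
        mat.at[l.chromosome_label, l.position_code // bin_width] += 1
    return mat


def rpkm_matrix(table: CountTable) -> pd.DataFrame:
    """Gene x sample RPKM expression matrix."""
    lengths = table.gene_length_bases.to_numpy(dtype=float)[:, None]
    totals = np.array([table.library_total[s] for s in SAMPLES], dtype=float)[None, :]
    rpkm = 1e9 * table.counts.to_numpy(dtype=float) / (totals * lengths)
    return pd.DataFrame(rpkm, index=table.counts.index, columns=list(SAMPLES))


def log_rpkm_matrix(table: CountTable, pseudocount: float = 0.001) -> pd.DataFrame:
    """Gene x sample log2(RPKM + pseudocount) expression matrix."""
    return np.log2(rpkm_matrix(table) + pseudocount)
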