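"""Hierarchical clustering of PS similarity profiles and quadrant analysis.

Beyond network fragmentation, two further views of inter-PS similarity:

* **Clustering.** The all-pairs coefficients form a symmetric m x m matrix
  whose row i is PS_i's full similarity profile. Rows are compared with the
  *uncentered* Pearson correlation, d(x, y) = 1 - sum(x_i y_i) /
  sqrt(sum(x_i^2) sum(y_i^2)), and clustered by average linkage (UPGMA),
  cutting the tree at a requested cluster count.

* **Quadrants.** For every PS pair with both a clinical and a biological
  coefficient, the (clinical, biological) point falls into one of four
  regimes around a cutoff (2.0 by default): both low (I), both high (II),
  biologically high only (III), clinically high only (IV). Discordant
  quadrants III/IV flag pairs where biology and clinic decouple.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage

from .similarity import SimilarityCoefficient

logger = logging.getLogger(__name__)

Pair = tuple[str, str]
QUADRANTS = ("I", "II", "III", "IV")


@dataclass
class PSSimilarityMatrixFull:
    """Symmetric all-pairs coefficient matrix; diagonal = self-BMA."""

    ps_ids: tuple[str, ...]
    values: np.ndarray

    def row(self, ps_id: str) -> np.ndarray:
        return self.values[self.ps_ids.index(ps_id)]


def full_similarity_matrix(
    coefficients: Sequence[SimilarityCoefficient],
    ps_ids: Sequence[str],
    diagonal: Mapping[str, float],
) -> PSSimilarityMatrixFull:
    """Assemble the symmetric coefficient matrix over ``ps_ids``.

    Every unordered pair must be covered by ``coefficients``; ``diagonal``
    supplies each PS's self-coefficient (its BMA against itself).
    """
    ids = tuple(ps_ids)
    index = {p: i for i, p in enumerate(ids)}
    m = len(ids)
    values = np.full((m, m), np.nan)
    for c in coefficients:
        i, j = index.get(c.ps_a), index.get(c.ps_b)
        if i is None or j is None or i == j:
            continue
        values[i, j] = values[j, i] = c.w
    for p, i in index.items():
        values[i, i] = diagonal[p]
    if np.isnan(values).any():
        missing = int(np.isnan(values).sum() // 2)
        raise ValueError(f"similarity matrix incomplete: {missing} pairs missing")
    return PSSimilarityMatrixFull(ps_ids=ids, values=values)


def uncentered_pearson_distance(x: np.ndarray, y: np.ndarray) -> float:
    """1 - uncentered Pearson correlation (cosine-type distance)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    nx, ny = np.sqrt((x * x).sum()), np.sqrt((y * y).sum())
    if nx == 0.0 or ny == 0.0:
        raise ValueError("uncentered correlation undefined for a zero-norm vector")
    return float(1.0 - (x * y).sum() / (nx * ny))


def _condensed_distances(values: np.ndarray) -> np.ndarray:
    norms = np.sqrt((values * values).sum(axis=1))
    if (norms == 0.0).any():
        raise ValueError("zero-norm similarity profile; cannot cluster")
    corr = (values @ values.T) / np.outer(norms, norms)
    d = np.clip(1.0 - corr, 0.0, None)
    m = len(values)
    return d[np.triu_indices(m, k=1)]


@dataclass
class Dendrogram:
    """Merge history of an agglomerative clustering (scipy linkage encoding)."""

    merges: np.ndarray  # (m-1, 4): cluster a, cluster b, height, size
    leaf_order: tuple[int, ...]

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


@dataclass
class ClusterAssignment:
    ps_ids: tuple[str, ...]
    labels: tuple[int, ...]  # 1-based cluster labels, aligned with ps_ids
    k: int
    dendrogram: Dendrogram

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.ps_ids, self.labels))


def average_linkage_cluster(
    matrix: PSSimilarityMatrixFull, k: int
) -> ClusterAssignment:
    """UPGMA clustering of similarity-profile rows, cut to k clusters.

    Distance between rows is the uncentered Pearson distance. Degenerate
    all-identical inputs still split deterministically (warning logged).
    """
    m = len(matrix.ps_ids)
    if not 1 <= k <= m:
        raise ValueError(f"cluster count k={k} outside 1..{m}")
    condensed = _condensed_distances(matrix.values)
    if m > 1 and np.allclose(condensed, condensed[0]) and k > 1:
        logger.warning("all profile rows equidistant; k=%d split is arbitrary", k)
    z = linkage(condensed, method="average")
    labels = fcluster(z, t=k, criterion="maxclust")
    dendro = Dendrogram(merges=z, leaf_order=tuple(int(i) for i in leaves_list(z)))
    return ClusterAssignment(
        ps_ids=matrix.ps_ids,
        labels=tuple(int(l) for l in labels),
        k=int(labels.max()),
        dendrogram=dendro,
    )


def dendrogram_newick(dendro: Dendrogram, labels: Sequence[str]) -> str:
    """Newick rendering of the merge history (branch lengths = merge heights)."""
    m = len(labels)
    nodes: dict[int, str] = {i: labels[i] for i in range(m)}
    heights: dict[int, float] = {i: 0.0 for i in range(m)}
    for idx, (a, b, h, _) in enumerate(dendro.merges):
        a, b = int(a), int(b)
        la = max(h - heights[a], 0.0)
        lb = max(h - heights[b], 0.0)
        nodes[m + idx] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[m + idx] = h
    return nodes[m + len(dendro.merges) - 1] + ";"


@dataclass
class QuadrantSummary:
    """PS pairs split by clinical x biological similarity regime."""

    threshold: float
    counts: dict[str, int]
    pairs: dict[str, list[Pair]]

    @property
    def n_pairs(self) -> int:
        return sum(self.counts.values())


def quadrant_counts(
    clinical: Mapping[Pair, float],
    biological: Mapping[Pair, float],
    threshold: float = 2.0,
) -> QuadrantSummary:
    """Partition pairs with both coefficients into the four quadrants.

    II: both >= threshold; III: biological >= threshold only; IV: clinical
    >= threshold only; I: both below. Evaluated pairs are the intersection
    of the two maps' keys.
    """
    shared = sorted(set(clinical) & set(biological))
    if not shared:
        raise ValueError("no PS pair has both a clinical and a biological coefficient")
    pairs: dict[str, list[Pair]] = {q: [] for q in QUADRANTS}
    for pair in shared:
        clin_high = clinical[pair] >= threshold
        bio_high = biological[pair] >= threshold
        if clin_high and bio_high:
            q = "II"
        elif bio_high:
            q = "III"
        elif clin_high:
            q = "IV"
        else:
            q = "I"
        pairs[q].append(pair)
    counts = {q: len(pairs[q]) for q in QUADRANTS}
    return QuadrantSummary(threshold=threshold, counts=counts, pairs=pairs)


def quadrant_table(summary: QuadrantSummary) -> pd.DataFrame:
    rows = [
        {"quadrant": q, "ps_a": a, "ps_b": b}
        for q in QUADRANTS
        for a, b in summary.pairs[q]
    ]
    return pd.DataFrame(rows, columns=["quadrant", "ps_a", "ps_b"])
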