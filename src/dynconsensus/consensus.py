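"""Group-network builders.

Three ways of collapsing a cohort of connectomes into one group network:

* **Uniform consensus** -- keep an edge iff it is present in at least a
  threshold fraction of subjects.  Sweeping the threshold over all
  multiples of ``100/n`` yields the candidate ladder from which the
  dynamics-based consensus is later selected.
* **Distance-dependent consensus** -- consensus applied separately within
  bins of inter-node Euclidean distance, and separately for intra- and
  inter-hemispheric connections, so the group network preserves the
  cohort's connection-length distribution and mean density.
* **Consistency-based thresholding** -- keep the node pairs whose weights
  have the lowest coefficient of variation across subjects, up to a
  target density.

All tie-breaks are deterministic and documented per function, so a given
cohort always maps to bit-identical group networks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .connectome import BinaryConnectome, Cohort, NodeTable

__all__ = [
    "ThresholdLadder", "edge_prevalence", "prevalence_histogram",
    "uniform_consensus", "min_subject_count", "build_ladder",
    "euclidean_distance_matrix", "distance_dependent_consensus",
    "consistency_consensus",
]


def edge_prevalence(cohort: Cohort) -> np.ndarray:
    """Per-pair count of cohort members containing each edge.

    Element-wise sum of the binary adjacency matrices; symmetric integer
    matrix with zero diagonal.
    """
    if not cohort.is_binary:
        raise TypeError("edge prevalence needs a binary cohort; binarize first")
    counts = np.zeros((len(cohort.nodes), len(cohort.nodes)), dtype=np.int64)
    for m in cohort:
        counts += m.adjacency
    return counts


def prevalence_histogram(prev: np.ndarray, n: int) -> np.ndarray:
    """Fraction of upper-triangle node pairs at each prevalence 0..n.

    Entry ``h[c]`` is the fraction of node pairs present in exactly ``c``
    of the ``n`` subjects; the fractions sum to 1.
    """
    iu, ju = np.triu_indices(prev.shape[0], k=1)
    vals = prev[iu, ju]
    counts = np.bincount(vals, minlength=n + 1).astype(float)
    return counts / counts.sum()


def min_subject_count(threshold: float, n: int) -> int:
    """Minimum subject count implied by a percentage consensus threshold.

    ``ceil(threshold * n / 100)``, treating the threshold as quoted to
    one decimal place: ladder thresholds (multiples of ``100/n``) give
    the exact integer even when rounded for display, e.g. 42.5% of 40
    subjects -> 17 and 66.7% of 3 subjects -> 2 (66.7 ~ 2/3).
    """
    if not 0 < threshold <= 100:
        raise ValueError("threshold must be in (0, 100]")
    x = threshold * n / 100.0
    # 0.05 percentage points of display rounding = 0.0005*n subject counts
    return int(math.ceil(x - 5e-4 * n - 1e-9))


def uniform_consensus(cohort: Cohort, threshold: float) -> BinaryConnectome:
    """Keep every edge present in at least ``threshold``% of members."""
    prev = edge_prevalence(cohort)
    need = min_subject_count(threshold, len(cohort))
    a = (prev >= need).astype(np.int8)
    np.fill_diagonal(a, 0)
    return BinaryConnectome(adjacency=a, nodes=cohort.nodes)


@dataclass(frozen=True)
class ThresholdLadder:
    """Uniform-consensus networks at every threshold ``k*100/n``, k=1..n.

    Edge sets are nested: raising the threshold can only remove edges.
    """

    thresholds: tuple[float, ...]
    networks: dict  # threshold -> BinaryConnectome

    def __len__(self) -> int:
        return len(self.thresholds)

    def __getitem__(self, threshold: float) -> BinaryConnectome:
        return self.networks[threshold]

    def __iter__(self):
        return iter(self.thresholds)


def build_ladder(cohort: Cohort) -> ThresholdLadder:
    """One consensus network per threshold multiple of ``100/n``."""
    n = len(cohort)
    prev = edge_prevalence(cohort)
    thresholds = tuple(k * 100.0 / n for k in range(1, n + 1))
    networks = {}
    for k, t in enumerate(thresholds, start=1):
        a = (prev >= k).astype(np.int8)
        np.fill_diagonal(a, 0)
        networks[t] = BinaryConnectome(adjacency=a, nodes=cohort.nodes)
    return ThresholdLadder(thresholds=thresholds, networks=networks)


def euclidean_distance_matrix(nodes: NodeTable) -> np.ndarray:
    """Straight-line distances between node centroids, in mm."""
    return squareform(pdist(nodes.coords))


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def distance_dependent_consensus(
    cohort: Cohort,
    distance_matrix: np.ndarray | None = None,
    n_bins: int = 41,
) -> BinaryConnectome:
    """Distance-binned consensus preserving the edge-length distribution.

    Separately for intra- and inter-hemispheric node pairs, the pairs are
    partitioned into ``n_bins`` linearly spaced distance bins spanning the
    class's observed [min, max] pair distance (final bin right-closed).
    Within each bin, ``m`` is the rounded mean number of that-class edges
    cohort members place in the bin, and the ``m`` most prevalent pairs
    are retained (ties: shorter distance, then lower (i, j)).  The union
    over classes and bins is the group network; its density closely tracks
    the mean member density, and no pair absent from every member is ever
    retained.
    """
    if not cohort.is_binary:
        raise TypeError("distance-dependent consensus needs a binary cohort")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    nodes = cohort.nodes
    if distance_matrix is None:
        distance_matrix = euclidean_distance_matrix(nodes)
    n = len(nodes)
    hemi = np.asarray(nodes.hemispheres)
    iu, ju = np.triu_indices(n, k=1)
    pair_d = distance_matrix[iu, ju]
    intra = hemi[iu] == hemi[ju]
    prev = edge_prevalence(cohort)
    pair_prev = prev[iu, ju]
    n_subj = len(cohort)

    keep = np.zeros(iu.size, dtype=bool)
    for cls_mask in (intra, ~intra):
        idx = np.flatnonzero(cls_mask)
        if idx.size == 0:
            continue
        d = pair_d[idx]
        lo, hi = d.min(), d.max()
        if hi == lo:
            bin_of = np.zeros(idx.size, dtype=int)
        else:
            edges = np.linspace(lo, hi, n_bins + 1)
            bin_of = np.clip(np.searchsorted(edges, d, side="right") - 1, 0, n_bins - 1)
        for b in range(n_bins):
            in_bin = idx[bin_of == b]
            if in_bin.size == 0:
                continue
            # mean per-subject edge count in this bin
            m = _round_half_away(pair_prev[in_bin].sum() / n_subj)
            if m <= 0:
                continue
            present = in_bin[pair_prev[in_bin] > 0]
            # rank: prevalence desc, distance asc, (i, j) lexicographic asc
            order = np.lexsort(
                (ju[present], iu[present], pair_d[present], -pair_prev[present])
            )
            keep[present[order[: min(m, present.size)]]] = True

    a = np.zeros((n, n), dtype=np.int8)
    a[iu[keep], ju[keep]] = 1
    a += a.T
    return BinaryConnectome(adjacency=a, nodes=nodes)


def consistency_consensus(
    cohort: Cohort,
    target_density: float,
    cv_include_zeros: bool = True,
) -> BinaryConnectome:
    """Keep the lowest-CV node pairs up to a target density, binarized.

    For every node pair with nonzero mean weight, the coefficient of
    variation is sample-SD/mean of the weight across subjects; with
    ``cv_include_zeros`` (default) absences contribute weight 0, otherwise
    only the subjects possessing the edge enter.  Pairs are ranked by
    ascending CV (ties: higher mean weight, then lower (i, j)) and the
    first ``floor(target_density * N(N-1)/2)`` are retained.
    """
    if cohort.is_binary:
        raise TypeError("consistency thresholding needs a weighted cohort")
    if not 0 < target_density <= 1:
        raise ValueError("target_density must be in (0, 1]")
    nodes = cohort.nodes
    n = len(nodes)
    iu, ju = np.triu_indices(n, k=1)
    stack = np.stack([m.weights[iu, ju] for m in cohort])  # (n_subj, n_pairs)

    mean = stack.mean(axis=0)
    if cv_include_zeros:
        sd = stack.std(axis=0, ddof=1) if len(cohort) > 1 else np.zeros_like(mean)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(mean > 0, sd / mean, np.inf)
    else:
        cv = np.full(mean.shape, np.inf)
        for p in np.flatnonzero(mean > 0):
            vals = stack[:, p][stack[:, p] > 0]
            if vals.size >= 2:
                cv[p] = vals.std(ddof=1) / vals.mean()
            else:
                cv[p] = 0.0

    candidates = np.flatnonzero(mean > 0)
    want = int(math.floor(target_density * iu.size))
    if want > candidates.size:
        warnings.warn(
            f"target density requests {want} pairs but only {candidates.size} "
            "have nonzero mean weight; keeping all of them"
        )
        want = candidates.size
    order = np.lexsort((ju[candidates], iu[candidates], -mean[candidates], cv[candidates]))
    chosen = candidates[order[:want]]

    a = np.zeros((n, n), dtype=np.int8)
    a[iu[chosen], ju[chosen]] = 1
    a += a.T
    return BinaryConnectome(adjacency=a, nodes=nodes)
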