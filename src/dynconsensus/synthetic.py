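"""Ground-truth-anchored synthetic cohorts.

A synthetic cohort starts from a known "seed" binary network (the ground
truth).  Each subject is produced by toggling a random number of distinct
upper-triangle entries -- edge additions and deletions -- with the toggle
count drawn from a rounded normal distribution.  A randomly chosen
immutable core (a fraction of the seed's *edges*) is excluded from
toggling, so every subject retains that part of the topology and very
high consensus thresholds keep a non-trivial network.

Because toggles are sampled without replacement, a subject's Manhattan
distance to the seed (counted over the strict upper triangle) equals its
drawn toggle count exactly, which makes the generator's noise level
directly interpretable.

The generator emulates the gross statistics of a tractography cohort
(edge density, conserved-topology fraction); it makes no attempt to model
the anatomical structure of real between-subject variability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .connectome import BinaryConnectome, Cohort, NodeTable

__all__ = [
    "CohortGenSpec", "generate_cohort", "manhattan_distance",
    "pairwise_flip_statistics", "nearest_member", "random_seed_network",
    "synthetic_node_table", "desikan_killiany_84_labels",
    "desikan_killiany_82_labels", "CEREBELLUM_LABELS",
]

# Desikan-Killiany cortical parcels (34 per hemisphere)
_DK_CORTICAL = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "fusiform", "inferiorparietal", "inferiortemporal",
    "isthmuscingulate", "lateraloccipital", "lateralorbitofrontal",
    "lingual", "medialorbitofrontal", "middletemporal", "parahippocampal",
    "paracentral", "parsopercularis", "parsorbitalis", "parstriangularis",
    "pericalcarine", "postcentral", "posteriorcingulate", "precentral",
    "precuneus", "rostralanteriorcingulate", "rostralmiddlefrontal",
    "superiorfrontal", "superiorparietal", "superiortemporal",
    "supramarginal", "frontalpole", "temporalpole", "transversetemporal",
    "insula",
)
# FreeSurfer subcortical segmentations kept in an 84-region connectome
_DK_SUBCORTICAL = (
    "Thalamus-Proper", "Caudate", "Putamen", "Pallidum", "Hippocampus",
    "Amygdala", "Accumbens-area",
)

CEREBELLUM_LABELS = ("Left-Cerebellum-Cortex", "Right-Cerebellum-Cortex")


def desikan_killiany_84_labels() -> tuple[str, ...]:
    """84 region labels: 2x34 cortical, 2x7 subcortical, 2 cerebellar."""
    labels = []
    for hemi, prefix in (("lh", "Left"), ("rh", "Right")):
        labels += [f"ctx-{hemi}-{r}" for r in _DK_CORTICAL]
        labels += [f"{prefix}-{r}" for r in _DK_SUBCORTICAL]
        labels.append(f"{prefix}-Cerebellum-Cortex")
    return tuple(labels)


def desikan_killiany_82_labels() -> tuple[str, ...]:
    """The 84-region list with the two cerebellar regions removed."""
    return tuple(l for l in desikan_killiany_84_labels() if l not in CEREBELLUM_LABELS)


def synthetic_node_table(labels: Sequence[str] | int, rng_seed: int = 0) -> NodeTable:
    """Node table with SYNTHETIC centroid coordinates.

    ``labels`` is either an explicit label sequence (hemisphere inferred
    from ``Left-``/``Right-``/``ctx-lh``/``ctx-rh`` prefixes, alternating
    otherwise) or a node count, in which case generic ``node-k`` labels
    are used with the first half assigned to the left hemisphere.

    Coordinates are drawn uniformly inside a head-sized box with the x
    coordinate signed by hemisphere; they are placeholders with realistic
    scale (mm), not real atlas centroids.
    """
    if isinstance(labels, int):
        n = labels
        labels = tuple(f"node-{k}" for k in range(n))
        hemis = tuple("left" if k < n / 2 else "right" for k in range(n))
    else:
        labels = tuple(labels)
        hemis = []
        for k, lab in enumerate(labels):
            low = lab.lower()
            if low.startswith(("left", "ctx-lh", "lh")):
                hemis.append("left")
            elif low.startswith(("right", "ctx-rh", "rh")):
                hemis.append("right")
            else:
                hemis.append("left" if k % 2 == 0 else "right")
        hemis = tuple(hemis)
    rng = np.random.default_rng(rng_seed)
    n = len(labels)
    coords = np.column_stack(
        [
            rng.uniform(5.0, 70.0, size=n),
            rng.uniform(-100.0, 70.0, size=n),
            rng.uniform(-50.0, 80.0, size=n),
        ]
    )
    sign = np.where(np.asarray(hemis) == "left", -1.0, 1.0)
    coords[:, 0] *= sign
    return NodeTable(labels=labels, hemispheres=hemis, coords=coords)


def random_seed_network(
    n_nodes: int,
    target_density: float,
    rng: np.random.Generator,
    nodes: NodeTable | None = None,
) -> BinaryConnectome:
    """Erdős–Rényi-style seed network with an exact edge count.

    Picks ``round(target_density * N(N-1)/2)`` distinct node pairs
    uniformly at random, so the realised density matches the target to
    within rounding.
    """
    if not 0 <= target_density <= 1:
        raise ValueError("target_density must be in [0, 1]")
    n_pairs = n_nodes * (n_nodes - 1) // 2
    n_edges = int(round(target_density * n_pairs))
    chosen = rng.choice(n_pairs, size=n_edges, replace=False)
    iu, ju = np.triu_indices(n_nodes, k=1)
    a = np.zeros((n_nodes, n_nodes), dtype=np.int8)
    a[iu[chosen], ju[chosen]] = 1
    a += a.T
    if nodes is None:
        nodes = synthetic_node_table(n_nodes, rng_seed=int(rng.integers(2**31)))
    return BinaryConnectome(adjacency=a, nodes=nodes)


@dataclass
class CohortGenSpec:
    """Parameters of the synthetic cohort generator.

    Defaults emulate a 40-subject, 82-node binary tractography cohort:
    seed density 0.59, an immutable core of 30% of the seed's edges, and
    per-subject toggle counts of 80 +/- 10 entries, a noise level at which
    roughly 40-45% of node pairs stay identical across the whole cohort.
    """

    n_subjects: int = 40
    n_nodes: int = 82
    seed_density: float = 0.59
    seed_network: BinaryConnectome | None = None
    flip_count_mean: float = 80.0
    flip_count_sd: float = 10.0
    core_fraction: float = 0.3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0 <= self.core_fraction <= 1:
            raise ValueError("core_fraction must be in [0, 1]")
        if self.flip_count_mean < 0 or self.flip_count_sd < 0:
            raise ValueError("flip count mean and sd must be >= 0")


def generate_cohort(spec: CohortGenSpec):
    """Generate ``(ground_truth, cohort, core_edges)`` per the spec.

    The immutable core is drawn once per cohort: ``floor(core_fraction *
    n_edges)`` of the seed's edges, present in every member.  Each member
    then toggles ``k ~ round(Normal(mean, sd))`` distinct non-core
    upper-triangle entries (clipped to ``[0, n_mutable]``), mirrored to
    keep symmetry; the diagonal is untouched.
    """
    rng = np.random.default_rng(spec.rng_seed)
    if spec.seed_network is not None:
        seed = spec.seed_network
    else:
        seed = random_seed_network(spec.n_nodes, spec.seed_density, rng)
    n = seed.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    edge_mask = seed.adjacency[iu, ju] > 0
    edge_pair_idx = np.flatnonzero(edge_mask)
    if edge_pair_idx.size < 1:
        raise ValueError("seed network must have at least one edge")
    n_core = int(np.floor(spec.core_fraction * edge_pair_idx.size))
    if n_core > edge_pair_idx.size:
        raise ValueError("immutable core larger than the seed edge set")
    core_idx = rng.choice(edge_pair_idx, size=n_core, replace=False)
    core_edges = {(int(iu[p]), int(ju[p])) for p in core_idx}

    mutable = np.setdiff1d(np.arange(iu.size), core_idx)
    n_mutable = mutable.size

    members = []
    for _ in range(spec.n_subjects):
        k = int(round(rng.normal(spec.flip_count_mean, spec.flip_count_sd)))
        if k < 0:
            k = 0
        if k > n_mutable:
            warnings.warn(
                f"toggle draw {k} exceeds the {n_mutable} mutable entries; clipping"
            )
            k = n_mutable
        flips = rng.choice(mutable, size=k, replace=False)
        a = seed.adjacency.copy()
        fi, fj = iu[flips], ju[flips]
        a[fi, fj] = 1 - a[fi, fj]
        a[fj, fi] = a[fi, fj]
        members.append(BinaryConnectome(adjacency=a, nodes=seed.nodes))

    return seed, Cohort(members=members, nodes=seed.nodes), core_edges


def manhattan_distance(a: BinaryConnectome, b: BinaryConnectome) -> int:
    """Number of differing adjacency entries in the strict upper triangle."""
    if a.n_nodes != b.n_nodes:
        raise ValueError(
            f"shape mismatch: {a.n_nodes} vs {b.n_nodes} nodes"
        )
    diff = a.adjacency != b.adjacency
    return int(np.triu(diff, k=1).sum())


def pairwise_flip_statistics(cohort: Cohort) -> tuple[float, float]:
    """Mean and sample SD of Manhattan distances over all unordered pairs.

    Used to parameterise :class:`CohortGenSpec` when emulating an
    empirical cohort.  A cohort of exactly two members has a single pair;
    its SD is reported as 0 with a warning.
    """
    n = len(cohort)
    if n < 2:
        raise ValueError("pairwise statistics require at least 2 members")
    dists = [
        manhattan_distance(cohort[i], cohort[j])
        for i in range(n)
        for j in range(i + 1, n)
    ]
    dists = np.asarray(dists, dtype=float)
    if dists.size == 1:
        warnings.warn("single member pair: SD reported as 0")
        return float(dists[0]), 0.0
    return float(dists.mean()), float(dists.std(ddof=1))


def nearest_member(query: BinaryConnectome, pool: Sequence[BinaryConnectome]):
    """Closest pool member to ``query`` by Manhattan distance.

    Returns ``((index, distance), table)`` where ``table`` lists every
    ``(index, distance)`` ascending by distance, ties by lowest index.
    """
    if not pool:
        raise ValueError("empty pool")
    dists = [manhattan_distance(query, m) for m in pool]
    table = sorted(enumerate(dists), key=lambda t: (t[1], t[0]))
    best = table[0]
    return best, table
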