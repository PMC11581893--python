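"""Connectome containers and delimited-text I/O.

Connectivity matrices are plain square numeric text files (whitespace- or
comma-delimited, no header, one row per node).  Node metadata lives in a
separate TSV with header ``node_id  label  hemisphere  x  y  z``; centroid
coordinates are in millimetres.  All node indices are 0-based everywhere:
in files, in logs and in every API of this package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NodeTable", "BinaryConnectome", "WeightedConnectome", "Cohort",
    "read_connectome", "read_node_table", "read_matrix", "write_matrix",
    "write_node_table", "binarize", "drop_regions", "density",
]

_HEMISPHERES = {"left", "right"}


@dataclass(frozen=True)
class NodeTable:
    """Parcellation node metadata: labels, hemisphere and 3-D centroids (mm).

    Node ids are implicit consecutive integers ``0..N-1`` in row order.
    """

    labels: tuple[str, ...]
    hemispheres: tuple[str, ...]
    coords: np.ndarray  # (N, 3) float, mm

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("node labels must be unique")
        if len(self.hemispheres) != n or coords.shape != (n, 3):
            raise ValueError("labels, hemispheres and coords must agree in length")
        bad = set(self.hemispheres) - _HEMISPHERES
        if bad:
            raise ValueError(f"unknown hemisphere values: {sorted(bad)}")
        if not np.all(np.isfinite(coords)):
            raise ValueError("node centroid coordinates must be finite")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown node label: {label!r}") from None

    def subset(self, keep: Sequence[int]) -> "NodeTable":
        keep = list(keep)
        return NodeTable(
            labels=tuple(self.labels[i] for i in keep),
            hemispheres=tuple(self.hemispheres[i] for i in keep),
            coords=self.coords[keep],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_id": np.arange(len(self)),
                "label": self.labels,
                "hemisphere": self.hemispheres,
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "z": self.coords[:, 2],
            }
        )


def _check_square_symmetric(mat: np.ndarray, tol: float, what: str) -> np.ndarray:
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"non-square {what} matrix with shape {mat.shape}")
    asym = np.abs(mat - mat.T)
    worst = np.unravel_index(np.argmax(asym), asym.shape)
    if asym[worst] > tol:
        i, j = int(worst[0]), int(worst[1])
        raise ValueError(
            f"{what} matrix asymmetric beyond tolerance {tol} at indices "
            f"({i}, {j}): {mat[i, j]} vs {mat[j, i]}"
        )
    mat = (mat + mat.T) / 2.0
    np.fill_diagonal(mat, 0.0)
    return mat


@dataclass(frozen=True)
class WeightedConnectome:
    """Symmetric non-negative connectivity matrix (e.g. streamline counts)."""

    weights: np.ndarray
    nodes: NodeTable

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        w = _check_square_symmetric(w, tol=0.0, what="weight")
        if np.any(w < 0):
            i, j = np.argwhere(w < 0)[0]
            raise ValueError(f"negative weight at ({i}, {j}): {w[i, j]}")
        if w.shape[0] != len(self.nodes):
            raise ValueError(
                f"matrix dimension {w.shape[0]} does not match node table "
                f"size {len(self.nodes)}"
            )
        object.__setattr__(self, "weights", w)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


@dataclass(frozen=True)
class BinaryConnectome:
    """Symmetric 0/1 adjacency with zero diagonal plus node metadata."""

    adjacency: np.ndarray
    nodes: NodeTable

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        a = a.astype(np.int8)
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if a.shape[0] != len(self.nodes):
            raise ValueError(
                f"matrix dimension {a.shape[0]} does not match node table "
                f"size {len(self.nodes)}"
            )
        object.__setattr__(self, "adjacency", a)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edge_set(self) -> set[tuple[int, int]]:
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        mask = self.adjacency[iu, ju] > 0
        return set(zip(iu[mask].tolist(), ju[mask].tolist()))


@dataclass
class Cohort:
    """Ordered collection of same-shape connectomes over one node set."""

    members: list
    nodes: NodeTable = field(default=None)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cohort must contain at least one member")
        kinds = {type(m) for m in self.members}
        if len(kinds) != 1:
            raise ValueError("cohort members must be all binary or all weighted")
        if self.nodes is None:
            self.nodes = self.members[0].nodes
        n = len(self.nodes)
        for k, m in enumerate(self.members):
            if m.n_nodes != n:
                raise ValueError(
                    f"member {k} has {m.n_nodes} nodes, expected {n}"
                )

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __getitem__(self, k):
        return self.members[k]

    @property
    def n_subjects(self) -> int:
        return len(self.members)

    @property
    def is_binary(self) -> bool:
        return isinstance(self.members[0], BinaryConnectome)


# ---------------------------------------------------------------------------
# file I/O


def read_matrix(path) -> np.ndarray:
    """Read a delimited numeric matrix; whitespace or comma separated."""
    path = Path(path)
    first = ""
    with open(path) as fh:
        for line in fh:
            if line.strip():
                first = line
                break
    delimiter = "," if "," in first else None
    mat = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    return mat


def write_matrix(mat: np.ndarray, path) -> None:
    """Write a matrix as whitespace-delimited text.

    Integer-valued matrices (including binary adjacencies) are written with
    integer formatting so that a read-write-read cycle is bit-identical.
    """
    mat = np.asarray(mat)
    if np.issubdtype(mat.dtype, np.integer) or np.all(mat == np.round(mat)):
        np.savetxt(path, mat, fmt="%d")
    else:
        np.savetxt(path, mat, fmt="%.17g")


def read_node_table(path) -> NodeTable:
    """Read node metadata TSV with columns node_id, label, hemisphere, x, y, z."""
    df = pd.read_csv(path, sep="\t")
    required = {"node_id", "label", "hemisphere", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"node table missing columns: {sorted(missing)}")
    df = df.sort_values("node_id")
    if not np.array_equal(df["node_id"].to_numpy(), np.arange(len(df))):
        raise ValueError("node_id must be consecutive integers 0..N-1")
    return NodeTable(
        labels=tuple(df["label"].astype(str)),
        hemispheres=tuple(df["hemisphere"].astype(str)),
        coords=df[["x", "y", "z"]].to_numpy(dtype=float),
    )


def write_node_table(nodes: NodeTable, path) -> None:
    nodes.to_frame().to_csv(path, sep="\t", index=False)


def read_connectome(matrix_path, node_table_path, *, tol: float = 1e-8) -> WeightedConnectome:
    """Read and validate a connectivity matrix with its node table.

    Near-symmetric matrices (asymmetry within ``tol`` absolute) are
    symmetrised as ``(W + W.T) / 2``; larger asymmetries are rejected with
    the offending indices.  The diagonal is forced to zero.
    """
    mat = read_matrix(matrix_path)
    nodes = read_node_table(node_table_path)
    mat = _check_square_symmetric(mat, tol=tol, what="connectivity")
    if mat.shape[0] != len(nodes):
        raise ValueError(
            f"matrix dimension {mat.shape[0]} does not match node table "
            f"size {len(nodes)}"
        )
    return WeightedConnectome(weights=mat, nodes=nodes)


# ---------------------------------------------------------------------------
# elementary transforms


def binarize(connectome: WeightedConnectome) -> BinaryConnectome:
    """Presence/absence adjacency: edge iff weight strictly positive."""
    if isinstance(connectome, BinaryConnectome):
        return connectome
    a = (connectome.weights > 0).astype(np.int8)
    return BinaryConnectome(adjacency=a, nodes=connectome.nodes)


def drop_regions(connectome, labels_to_drop: Iterable[str]):
    """Remove named regions, re-indexing the remaining nodes 0..N'-1.

    Works for binary and weighted connectomes; node order is preserved.
    """
    drop = set(labels_to_drop)
    unknown = drop - set(connectome.nodes.labels)
    if unknown:
        raise KeyError(f"unknown node labels: {sorted(unknown)}")
    keep = [i for i, lab in enumerate(connectome.nodes.labels) if lab not in drop]
    nodes = connectome.nodes.subset(keep)
    if isinstance(connectome, BinaryConnectome):
        a = connectome.adjacency[np.ix_(keep, keep)]
        return BinaryConnectome(adjacency=a, nodes=nodes)
    w = connectome.weights[np.ix_(keep, keep)]
    return WeightedConnectome(weights=w, nodes=nodes)


def density(connectome: BinaryConnectome) -> float:
    """Fraction of present edges among the N(N-1)/2 possible node pairs."""
    n = connectome.n_nodes
    if n < 2:
        raise ValueError("density undefined for fewer than 2 nodes")
    return connectome.n_edges / (n * (n - 1) / 2)
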