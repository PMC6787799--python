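"""Face-to-face NJ trees over plant and rhizobial cluster sets, with
mutual k-nearest-neighbor edges computed in the aligned embedding."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .seq_io import DistanceMatrix, RootedTree, neighbor_joining
from .topology_beta import ClusterSet, EmbeddedMixture

__all__ = [
    "Tanglegram",
    "cluster_nj_tree",
    "mutual_knn_edges",
    "export_tanglegram",
]


@dataclass
class Tanglegram:
    tree_left: RootedTree
    tree_right: RootedTree
    edges: list[tuple[int, int, float]]  # (left leaf, right leaf, distance)
    k: int


def cluster_nj_tree(cs: ClusterSet, prefix: str = "c") -> RootedTree:
    """NJ tree over the reduced between-cluster distance matrix; leaves are
    labeled by cluster index."""
    if cs.m < 2:
        raise ValueError("need at least 2 clusters for a tree")
    D = DistanceMatrix(
        cs.reduced_D.values, labels=[f"{prefix}{i}" for i in range(cs.m)]
    )
    return neighbor_joining(D)


def mutual_knn_edges(
    g_left: EmbeddedMixture, g_right: EmbeddedMixture, k: int = 5
) -> list[tuple[int, int, float]]:
    """Edges (i, j) where j is among the k nearest right-points to left
    point i AND i is among the k nearest left-points to right point j.

    Neighborhoods are over the opposite set only; ties break by index.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    XL, XR = g_left.coordinates, g_right.coordinates
    if XL.shape[1] != XR.shape[1]:
        raise ValueError("embeddings have different dimensions")
    nl, nr = XL.shape[0], XR.shape[0]
    if k > min(nl, nr):
        warnings.warn(f"k={k} capped to {min(nl, nr)}")
        k = min(nl, nr)
    dist = np.sqrt(((XL[:, None, :] - XR[None, :, :]) ** 2).sum(-1))

    def knn(row: np.ndarray) -> set[int]:
        order = sorted(range(len(row)), key=lambda t: (row[t], t))
        return set(order[:k])

    right_nn = [knn(dist[i]) for i in range(nl)]  # per left point
    left_nn = [knn(dist[:, j]) for j in range(nr)]  # per right point
    edges = []
    for i in range(nl):
        for j in range(nr):
            if j in right_nn[i] and i in left_nn[j]:
                edges.append((i, j, float(dist[i, j])))
    return edges


def export_tanglegram(t: Tanglegram, path_prefix) -> dict[str, str]:
    """Write the two Newick trees and the edge list TSV.

    Returns the written file paths keyed by role.
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    left = prefix.with_name(prefix.name + "_left.nwk")
    right = prefix.with_name(prefix.name + "_right.nwk")
    edges = prefix.with_name(prefix.name + "_edges.tsv")
    left.write_text(t.tree_left.newick() + "\n")
    right.write_text(t.tree_right.newick() + "\n")
    pd.DataFrame(
        t.edges, columns=["left_cluster", "right_cluster", "distance"]
    ).to_csv(edges, sep="\t", index=False)
    return {"left": str(left), "right": str(right), "edges": str(edges)}
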