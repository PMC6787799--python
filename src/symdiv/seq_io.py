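"""Aligned sequence pools: ingestion, haplotype collapsing, distances,
greedy OTU picking, neighbor-joining trees and clade-based pool filtering.

A *pool* is a gap-free multiple alignment of equal-length nucleotide
sequences sampled from one origin (plant / nodule / soil) of one species.
All downstream statistics operate on pools or on their collapsed
haplotype representation.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "AlignedPool",
    "HaplotypeSet",
    "DistanceMatrix",
    "OtuPartition",
    "TreeNode",
    "RootedTree",
    "read_aligned_fasta",
    "filter_pool",
    "collapse_haplotypes",
    "hamming_matrix",
    "greedy_identity_otus",
    "neighbor_joining",
    "biovar_partition_filter",
    "concat_pools",
]

ORIGINS = ("plant", "nodule", "soil")

_STOP_CODONS = {"TAA", "TAG", "TGA"}

# alignment alphabet accepted at ingestion; filter_pool narrows to ACGT
_ALLOWED_CHARS = set("ACGTN-")

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, "-": 5}


@dataclass
class AlignedPool:
    """Equal-length, gap-free (after filtering) nucleotide sequences."""

    pool_id: str
    species: str
    origin: str
    sequences: list[str]
    length: int = -1

    def __post_init__(self) -> None:
        if self.origin not in ORIGINS:
            raise ValueError(
                f"origin {self.origin!r} invalid; allowed: {ORIGINS}"
            )
        if len(self.sequences) < 2:
            raise ValueError(
                f"pool {self.pool_id!r}: need at least 2 sequences, "
                f"got {len(self.sequences)}"
            )
        self.sequences = [s.upper() for s in self.sequences]
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(
                f"pool {self.pool_id!r}: length mismatch, observed lengths "
                f"{sorted(lengths)}"
            )
        self.length = len(self.sequences[0])
        bad = set("".join(self.sequences)) - _ALLOWED_CHARS
        if bad:
            raise ValueError(
                f"pool {self.pool_id!r}: illegal characters {sorted(bad)}"
            )

    @property
    def n(self) -> int:
        return len(self.sequences)

    def encoded(self) -> np.ndarray:
        """(n, length) uint8 matrix, A/C/G/T/N/- coded 0..5."""
        flat = np.frombuffer(
            "".join(self.sequences).encode("ascii"), dtype=np.uint8
        )
        codes = np.full(128, 255, dtype=np.uint8)
        for base, code in _BASE_CODE.items():
            codes[ord(base)] = code
        return codes[flat].reshape(self.n, self.length)

    def replace_sequences(self, sequences: Sequence[str], suffix: str = "") -> "AlignedPool":
        return AlignedPool(
            pool_id=self.pool_id + suffix,
            species=self.species,
            origin=self.origin,
            sequences=list(sequences),
        )


@dataclass
class HaplotypeSet:
    """Unique haplotypes with sample frequencies, ordered by descending
    frequency (ties broken lexicographically)."""

    haplotypes: list[str]
    frequencies: np.ndarray
    counts: np.ndarray
    n_unique: int
    sample_size: int

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if len(set(self.haplotypes)) != len(self.haplotypes):
            raise ValueError("haplotypes not pairwise distinct")
        if abs(self.frequencies.sum() - 1.0) > 1e-12:
            raise ValueError("frequencies do not sum to 1")
        if (self.frequencies <= 0).any():
            raise ValueError("non-positive haplotype frequency")

    @property
    def length(self) -> int:
        return len(self.haplotypes[0]) if self.haplotypes else 0

    def index_of(self) -> dict[str, int]:
        return {h: i for i, h in enumerate(self.haplotypes)}


@dataclass
class DistanceMatrix:
    values: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("distance matrix not square")
        if len(self.labels) != n:
            raise ValueError("labels do not match matrix size")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix not symmetric")
        if np.diagonal(self.values).any():
            raise ValueError("nonzero diagonal")
        if (self.values < 0).any():
            raise ValueError("negative distances")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class OtuPartition:
    otu_centroids: list[str]
    otu_membership: dict[int, int]  # sequence index -> OTU index
    identity_threshold: float
    haplotype_otu: dict[str, int] = field(default_factory=dict)
    clade_assignment: dict[int, str] = field(default_factory=dict)
    per_pool_clade_counts: pd.DataFrame | None = None

    @property
    def n_otus(self) -> int:
        return len(self.otu_centroids)


# ---------------------------------------------------------------------------
# trees


@dataclass
class TreeNode:
    label: str | None = None
    length: float = 0.0  # edge length to parent
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self) -> str:
        if self.is_leaf():
            return f"{self.label}:{self.length:.10g}"
        inner = ",".join(c.newick() for c in self.children)
        lab = self.label or ""
        return f"({inner}){lab}:{self.length:.10g}"


@dataclass
class RootedTree:
    root: TreeNode
    negative_branches_clamped: bool = False

    def leaf_labels(self) -> list[str]:
        return [leaf.label for leaf in self.root.leaves()]

    def newick(self) -> str:
        if self.root.is_leaf():
            return f"{self.root.label};"
        inner = ",".join(c.newick() for c in self.root.children)
        return f"({inner});"

    def splits(self) -> dict[frozenset, float]:
        """Unrooted bipartition -> branch length map.

        Each split is keyed by the leaf set of the smaller side (ties broken
        by sorted label tuple); the two root edges merge into one split.
        """
        all_leaves = frozenset(self.leaf_labels())

        def canon(side: frozenset) -> frozenset:
            other = all_leaves - side
            if len(side) < len(other):
                return side
            if len(other) < len(side):
                return other
            return side if tuple(sorted(side)) <= tuple(sorted(other)) else other

        out: dict[frozenset, float] = {}

        def visit(node: TreeNode) -> frozenset:
            if node.is_leaf():
                below = frozenset([node.label])
            else:
                below = frozenset().union(*(visit(c) for c in node.children))
            if node is not self.root:
                key = canon(below)
                out[key] = out.get(key, 0.0) + node.length
            return below

        visit(self.root)
        return out


# ---------------------------------------------------------------------------
# ingestion & filtering


def _open_maybe_gzip(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_aligned_fasta(path, species: str, origin: str, pool_id: str | None = None) -> AlignedPool:
    """Read one pool from a (plain or gzipped) multi-FASTA alignment.

    Records must be non-empty and of equal length; gap/N characters are
    tolerated here and removed later by :func:`filter_pool`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with _open_maybe_gzip(path) as fh:
        records = list(SeqIO.parse(fh, "fasta"))
    if not records:
        raise ValueError(f"{path}: empty FASTA")
    seqs = [str(r.seq).upper() for r in records]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        modal = max(lengths, key=lambda L: sum(len(x) == L for x in seqs))
        offenders = [r.id for r, s in zip(records, seqs) if len(s) != modal]
        raise ValueError(
            f"{path}: length mismatch among records: {offenders[:20]}"
        )
    return AlignedPool(
        pool_id=pool_id or path.stem,
        species=species,
        origin=origin,
        sequences=seqs,
    )


def _has_internal_stop(seq: str, frame_offset: int) -> bool:
    usable = len(seq) - frame_offset
    n_codons = usable // 3
    for k in range(n_codons):
        codon = seq[frame_offset + 3 * k: frame_offset + 3 * k + 3]
        if codon in _STOP_CODONS:
            return True
    return False


def filter_pool(pool: AlignedPool, frame_offset: int = 0) -> tuple[AlignedPool, pd.DataFrame]:
    """Drop sequences with gaps/ambiguous bases or in-frame stop codons.

    Returns the cleaned pool and a removal report (index, reason).
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be 0, 1 or 2")
    keep: list[str] = []
    removed: list[dict] = []
    for i, seq in enumerate(pool.sequences):
        if set(seq) - set("ACGT"):
            removed.append({"index": i, "reason": "non-ACGT/gap characters"})
        elif _has_internal_stop(seq, frame_offset):
            removed.append({"index": i, "reason": "internal stop"})
        else:
            keep.append(seq)
    report = pd.DataFrame(removed, columns=["index", "reason"])
    if len(keep) < 2:
        raise ValueError(
            f"pool {pool.pool_id!r}: fewer than 2 sequences survive filtering"
        )
    if not removed:
        return pool, report
    return pool.replace_sequences(keep), report


def collapse_sequences(sequences: Sequence[str]) -> HaplotypeSet:
    """Collapse a raw sequence list to a HaplotypeSet (descending frequency,
    ties by lexicographic sequence order)."""
    counts: dict[str, int] = {}
    for s in sequences:
        counts[s] = counts.get(s, 0) + 1
    items = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    haps = [h for h, _ in items]
    cts = np.array([c for _, c in items], dtype=int)
    return HaplotypeSet(
        haplotypes=haps,
        frequencies=cts / len(sequences),
        counts=cts,
        n_unique=len(haps),
        sample_size=len(sequences),
    )


def collapse_haplotypes(pool: AlignedPool) -> HaplotypeSet:
    """Unique haplotypes with frequencies; descending frequency, ties by
    lexicographic sequence order."""
    counts: dict[str, int] = {}
    for s in pool.sequences:
        counts[s] = counts.get(s, 0) + 1
    items = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    haps = [h for h, _ in items]
    cts = np.array([c for _, c in items], dtype=int)
    return HaplotypeSet(
        haplotypes=haps,
        frequencies=cts / pool.n,
        counts=cts,
        n_unique=len(haps),
        sample_size=pool.n,
    )


def _encode(seqs: Sequence[str]) -> np.ndarray:
    flat = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    return flat.reshape(len(seqs), len(seqs[0]))


def hamming_matrix(hs: HaplotypeSet | Sequence[str], labels: list[str] | None = None) -> DistanceMatrix:
    """Pairwise count of mismatching positions (raw nucleotide differences)."""
    if isinstance(hs, HaplotypeSet):
        seqs = hs.haplotypes
    else:
        seqs = list(hs)
    mat = _encode(seqs)
    n = mat.shape[0]
    diffs = np.zeros((n, n), dtype=float)
    for i in range(n):
        diffs[i] = (mat != mat[i]).sum(axis=1)
    if labels is None:
        labels = [f"h{i}" for i in range(n)]
    return DistanceMatrix(values=diffs, labels=labels)


# ---------------------------------------------------------------------------
# OTU picking


def greedy_identity_otus(pool: AlignedPool, threshold: float = 0.95) -> OtuPartition:
    """Abundance-ordered greedy centroid clustering at an identity threshold.

    Haplotypes are processed in descending abundance; a haplotype joins the
    highest-identity existing centroid at or above the threshold (ties go to
    the earliest centroid), otherwise it founds a new OTU.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    hs = collapse_haplotypes(pool)
    L = hs.length
    centroids: list[str] = []
    cent_mat: list[np.ndarray] = []
    hap_otu: dict[str, int] = {}
    enc = _encode(hs.haplotypes)
    for idx, hap in enumerate(hs.haplotypes):
        row = enc[idx]
        best_otu, best_ident = -1, -1.0
        for c_idx, c_row in enumerate(cent_mat):
            ident = 1.0 - (row != c_row).sum() / L
            if ident > best_ident + 1e-15:
                best_otu, best_ident = c_idx, ident
        if best_otu >= 0 and best_ident >= threshold - 1e-12:
            hap_otu[hap] = best_otu
        else:
            centroids.append(hap)
            cent_mat.append(row)
            hap_otu[hap] = len(centroids) - 1
    membership = {i: hap_otu[s] for i, s in enumerate(pool.sequences)}
    return OtuPartition(
        otu_centroids=centroids,
        otu_membership=membership,
        identity_threshold=threshold,
        haplotype_otu=hap_otu,
    )


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(D: DistanceMatrix, outgroup_label: str | None = None) -> RootedTree:
    """Saitou–Nei neighbor joining with optional outgroup rooting.

    Negative branch lengths are clamped to zero (recorded on the tree).
    The root is placed at the midpoint of the outgroup's pendant edge when
    an outgroup is given, else at the midpoint of the final join edge.
    """
    n = D.n
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if outgroup_label is not None and outgroup_label not in D.labels:
        raise ValueError(f"outgroup {outgroup_label!r} not among labels")

    clamped = False
    # adjacency: node id -> list of (neighbor id, length)
    adj: dict[int, list[tuple[int, float]]] = {i: [] for i in range(n)}
    node_label: dict[int, str] = dict(enumerate(D.labels))
    next_id = n

    def add_edge(a: int, b: int, length: float) -> None:
        nonlocal clamped
        if length < 0:
            clamped = True
            length = 0.0
        adj.setdefault(a, []).append((b, length))
        adj.setdefault(b, []).append((a, length))

    active = list(range(n))
    dist = {i: {j: float(D.values[i, j]) for j in range(n)} for i in range(n)}

    last_edge: tuple[int, int] | None = None
    while len(active) > 2:
        nn = len(active)
        r = {i: sum(dist[i][j] for j in active if j != i) for i in active}
        best = None
        best_q = np.inf
        for ai in range(nn):
            for aj in range(ai + 1, nn):
                i, j = active[ai], active[aj]
                q = (nn - 2) * dist[i][j] - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q, best = q, (i, j)
        i, j = best  # type: ignore[misc]
        dij = dist[i][j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (nn - 2))
        lj = dij - li
        new = next_id
        next_id += 1
        add_edge(new, i, li)
        add_edge(new, j, lj)
        dist[new] = {}
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (dist[i][k] + dist[j][k] - dij)
            dist[new][k] = dk
            dist[k][new] = dk
        active = [k for k in active if k not in (i, j)] + [new]

    a, b = active
    add_edge(a, b, dist[a][b])
    last_edge = (a, b)

    # pick the edge on which to place the root
    if outgroup_label is not None:
        og_id = next(i for i, lab in node_label.items() if lab == outgroup_label)
        nbr, length = adj[og_id][0]
        root_edge = (og_id, nbr, length)
    else:
        la = max(0.0, dist[last_edge[0]][last_edge[1]])
        root_edge = (last_edge[0], last_edge[1], la)

    u, v, e_len = root_edge

    def build(node_id: int, parent_id: int, edge_len: float) -> TreeNode:
        node = TreeNode(label=node_label.get(node_id), length=edge_len)
        for nb, ln in adj[node_id]:
            if nb == parent_id:
                continue
            node.children.append(build(nb, node_id, ln))
        # suppress unlabeled unifurcations created by edge orientation
        if len(node.children) == 1 and node.label is None:
            child = node.children[0]
            child.length += node.length
            return child
        return node

    root = TreeNode(label=None, length=0.0)
    # remove the root edge from adjacency for orientation purposes
    adj[u] = [(nb, ln) for nb, ln in adj[u] if nb != v]
    adj[v] = [(nb, ln) for nb, ln in adj[v] if nb != u]
    root.children.append(build(u, -1, e_len / 2.0))
    root.children.append(build(v, -1, e_len / 2.0))
    return RootedTree(root=root, negative_branches_clamped=clamped)


# ---------------------------------------------------------------------------
# biovar clade partition and filtering


def concat_pools(pools: Iterable[AlignedPool], pool_id: str = "combined",
                 species: str = "combined", origin: str = "soil") -> AlignedPool:
    seqs: list[str] = []
    for p in pools:
        seqs.extend(p.sequences)
    return AlignedPool(pool_id=pool_id, species=species, origin=origin, sequences=seqs)


def _clade_bipartition(tree: RootedTree, otu_labels: set[str]) -> tuple[set[str], set[str]]:
    """Two clades from the root; an outgroup-only child is skipped over."""
    node = tree.root
    while True:
        kids = node.children
        if len(kids) != 2:
            raise ValueError("tree root is not binary")
        sides = [set(leaf.label for leaf in k.leaves()) for k in kids]
        og_side = [i for i, s in enumerate(sides) if not (s & otu_labels)]
        if og_side:
            node = kids[1 - og_side[0]]
            continue
        return sides[0] & otu_labels, sides[1] & otu_labels


def biovar_partition_filter(
    pools: Sequence[AlignedPool],
    otus: OtuPartition,
    tree: RootedTree,
) -> tuple[list[AlignedPool], dict]:
    """Assign each pool to the clade holding its sequence majority and drop
    minority ("improper") sequences; report per-pool improper fractions.

    The two clades come from the root bipartition of the OTU-centroid NJ
    tree (outgroup leaf, if present, is skipped).
    """
    otu_labels = {f"OTU{i}" for i in range(otus.n_otus)}
    side_a, side_b = _clade_bipartition(tree, otu_labels)
    clade_of_otu: dict[int, str] = {}
    for i in range(otus.n_otus):
        lab = f"OTU{i}"
        clade_of_otu[i] = "clade_A" if lab in side_a else "clade_B"
    otus.clade_assignment = clade_of_otu

    filtered: list[AlignedPool] = []
    report: dict[str, dict] = {}
    counts_rows = []
    for pool in pools:
        clades = []
        for s in pool.sequences:
            if s not in otus.haplotype_otu:
                raise KeyError(
                    f"sequence from pool {pool.pool_id!r} absent from OTU partition"
                )
            clades.append(clade_of_otu[otus.haplotype_otu[s]])
        n_a = clades.count("clade_A")
        n_b = len(clades) - n_a
        if n_a == n_b:
            raise ValueError(
                f"pool {pool.pool_id!r}: clade majority tie ({n_a} vs {n_b})"
            )
        major = "clade_A" if n_a > n_b else "clade_B"
        keep = [s for s, c in zip(pool.sequences, clades) if c == major]
        improper = 1.0 - len(keep) / len(clades)
        filtered.append(pool.replace_sequences(keep))
        report[pool.pool_id] = {
            "assigned_clade": major,
            "improper_fraction": improper,
            "n_kept": len(keep),
            "n_removed": len(clades) - len(keep),
        }
        counts_rows.append(
            {"pool_id": pool.pool_id, "clade_A": n_a, "clade_B": n_b}
        )
    otus.per_pool_clade_counts = pd.DataFrame(counts_rows)
    return filtered, report


def write_haplotype_table(hs: HaplotypeSet, path) -> None:
    pd.DataFrame(
        {
            "haplotype": hs.haplotypes,
            "count": hs.counts,
            "frequency": hs.frequencies,
        }
    ).to_csv(path, sep="\t", index=False)


def write_admixture_report(report: Mapping, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
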