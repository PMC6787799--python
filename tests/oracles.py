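"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive (double loops, explicit enumeration)
and shares no code with the package implementations it checks.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np

GENETIC_CODE = {}
_bases = "TCAG"
_aas = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, (_a, _b, _c) in enumerate(itertools.product(_bases, repeat=3)):
    GENETIC_CODE[_a + _b + _c] = _aas[_i]


def brute_pi(seqs: list[str]) -> float:
    n = len(seqs)
    L = len(seqs[0])
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            d = sum(a != b for a, b in zip(seqs[i], seqs[j]))
            total += d / L
    return total / (n * (n - 1) / 2)


def brute_hamming(seqs: list[str]) -> np.ndarray:
    n = len(seqs)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = sum(a != b for a, b in zip(seqs[i], seqs[j]))
    return out


def brute_hap_counts(seqs: list[str]) -> dict[str, int]:
    out: dict[str, int] = {}
    for s in seqs:
        out[s] = out.get(s, 0) + 1
    return out


# --- Nei-Gojobori ----------------------------------------------------------

def brute_codon_sites(codon: str) -> tuple[float, float]:
    aa = GENETIC_CODE[codon]
    syn = 0
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if GENETIC_CODE[alt] == aa:
                syn += 1
    return syn / 3.0, 3.0 - syn / 3.0


def brute_codon_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (syn, nonsyn) differences; stop-free pathways only,
    falling back to all pathways when none avoid stops."""
    if c1 == c2:
        return 0.0, 0.0
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    paths_ok, paths_all = [], []
    for order in itertools.permutations(diff_pos):
        cur = c1
        syn = nonsyn = 0
        hit_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if GENETIC_CODE[nxt] == "*" and nxt != c2:
                hit_stop = True
            if GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        paths_all.append((syn, nonsyn))
        if not hit_stop:
            paths_ok.append((syn, nonsyn))
    paths = paths_ok or paths_all
    return (
        sum(p[0] for p in paths) / len(paths),
        sum(p[1] for p in paths) / len(paths),
    )


def brute_pn_ps(seqs: list[str]) -> tuple[float, float]:
    """(pN, pS) for frame-0 codon-aligned sequences."""
    n = len(seqs)
    site_s = []
    site_n = []
    for s in seqs:
        ssum = nsum = 0.0
        for k in range(0, len(s) - len(s) % 3, 3):
            a, b = brute_codon_sites(s[k:k + 3])
            ssum += a
            nsum += b
        site_s.append(ssum)
        site_n.append(nsum)
    mean_s = sum(site_s) / n
    mean_n = sum(site_n) / n
    tot_sd = tot_nd = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(0, len(seqs[i]) - len(seqs[i]) % 3, 3):
                ci, cj = seqs[i][k:k + 3], seqs[j][k:k + 3]
                if ci != cj:
                    sd, nd = brute_codon_diffs(ci, cj)
                    tot_sd += sd
                    tot_nd += nd
    pairs = n * (n - 1) / 2
    pS = (tot_sd / pairs) / mean_s if mean_s else 0.0
    pN = (tot_nd / pairs) / mean_n if mean_n else 0.0
    return pN, pS


def brute_tajimas_d(seqs: list[str]) -> float | None:
    n = len(seqs)
    L = len(seqs[0])
    S = sum(1 for k in range(L) if len({s[k] for s in seqs}) > 1)
    if S == 0:
        return None
    pi_total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            pi_total += sum(a != b for a, b in zip(seqs[i], seqs[j]))
    pi_total /= n * (n - 1) / 2
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi_total - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


# --- mutual kNN ------------------------------------------------------------

def brute_mutual_knn(XL: np.ndarray, XR: np.ndarray, k: int):
    def dist(a, b):
        return float(np.sqrt(((a - b) ** 2).sum()))

    edges = []
    for i in range(len(XL)):
        row = sorted(range(len(XR)), key=lambda j: (dist(XL[i], XR[j]), j))
        nn_i = set(row[:k])
        for j in range(len(XR)):
            col = sorted(range(len(XL)), key=lambda t: (dist(XL[t], XR[j]), t))
            if j in nn_i and i in set(col[:k]):
                edges.append((i, j))
    return edges


# --- Mann-Whitney exact ----------------------------------------------------

def brute_mw_exact_p(a: list[float], b: list[float], alternative: str) -> float:
    """Exact one-sided p by enumerating all rank assignments (no ties)."""
    n1, n2 = len(a), len(b)
    combined = sorted(a + b)
    ranks_a = [combined.index(x) + 1 for x in a]
    u_obs = sum(ranks_a) - n1 * (n1 + 1) / 2
    count = 0
    total = comb(n1 + n2, n1)
    for subset in itertools.combinations(range(1, n1 + n2 + 1), n1):
        u = sum(subset) - n1 * (n1 + 1) / 2
        if alternative == "a_less" and u <= u_obs + 1e-9:
            count += 1
        if alternative == "a_greater" and u >= u_obs - 1e-9:
            count += 1
    return count / total


# --- trees -----------------------------------------------------------------

def random_additive_tree(rng: np.random.Generator, n_taxa: int):
    """Random binary tree with positive branch lengths; returns
    (distance matrix, labels, splits dict as canonical frozenset -> length)."""
    labels = [f"t{i}" for i in range(n_taxa)]
    nodes = [(i, frozenset([labels[i]])) for i in range(n_taxa)]
    next_id = n_taxa
    children: dict[int, list[tuple[int, float]]] = {}
    leafsets = {i: s for i, s in nodes}
    active = [i for i, _ in nodes]
    while len(active) > 1:
        i, j = rng.choice(len(active), size=2, replace=False)
        a, b = active[int(i)], active[int(j)]
        la = float(rng.uniform(0.5, 3.0))
        lb = float(rng.uniform(0.5, 3.0))
        children[next_id] = [(a, la), (b, lb)]
        leafsets[next_id] = leafsets[a] | leafsets[b]
        active = [x for x in active if x not in (a, b)] + [next_id]
        next_id += 1
    root = active[0]

    # leaf -> distance accumulation
    dist_to_leaf: dict[str, float] = {}
    D = np.zeros((n_taxa, n_taxa))
    index = {lab: i for i, lab in enumerate(labels)}

    def walk(node: int, acc: float, found: dict[str, float]):
        if node < n_taxa:
            found[labels[node]] = acc
            return
        for child, ln in children[node]:
            walk(child, acc + ln, found)

    # pairwise distances via path through tree: compute per-node leaf dists
    memo: dict[int, dict[str, float]] = {}

    def leaf_dists(node: int) -> dict[str, float]:
        if node in memo:
            return memo[node]
        out: dict[str, float] = {}
        if node < n_taxa:
            out[labels[node]] = 0.0
        else:
            for child, ln in children[node]:
                for lab, d in leaf_dists(child).items():
                    out[lab] = d + ln
        memo[node] = out
        return out

    def fill(node: int):
        if node < n_taxa:
            return
        kids = children[node]
        for (c1, l1), (c2, l2) in itertools.combinations(kids, 2):
            d1 = leaf_dists(c1)
            d2 = leaf_dists(c2)
            for lab1, x in d1.items():
                for lab2, y in d2.items():
                    D[index[lab1], index[lab2]] = x + l1 + y + l2
                    D[index[lab2], index[lab1]] = x + l1 + y + l2
        for child, _ in kids:
            fill(child)

    fill(root)

    all_leaves = frozenset(labels)

    def canon(side: frozenset) -> frozenset:
        other = all_leaves - side
        if len(side) < len(other):
            return side
        if len(other) < len(side):
            return other
        return side if tuple(sorted(side)) <= tuple(sorted(other)) else other

    splits: dict[frozenset, float] = {}

    def collect(node: int):
        if node < n_taxa:
            return
        for child, ln in children[node]:
            key = canon(leafsets[child])
            splits[key] = splits.get(key, 0.0) + ln
            collect(child)

    collect(root)
    # drop the trivial whole-set split if any (root had 2 children: their two
    # edges form one unrooted branch and are already summed via canon)
    splits.pop(canon(all_leaves), None)
    return D, labels, splits
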