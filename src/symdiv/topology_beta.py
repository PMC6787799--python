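"""Topological beta-diversity between gene pools.

Pipeline: frequency-weighted agglomerative clustering of haplotypes ->
median normalization with a zero-sigma substitution rule -> metric MDS into
K-dimensional space -> isotropic Gaussian mixture per pool -> Procrustes
superimposition (rotation, translation, mirror reflection) minimizing a
normalized L2 mixture dissimilarity (DeltaG) -> bootstrap + one-sided
Mann-Whitney inference on nodule-vs-soil DeltaG sets.

The joint-embed/split protocol clusters and embeds the pooled rhizobial
(nodule + soil) haplotypes once, then splits per-origin mixtures on the
shared coordinates so both comparisons treat identical haplotypes
identically.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from sklearn.manifold import smacof

from .seq_io import (
    AlignedPool,
    DistanceMatrix,
    HaplotypeSet,
    collapse_haplotypes,
    collapse_sequences,
    hamming_matrix,
)
from .selection import ContrastResult

__all__ = [
    "ClusterSet",
    "EmbeddedMixture",
    "DeltaGResult",
    "TopologyTestResult",
    "JointEmbedding",
    "frequency_weighted_clustering",
    "normalize_clusters",
    "metric_mds",
    "MdsResult",
    "build_gmm",
    "delta_g",
    "procrustes_min_delta_g",
    "embed_pool",
    "joint_rhizobia_embedding",
    "origin_mixture",
    "joint_embed_split",
    "bootstrap_delta_g",
    "mann_whitney_one_sided",
]


# ---------------------------------------------------------------------------
# cluster sets


@dataclass
class ClusterSet:
    m: int
    frequencies: np.ndarray
    sigmas: np.ndarray
    reduced_D: DistanceMatrix
    member_map: np.ndarray  # haplotype index -> cluster index
    normalized: bool = False
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        self.member_map = np.asarray(self.member_map, dtype=int)
        if len(self.frequencies) != self.m or len(self.sigmas) != self.m:
            raise ValueError("cluster parameter lengths != m")
        if abs(self.frequencies.sum() - 1.0) > 1e-12:
            raise ValueError("cluster frequencies do not sum to 1")
        if (self.sigmas < 0).any():
            raise ValueError("negative sigma")
        if self.reduced_D.n != self.m:
            raise ValueError("reduced distance matrix size != m")


def frequency_weighted_clustering(
    D: DistanceMatrix, f: np.ndarray, m: int
) -> ClusterSet:
    """Agglomerate haplotypes down to m clusters.

    At each step the minimum-distance pair (ties: smallest current index
    pair) merges; the merged cluster's distance to cluster k is the
    frequency-weighted average (D_ik f_i + D_jk f_j)/(f_i + f_j), its
    frequency is f_i + f_j and its mean difference sigma is the merge
    distance D_ij.
    """
    f = np.asarray(f, dtype=float)
    n = len(f)
    if not 1 <= m <= n:
        raise ValueError(f"m={m} infeasible for {n} haplotypes")
    if D.n != n:
        raise ValueError("distance matrix size != number of frequencies")
    cur = D.values.astype(float).copy()
    fs = f.copy().tolist()
    sigmas = [0.0] * n
    members: list[list[int]] = [[i] for i in range(n)]
    while len(fs) > m:
        k = len(fs)
        iu, ju = np.triu_indices(k, 1)
        idx = int(np.argmin(cur[iu, ju]))  # row-major => smallest (i, j) tie-break
        i, j = int(iu[idx]), int(ju[idx])
        dij = cur[i, j]
        fi, fj = fs[i], fs[j]
        dvec = (cur[i] * fi + cur[j] * fj) / (fi + fj)
        cur[i, :] = dvec
        cur[:, i] = dvec
        cur[i, i] = 0.0
        cur = np.delete(np.delete(cur, j, axis=0), j, axis=1)
        fs[i] = fi + fj
        sigmas[i] = float(dij)
        members[i] = members[i] + members[j]
        del fs[j], sigmas[j], members[j]
    member_map = np.empty(n, dtype=int)
    for c_idx, mem in enumerate(members):
        member_map[mem] = c_idx
    return ClusterSet(
        m=m,
        frequencies=np.array(fs),
        sigmas=np.array(sigmas),
        reduced_D=DistanceMatrix(cur, labels=[f"c{i}" for i in range(m)]),
        member_map=member_map,
    )


def normalize_clusters(
    cs: ClusterSet, zero_sigma_rule: str = "product_min"
) -> ClusterSet:
    """Divide distances and sigmas by the median off-diagonal distance and
    substitute zero sigmas.

    zero_sigma_rule:
      * "product_min": sigma_i <- min over clusters with sigma != 0 of
        (sigma_j * f_j)   [default reading]
      * "own_f":       sigma_i <- (min over sigma != 0 of sigma_j) * f_i
    If every sigma is zero, sigmas are set to 0.1 x (normalized median) and
    the result is flagged degenerate.
    """
    if zero_sigma_rule not in ("product_min", "own_f"):
        raise ValueError("unknown zero_sigma_rule")
    D = cs.reduced_D.values
    m = cs.m
    degenerate = False
    if m > 1:
        iu, ju = np.triu_indices(m, 1)
        med = float(np.median(D[iu, ju]))
    else:
        med = 0.0
    if med <= 0.0:
        med = 1.0
        degenerate = True
    Dn = D / med
    sn = cs.sigmas / med
    nz = sn > 0
    if nz.any():
        if zero_sigma_rule == "product_min":
            fill = float(np.min(sn[nz] * cs.frequencies[nz]))
            sn = np.where(nz, sn, fill)
        else:
            min_sigma = float(np.min(sn[nz]))
            sn = np.where(nz, sn, min_sigma * cs.frequencies)
    else:
        sn = np.full(m, 0.1)
        degenerate = True
    return ClusterSet(
        m=m,
        frequencies=cs.frequencies.copy(),
        sigmas=sn,
        reduced_D=DistanceMatrix(Dn, labels=list(cs.reduced_D.labels)),
        member_map=cs.member_map.copy(),
        normalized=True,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# metric MDS


@dataclass
class MdsResult:
    coordinates: np.ndarray
    stress: float
    converged: bool


def _classical_scaling(D: np.ndarray, K: int) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:K]
    w = np.clip(w[order], 0.0, None)
    X = V[:, order] * np.sqrt(w)
    if X.shape[1] < K:
        X = np.hstack([X, np.zeros((n, K - X.shape[1]))])
    # deterministic sign: largest-magnitude coordinate positive per axis
    for k in range(K):
        col = X[:, k]
        if len(col) and col[np.argmax(np.abs(col))] < 0:
            X[:, k] = -col
    return X


def _raw_stress(D: np.ndarray, X: np.ndarray) -> float:
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    iu, ju = np.triu_indices(D.shape[0], 1)
    return float(((d[iu, ju] - D[iu, ju]) ** 2).sum())


def metric_mds(D: np.ndarray | DistanceMatrix, K: int = 3, seed: int = 0,
               max_iter: int = 300) -> MdsResult:
    """Raw-stress majorization (SMACOF) initialized from classical scaling.

    Deterministic given the input; the result is centered at the origin.
    """
    if isinstance(D, DistanceMatrix):
        D = D.values
    D = np.asarray(D, dtype=float)
    if K < 1:
        raise ValueError("K must be >= 1")
    n = D.shape[0]
    if n == 1:
        return MdsResult(np.zeros((1, K)), 0.0, True)
    X0 = _classical_scaling(D, K)
    if not np.any(D > 0):
        return MdsResult(np.zeros((n, K)), 0.0, True)
    X, stress, n_iter = smacof(
        D,
        metric=True,
        n_components=K,
        init=X0,
        n_init=1,
        max_iter=max_iter,
        eps=1e-10,
        random_state=seed,
        return_n_iter=True,
        normalized_stress=False,
    )
    X = X - X.mean(axis=0)
    return MdsResult(X, float(stress), bool(n_iter < max_iter))


# ---------------------------------------------------------------------------
# Gaussian mixtures and DeltaG


@dataclass
class EmbeddedMixture:
    coordinates: np.ndarray  # (m, K)
    frequencies: np.ndarray
    sigmas: np.ndarray
    K: int = field(default=0)

    def __post_init__(self) -> None:
        self.coordinates = np.atleast_2d(np.asarray(self.coordinates, dtype=float))
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        self.K = self.coordinates.shape[1]
        if (self.sigmas <= 0).any():
            raise ValueError("sigmas must be positive (run normalize_clusters)")
        if not (
            len(self.frequencies) == len(self.sigmas) == self.coordinates.shape[0]
        ):
            raise ValueError("component count mismatch")

    @property
    def m(self) -> int:
        return self.coordinates.shape[0]

    def pdf(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        d2 = ((pts[:, None, :] - self.coordinates[None, :, :]) ** 2).sum(-1)
        var = self.sigmas**2
        comp = (2 * np.pi * var) ** (-self.K / 2) * np.exp(-d2 / (2 * var))
        return comp @ self.frequencies


def build_gmm(coords: np.ndarray, f: np.ndarray, sigmas: np.ndarray) -> EmbeddedMixture:
    """Isotropic GMM with component weights f, centers coords and standard
    deviations sigmas."""
    return EmbeddedMixture(coordinates=coords, frequencies=f, sigmas=sigmas)


def _cross_l2(
    X1: np.ndarray, f1: np.ndarray, s1: np.ndarray,
    X2: np.ndarray, f2: np.ndarray, s2: np.ndarray, K: int,
) -> float:
    """Closed-form integral of G1*G2 (Gaussian product integral)."""
    d2 = ((X1[:, None, :] - X2[None, :, :]) ** 2).sum(-1)
    v = (s1**2)[:, None] + (s2**2)[None, :]
    vals = (2 * np.pi * v) ** (-K / 2) * np.exp(-d2 / (2 * v))
    return float(f1 @ vals @ f2)


def _self_l2(g: EmbeddedMixture) -> float:
    return _cross_l2(
        g.coordinates, g.frequencies, g.sigmas,
        g.coordinates, g.frequencies, g.sigmas, g.K,
    )


def delta_g(g1: EmbeddedMixture, g2: EmbeddedMixture) -> float:
    """Normalized L2 dissimilarity:
    DeltaG = integral (G1-G2)^2 / sqrt(integral G1^2 * integral G2^2)."""
    if g1.K != g2.K:
        raise ValueError("dimension mismatch")
    i11 = _self_l2(g1)
    i22 = _self_l2(g2)
    i12 = _cross_l2(
        g1.coordinates, g1.frequencies, g1.sigmas,
        g2.coordinates, g2.frequencies, g2.sigmas, g1.K,
    )
    val = (i11 + i22 - 2 * i12) / math.sqrt(i11 * i22)
    return max(val, 0.0)


# ---------------------------------------------------------------------------
# Procrustes alignment


@dataclass
class DeltaGResult:
    delta_g: float
    rotation: np.ndarray
    translation: np.ndarray  # for y = x @ R.T + t on raw coordinates
    reflection: bool
    converged: bool
    # offset in the centered parametrization (useful as a warm start)
    translation_centered: np.ndarray | None = None


def _rotation_from_params(theta: np.ndarray, K: int) -> np.ndarray:
    """exp of a skew-symmetric matrix built from K(K-1)/2 parameters."""
    if K == 1:
        return np.eye(1)
    if K == 2:
        c, s = math.cos(theta[0]), math.sin(theta[0])
        return np.array([[c, -s], [s, c]])
    if K == 3:
        w = np.asarray(theta, dtype=float)
        t = np.linalg.norm(w)
        Wx = np.array(
            [[0, -w[2], w[1]], [w[2], 0, -w[0]], [-w[1], w[0], 0]]
        )
        if t < 1e-12:
            return np.eye(3) + Wx
        return (
            np.eye(3)
            + math.sin(t) / t * Wx
            + (1 - math.cos(t)) / t**2 * (Wx @ Wx)
        )
    A = np.zeros((K, K))
    iu, ju = np.triu_indices(K, 1)
    A[iu, ju] = theta
    A[ju, iu] = -theta
    from scipy.linalg import expm

    return expm(A)


def _weighted_moments(g: EmbeddedMixture) -> tuple[np.ndarray, np.ndarray]:
    mu = g.frequencies @ g.coordinates
    Xc = g.coordinates - mu
    C = (Xc * g.frequencies[:, None]).T @ Xc
    return mu, C


def _principal_axes(C: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    V = V[:, order]
    for k in range(V.shape[1]):
        col = V[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            V[:, k] = -col
    return V


def procrustes_min_delta_g(
    g_ref: EmbeddedMixture,
    g_mov: EmbeddedMixture,
    seed: int = 0,
    n_starts: int = 20,
    init_rotation: np.ndarray | None = None,
    init_translation: np.ndarray | None = None,
    maxiter: int = 300,
    axis_starts: bool = True,
) -> DeltaGResult:
    """Minimize DeltaG over rigid transforms + reflection of g_mov.

    Starts: principal-axes alignment of the frequency-weighted component
    covariances with all 2^K axis-sign combinations (covering reflections),
    plus n_starts random orthogonal matrices, each refined by local
    (Nelder-Mead) optimization over rotation parameters and translation.
    An optional (init_rotation, init_translation) warm start is prepended.
    """
    if g_ref.K != g_mov.K:
        raise ValueError("dimension mismatch")
    K = g_ref.K
    d_rot = K * (K - 1) // 2
    rng = np.random.default_rng(seed)

    mu_r, C_r = _weighted_moments(g_ref)
    mu_m, C_m = _weighted_moments(g_mov)
    Xc = g_mov.coordinates - mu_m
    U_r = _principal_axes(C_r)
    U_m = _principal_axes(C_m)

    i11 = _self_l2(g_ref)
    i22 = _self_l2(g_mov)  # invariant under rigid transforms
    norm = math.sqrt(i11 * i22)
    base = (i11 + i22) / norm

    def eval_transform(R: np.ndarray, t: np.ndarray) -> float:
        Y = Xc @ R.T + mu_r + t
        i12 = _cross_l2(
            g_ref.coordinates, g_ref.frequencies, g_ref.sigmas,
            Y, g_mov.frequencies, g_mov.sigmas, K,
        )
        return max(base - 2 * i12 / norm, 0.0)

    starts: list[tuple[np.ndarray, np.ndarray]] = []
    if init_rotation is not None:
        t0 = (
            np.zeros(K)
            if init_translation is None
            else np.asarray(init_translation, dtype=float)
        )
        starts.append((np.asarray(init_rotation, dtype=float), t0))
    if axis_starts:
        for signs in itertools.product((1.0, -1.0), repeat=K):
            starts.append((U_r @ np.diag(signs) @ U_m.T, np.zeros(K)))
    for _ in range(n_starts):
        M = rng.normal(size=(K, K))
        Q, R_ = np.linalg.qr(M)
        Q = Q * np.sign(np.diag(R_))
        if rng.random() < 0.5:
            Q[:, 0] = -Q[:, 0]
        starts.append((Q, np.zeros(K)))

    best_val = np.inf
    best_R = np.eye(K)
    best_t = np.zeros(K)
    converged = False

    def refine(S0: np.ndarray, t_init: np.ndarray, budget: int):
        def obj(p: np.ndarray) -> float:
            R = S0 @ _rotation_from_params(p[:d_rot], K)
            return eval_transform(R, t_init + p[d_rot:])

        res = optimize.minimize(
            obj,
            np.zeros(d_rot + K),
            method="Nelder-Mead",
            options={
                "maxiter": budget,
                "xatol": 1e-10,
                "fatol": 1e-14,
            },
        )
        R = S0 @ _rotation_from_params(res.x[:d_rot], K)
        return float(res.fun), R, t_init + res.x[d_rot:], bool(res.success)

    for S0, t_init in starts:
        val, R, t, ok = refine(S0, t_init, maxiter)
        if val < best_val:
            best_val, best_R, best_t, converged = val, R, t, ok
    if len(starts) > 1:  # polish the winner
        val, R, t, ok = refine(best_R, best_t, 4 * maxiter)
        if val < best_val:
            best_val, best_R, best_t, converged = val, R, t, ok

    # report translation for y = x @ R.T + t on raw (uncentered) coordinates
    t_full = mu_r + best_t - mu_m @ best_R.T
    return DeltaGResult(
        delta_g=best_val,
        rotation=best_R,
        translation=t_full,
        reflection=bool(np.linalg.det(best_R) < 0),
        converged=converged,
        translation_centered=best_t,
    )


# ---------------------------------------------------------------------------
# joint embed / split protocol


@dataclass
class JointEmbedding:
    clusters: ClusterSet  # normalized
    coordinates: np.ndarray
    haplotypes: HaplotypeSet  # joint rhizobial haplotypes
    origin_hap_counts: dict[str, np.ndarray]
    K: int


def _embed_clusters(
    cs: ClusterSet, K: int, seed: int, zero_sigma_rule: str
) -> tuple[ClusterSet, np.ndarray]:
    csn = normalize_clusters(cs, zero_sigma_rule)
    mds = metric_mds(csn.reduced_D, K=K, seed=seed)
    return csn, mds.coordinates


def embed_pool_details(
    pool: AlignedPool, m: int, K: int = 3, seed: int = 0,
    zero_sigma_rule: str = "product_min",
) -> tuple[ClusterSet, np.ndarray, EmbeddedMixture]:
    """Cluster, normalize and embed a single pool; returns the normalized
    cluster set, the MDS coordinates and the mixture."""
    hs = collapse_haplotypes(pool)
    D = hamming_matrix(hs)
    cs = frequency_weighted_clustering(D, hs.frequencies, m)
    csn, coords = _embed_clusters(cs, K, seed, zero_sigma_rule)
    return csn, coords, build_gmm(coords, csn.frequencies, csn.sigmas)


def embed_pool(
    pool: AlignedPool, m: int, K: int = 3, seed: int = 0,
    zero_sigma_rule: str = "product_min",
) -> EmbeddedMixture:
    """Cluster, normalize and embed a single pool into a GMM."""
    return embed_pool_details(pool, m, K, seed, zero_sigma_rule)[2]


def joint_rhizobia_embedding(
    nodule_pool: AlignedPool,
    soil_pool: AlignedPool,
    m: int,
    K: int = 3,
    seed: int = 0,
    zero_sigma_rule: str = "product_min",
) -> JointEmbedding:
    """Cluster + embed the pooled nodule+soil haplotypes once."""
    joint = collapse_sequences(nodule_pool.sequences + soil_pool.sequences)
    D = hamming_matrix(joint)
    cs = frequency_weighted_clustering(D, joint.frequencies, m)
    csn, coords = _embed_clusters(cs, K, seed, zero_sigma_rule)
    hap_index = joint.index_of()
    counts = {}
    for name, pool in (("nodule", nodule_pool), ("soil", soil_pool)):
        c = np.zeros(joint.n_unique, dtype=int)
        for s in pool.sequences:
            c[hap_index[s]] += 1
        if c.sum() == 0:
            raise ValueError(f"origin {name!r} has no sequences")
        counts[name] = c
    return JointEmbedding(
        clusters=csn,
        coordinates=coords,
        haplotypes=joint,
        origin_hap_counts=counts,
        K=K,
    )


def origin_mixture(je: JointEmbedding, hap_counts: np.ndarray) -> EmbeddedMixture:
    """Per-origin mixture on the shared joint coordinates; clusters with
    zero origin frequency are omitted."""
    total = hap_counts.sum()
    if total == 0:
        raise ValueError("origin has all-zero frequencies")
    cluster_counts = np.zeros(je.clusters.m)
    np.add.at(cluster_counts, je.clusters.member_map, hap_counts)
    f = cluster_counts / total
    mask = f > 0
    return build_gmm(
        je.coordinates[mask], f[mask], je.clusters.sigmas[mask]
    )


def joint_embed_split(
    plant_pool: AlignedPool,
    nodule_pool: AlignedPool,
    soil_pool: AlignedPool,
    m: int = 10,
    K: int = 3,
    seed: int = 0,
    zero_sigma_rule: str = "product_min",
) -> tuple[EmbeddedMixture, EmbeddedMixture, EmbeddedMixture]:
    g_plant = embed_pool(plant_pool, m=m, K=K, seed=seed,
                         zero_sigma_rule=zero_sigma_rule)
    je = joint_rhizobia_embedding(
        nodule_pool, soil_pool, m=m, K=K, seed=seed + 1,
        zero_sigma_rule=zero_sigma_rule,
    )
    g_nodule = origin_mixture(je, je.origin_hap_counts["nodule"])
    g_soil = origin_mixture(je, je.origin_hap_counts["soil"])
    return g_plant, g_nodule, g_soil


# ---------------------------------------------------------------------------
# bootstrap + Mann-Whitney


@dataclass
class TopologyTestResult:
    delta_g_nodule: np.ndarray
    delta_g_soil: np.ndarray
    delta_g_nodule_full: float
    delta_g_soil_full: float
    U_statistic: float
    p_value: float
    alpha: float
    significant: bool


def mann_whitney_one_sided(
    a, b, alternative: str = "a_less", alpha: float = 0.01
) -> ContrastResult:
    """Mann-Whitney U. Exact tail enumeration when min(n) <= 8 and there are
    no ties; tie-corrected, continuity-corrected normal approximation
    otherwise."""
    if alternative not in ("a_less", "a_greater"):
        raise ValueError("alternative must be 'a_less' or 'a_greater'")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("empty sample")
    combined = np.concatenate([a, b])
    from scipy.stats import rankdata

    ranks = rankdata(combined)
    R1 = ranks[:n1].sum()
    U1 = R1 - n1 * (n1 + 1) / 2.0
    has_ties = len(np.unique(combined)) < n1 + n2

    if min(n1, n2) <= 8 and not has_ties:
        dist = _u_count_distribution(n1, n2)
        total = dist.sum()
        u = int(round(U1))
        if alternative == "a_less":
            p = float(dist[: u + 1].sum() / total)
        else:
            p = float(dist[u:].sum() / total)
    else:
        mu = n1 * n2 / 2.0
        n = n1 + n2
        _, tie_counts = np.unique(combined, return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts)).sum())
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:
            p = 0.5
        else:
            from scipy.stats import norm

            sd = math.sqrt(var)
            if alternative == "a_less":
                p = float(norm.cdf((U1 - mu + 0.5) / sd))
            else:
                p = float(norm.sf((U1 - mu - 0.5) / sd))
    return ContrastResult(
        statistic=float(U1), p_value=p, alternative=alternative, alpha=alpha
    )


def _u_count_distribution(n1: int, n2: int) -> np.ndarray:
    """Counts of rank arrangements for each U value (no ties).

    Recurrence: N(u | n1, n2) = N(u - n2 | n1-1, n2) + N(u | n1, n2-1).
    """
    maxu = n1 * n2
    # rows: current n1' from 0..n1; each row is an array over j = 0..n2
    prev = [np.array([1.0] + [0.0] * maxu) for _ in range(n2 + 1)]
    for _i in range(1, n1 + 1):
        cur = [np.zeros(maxu + 1) for _ in range(n2 + 1)]
        cur[0][0] = 1.0
        for j in range(1, n2 + 1):
            shifted = np.zeros(maxu + 1)
            shifted[j:] = prev[j][: maxu + 1 - j]
            cur[j] = shifted + cur[j - 1]
        prev = cur
    return prev[n2]


def bootstrap_delta_g(
    plant_pool: AlignedPool,
    nodule_pool: AlignedPool,
    soil_pool: AlignedPool,
    m: int = 10,
    K: int = 3,
    n_boot: int = 100,
    seed: int = 0,
    n_starts: int = 20,
    alpha: float = 0.01,
    zero_sigma_rule: str = "product_min",
    warm_start: bool = True,
    refine_maxiter: int = 120,
) -> TopologyTestResult:
    """Paired bootstrap DeltaG sets for plant-vs-nodule and plant-vs-soil.

    Joint clustering and MDS are computed once on the full data and held
    fixed; each replicate resamples sequences with replacement within each
    rhizobial origin, recomputes per-origin cluster frequencies through the
    fixed member map, and re-aligns the rebuilt mixture against the fixed
    plant mixture. With warm_start the full-data optimal transform seeds
    each replicate's local refinement; warm_start=False reruns the full
    Procrustes search per replicate.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    g_plant = embed_pool(plant_pool, m=m, K=K, seed=seed,
                         zero_sigma_rule=zero_sigma_rule)
    je = joint_rhizobia_embedding(
        nodule_pool, soil_pool, m=m, K=K, seed=seed + 1,
        zero_sigma_rule=zero_sigma_rule,
    )
    # one shared seed for both origins' full searches: identical inputs must
    # yield identical transforms (keeps the copy-null exchangeable)
    full_seed = int(rng.integers(2**31))
    full: dict[str, DeltaGResult] = {}
    for origin in ("nodule", "soil"):
        g_full = origin_mixture(je, je.origin_hap_counts[origin])
        full[origin] = procrustes_min_delta_g(
            g_plant, g_full, seed=full_seed, n_starts=n_starts
        )

    out = {"nodule": np.empty(n_boot), "soil": np.empty(n_boot)}
    for origin in ("nodule", "soil"):
        counts = je.origin_hap_counts[origin]
        n_seq = int(counts.sum())
        freqs = counts / n_seq
        res_full = full[origin]
        for b in range(n_boot):
            draw = None
            for _attempt in range(100):
                draw = rng.multinomial(n_seq, freqs)
                if draw.sum() > 0:
                    break
            else:  # pragma: no cover - multinomial cannot empty an origin
                raise RuntimeError("bootstrap replicate emptied an origin")
            g_b = origin_mixture(je, draw)
            if warm_start:
                res = procrustes_min_delta_g(
                    g_plant, g_b,
                    seed=int(rng.integers(2**31)),
                    n_starts=0,
                    init_rotation=res_full.rotation,
                    init_translation=res_full.translation_centered,
                    maxiter=refine_maxiter,
                    axis_starts=False,
                )
                out[origin][b] = res.delta_g
            else:
                res = procrustes_min_delta_g(
                    g_plant, g_b, seed=int(rng.integers(2**31)),
                    n_starts=n_starts,
                )
                out[origin][b] = res.delta_g

    mw = mann_whitney_one_sided(
        out["nodule"], out["soil"], alternative="a_less", alpha=alpha
    )
    return TopologyTestResult(
        delta_g_nodule=out["nodule"],
        delta_g_soil=out["soil"],
        delta_g_nodule_full=full["nodule"].delta_g,
        delta_g_soil_full=full["soil"].delta_g,
        U_statistic=mw.statistic,
        p_value=mw.p_value,
        alpha=alpha,
        significant=mw.significant,
    )
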