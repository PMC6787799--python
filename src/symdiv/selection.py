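"""Within-pool selection statistics: Nei–Gojobori pN/pS, Tajima's D,
one-sided Welch contrasts and a synonymous/nonsynonymous site linkage check.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

from .seq_io import AlignedPool, collapse_haplotypes, hamming_matrix
from .diversity import BootstrapDistribution

__all__ = [
    "SelectionStats",
    "ContrastResult",
    "ng_site_counts",
    "pn_ps",
    "tajimas_d",
    "selection_stats",
    "welch_contrast",
    "site_linkage_check",
    "translate_codon",
]

_BASES = "ACGT"

# standard genetic code; stops as '*'
_CODON_TABLE: dict[str, str] = {}
_T = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, (_a, _b, _c) in enumerate(itertools.product("TCAG", repeat=3)):
    _CODON_TABLE[_a + _b + _c] = _T[_i]


def translate_codon(codon: str) -> str:
    return _CODON_TABLE[codon]


@dataclass
class SelectionStats:
    pool_id: str
    pN: float
    pS: float
    pN_over_pS: float | None
    tajimas_D: float | None
    S_segregating: int
    n: int
    syn_sites: float
    nonsyn_sites: float


@dataclass
class ContrastResult:
    statistic: float
    p_value: float
    alternative: str
    alpha: float
    significant: bool = False
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not np.isnan(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value out of [0, 1]")
        self.significant = bool(self.p_value < self.alpha)


# ---------------------------------------------------------------------------
# Nei–Gojobori counting


@lru_cache(maxsize=None)
def _codon_site_counts(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts for one codon.

    Each position contributes (#synonymous single-base changes)/3 synonymous
    weight; the nonsynonymous weight is the complement, so syn + nonsyn = 3
    exactly (changes to stop codons count as nonsynonymous).
    """
    aa = _CODON_TABLE[codon]
    syn = 0.0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if _CODON_TABLE[alt] == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def _codon_pair_diffs(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts between two codons,
    averaged over all mutational pathways.

    Pathways passing through an intermediate stop codon are excluded; if all
    pathways are blocked, every pathway is used with '*' as a 21st residue.
    """
    if c1 == c2:
        return 0.0, 0.0
    positions = [i for i in range(3) if c1[i] != c2[i]]

    def walk(allow_stops: bool):
        results = []
        for order in itertools.permutations(positions):
            cur = c1
            syn = nonsyn = 0
            ok = True
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                if (not allow_stops) and _CODON_TABLE[nxt] == "*" and nxt != c2:
                    ok = False
                    break
                if _CODON_TABLE[cur] == _CODON_TABLE[nxt]:
                    syn += 1
                else:
                    nonsyn += 1
                cur = nxt
            if ok:
                results.append((syn, nonsyn))
        return results

    paths = walk(allow_stops=False)
    if not paths:
        paths = walk(allow_stops=True)
    syn = sum(p[0] for p in paths) / len(paths)
    nonsyn = sum(p[1] for p in paths) / len(paths)
    return syn, nonsyn


def _frame_trim(seq: str, frame_offset: int) -> str:
    usable = len(seq) - frame_offset
    return seq[frame_offset: frame_offset + 3 * (usable // 3)]


def _codons(seq: str) -> list[str]:
    return [seq[i: i + 3] for i in range(0, len(seq), 3)]


def ng_site_counts(sequence: str, frame_offset: int = 0) -> tuple[float, float]:
    """Expected (synonymous, nonsynonymous) site counts for one sequence."""
    cds = _frame_trim(sequence, frame_offset)
    if len(cds) % 3:
        raise ValueError("length not divisible by 3 after frame trim")
    syn = nonsyn = 0.0
    for codon in _codons(cds):
        if _CODON_TABLE[codon] == "*":
            raise ValueError(f"stop codon {codon} in sequence")
        s, ns = _codon_site_counts(codon)
        syn += s
        nonsyn += ns
    return syn, nonsyn


def pn_ps(
    pool: AlignedPool, frame_offset: int = 0
) -> tuple[float, float, float | None]:
    """Pool-level pN and pS.

    pN = (mean pairwise nonsynonymous differences) / (mean nonsynonymous
    sites per sequence); pS analogous. Raw proportions, no multiple-hit
    correction. The ratio is None when pS = 0.
    """
    hs = collapse_haplotypes(pool)
    counts = hs.counts
    n = hs.sample_size
    syn_sites = np.empty(hs.n_unique)
    nonsyn_sites = np.empty(hs.n_unique)
    hap_codons = []
    for i, h in enumerate(hs.haplotypes):
        syn_sites[i], nonsyn_sites[i] = ng_site_counts(h, frame_offset)
        hap_codons.append(_codons(_frame_trim(h, frame_offset)))
    mean_syn_sites = float(syn_sites @ counts / n)
    mean_nonsyn_sites = float(nonsyn_sites @ counts / n)

    total_pairs = n * (n - 1) / 2.0
    sum_sd = sum_nd = 0.0
    for i in range(hs.n_unique):
        for j in range(i + 1, hs.n_unique):
            w = counts[i] * counts[j]
            sd = nd = 0.0
            for ci, cj in zip(hap_codons[i], hap_codons[j]):
                if ci != cj:
                    s, ns = _codon_pair_diffs(ci, cj)
                    sd += s
                    nd += ns
            sum_sd += w * sd
            sum_nd += w * nd
    mean_sd = sum_sd / total_pairs
    mean_nd = sum_nd / total_pairs
    pS = mean_sd / mean_syn_sites if mean_syn_sites > 0 else 0.0
    pN = mean_nd / mean_nonsyn_sites if mean_nonsyn_sites > 0 else 0.0
    ratio = (pN / pS) if pS > 0 else None
    return pN, pS, ratio


# ---------------------------------------------------------------------------
# Tajima's D


def _segregating_sites(pool: AlignedPool) -> int:
    enc = pool.encoded()
    return int((enc != enc[0]).any(axis=0).sum())


def tajimas_d(pool: AlignedPool) -> float | None:
    """Tajima (1989) D from segregating sites and total pairwise diversity.

    pi here is the unnormalized sum over sites of average pairwise
    differences. Returns None (with a warning) when S = 0.
    """
    n = pool.n
    if n < 4:
        raise ValueError("Tajima's D needs n >= 4")
    S = _segregating_sites(pool)
    if S == 0:
        warnings.warn("no segregating sites; Tajima's D undefined")
        return None
    hs = collapse_haplotypes(pool)
    D = hamming_matrix(hs).values
    pi_total = float(hs.counts @ D @ hs.counts) / (n * (n - 1))

    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    denom = np.sqrt(e1 * S + e2 * S * (S - 1))
    return float((pi_total - S / a1) / denom)


def selection_stats(pool: AlignedPool, frame_offset: int = 0) -> SelectionStats:
    pN, pS, ratio = pn_ps(pool, frame_offset)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        D = tajimas_d(pool) if pool.n >= 4 else None
    rep = pool.sequences[0]
    syn, nonsyn = ng_site_counts(rep, frame_offset)
    return SelectionStats(
        pool_id=pool.pool_id,
        pN=pN,
        pS=pS,
        pN_over_pS=ratio,
        tajimas_D=D,
        S_segregating=_segregating_sites(pool),
        n=pool.n,
        syn_sites=syn,
        nonsyn_sites=nonsyn,
    )


# ---------------------------------------------------------------------------
# contrasts


def welch_contrast(
    dist_a: BootstrapDistribution | np.ndarray,
    dist_b: BootstrapDistribution | np.ndarray,
    alternative: str = "a_less",
    alpha: float = 0.01,
) -> ContrastResult:
    """One-sided Welch t test (Satterthwaite df) on two replicate sets."""
    if alternative not in ("a_less", "a_greater"):
        raise ValueError("alternative must be 'a_less' or 'a_greater'")
    a = np.asarray(
        dist_a.values if isinstance(dist_a, BootstrapDistribution) else dist_a,
        dtype=float,
    )
    b = np.asarray(
        dist_b.values if isinstance(dist_b, BootstrapDistribution) else dist_b,
        dtype=float,
    )
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty replicate set")
    va, vb = a.var(ddof=1) if len(a) > 1 else 0.0, b.var(ddof=1) if len(b) > 1 else 0.0
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            p = 0.5
        elif alternative == "a_less":
            p = 0.0 if a.mean() < b.mean() else 1.0
        else:
            p = 0.0 if a.mean() > b.mean() else 1.0
        return ContrastResult(
            statistic=np.nan, p_value=p, alternative=alternative,
            alpha=alpha, degenerate=True,
        )
    scipy_alt = "less" if alternative == "a_less" else "greater"
    res = stats.ttest_ind(a, b, equal_var=False, alternative=scipy_alt)
    return ContrastResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        alternative=alternative,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# syn/nonsyn site linkage


def _classify_biallelic_sites(pool: AlignedPool, frame_offset: int):
    """Biallelic polymorphic site positions with syn/nonsyn class.

    A site's class is decided by substituting its two alleles into the
    majority-consensus codon at that position.
    """
    seqs = [_frame_trim(s, frame_offset) for s in pool.sequences]
    L = len(seqs[0])
    arr = np.array([list(s) for s in seqs])
    sites = []
    for pos in range(L):
        col = arr[:, pos]
        alleles = sorted(set(col))
        if len(alleles) != 2:
            continue
        codon_idx = pos // 3
        within = pos % 3
        codon_cols = arr[:, 3 * codon_idx: 3 * codon_idx + 3]
        codons = ["".join(r) for r in codon_cols]
        consensus = max(sorted(set(codons)), key=codons.count)
        v1 = consensus[:within] + alleles[0] + consensus[within + 1:]
        v2 = consensus[:within] + alleles[1] + consensus[within + 1:]
        klass = "syn" if _CODON_TABLE[v1] == _CODON_TABLE[v2] else "nonsyn"
        minor = alleles[1] if list(col).count(alleles[0]) >= list(col).count(alleles[1]) else alleles[0]
        sites.append((pos, klass, (col == minor).astype(float)))
    return sites


def _mean_cross_r2(syn_cols: np.ndarray, nonsyn_cols: np.ndarray) -> float:
    vals = []
    for x in syn_cols.T:
        for y in nonsyn_cols.T:
            vx, vy = x.var(), y.var()
            if vx == 0 or vy == 0:
                continue
            c = np.cov(x, y, bias=True)[0, 1]
            vals.append(c * c / (vx * vy))
    return float(np.mean(vals)) if vals else np.nan


def site_linkage_check(
    pool: AlignedPool,
    frame_offset: int = 0,
    permutations: int = 200,
    seed: int = 0,
):
    """Mean r^2 between synonymous and nonsynonymous biallelic sites, with a
    permutation p-value (synonymous-site columns permuted as a block across
    sequences, preserving within-class linkage).

    Returns (r2_matrix_mean, p_value) or (None, None) with a warning when
    fewer than 2 polymorphic sites of either class exist.
    """
    sites = _classify_biallelic_sites(pool, frame_offset)
    syn = [v for _, k, v in sites if k == "syn"]
    nonsyn = [v for _, k, v in sites if k == "nonsyn"]
    if len(syn) < 1 or len(nonsyn) < 1:
        warnings.warn("insufficient polymorphic sites for linkage check")
        return None, None
    syn_cols = np.column_stack(syn)
    nonsyn_cols = np.column_stack(nonsyn)
    observed = _mean_cross_r2(syn_cols, nonsyn_cols)
    rng = np.random.default_rng(seed)
    n = syn_cols.shape[0]
    exceed = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        r2 = _mean_cross_r2(syn_cols[perm], nonsyn_cols)
        if r2 >= observed - 1e-12:
            exceed += 1
    p = (exceed + 1) / (permutations + 1)
    return observed, p
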