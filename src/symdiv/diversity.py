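"""Nucleotide diversity (pi), bootstrap/rarefaction resampling and the
plant-vs-nodule Spearman concordance test.

pi is the raw (uncorrected) average per-site pairwise difference; bootstrap
resampling draws sequences with replacement and recomputes pi per trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .seq_io import AlignedPool, HaplotypeSet, collapse_haplotypes, hamming_matrix

__all__ = [
    "DiversityEstimate",
    "BootstrapDistribution",
    "ConcordanceResult",
    "pi_diversity",
    "bootstrap_pi",
    "bootstrap_statistic",
    "rarefaction_pi",
    "paired_spearman_concordance",
]


@dataclass
class DiversityEstimate:
    pi: float
    sample_size: int
    pool_id: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError(f"pi out of range: {self.pi}")


@dataclass
class BootstrapDistribution:
    values: np.ndarray
    subsample_size: int
    trials: int
    seed: int
    statistic: str = "pi"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.trials:
            raise ValueError("values length != trials")


@dataclass
class ConcordanceResult:
    spearman_rho: float
    n_pairs: int
    threshold: float
    is_monotonic: bool
    degenerate: bool = False


def _pi_from_counts(counts: np.ndarray, D: np.ndarray, length: int) -> float:
    """pi from haplotype counts and a haplotype difference matrix."""
    n = counts.sum()
    if n < 2:
        raise ValueError("need at least 2 sequences for pi")
    total = counts @ D @ counts  # 2 * sum over unordered pairs of diffs
    return float(total / (n * (n - 1)) / length)


def pi_diversity(pool: AlignedPool) -> DiversityEstimate:
    """Average pairwise proportion of differing sites over all unordered
    sequence pairs."""
    hs = collapse_haplotypes(pool)
    D = hamming_matrix(hs).values
    pi = _pi_from_counts(hs.counts, D, pool.length)
    return DiversityEstimate(pi=pi, sample_size=pool.n, pool_id=pool.pool_id)


def bootstrap_pi(
    pool: AlignedPool,
    subsample_size: int = 70,
    trials: int = 2000,
    seed: int = 0,
) -> BootstrapDistribution:
    """Per-trial pi from `subsample_size` sequences drawn with replacement."""
    if subsample_size < 2:
        raise ValueError("subsample_size must be >= 2")
    hs = collapse_haplotypes(pool)
    D = hamming_matrix(hs).values
    rng = np.random.default_rng(seed)
    # multinomial over haplotypes == iid draws of sequences with replacement
    draws = rng.multinomial(subsample_size, hs.frequencies, size=trials)
    vals = np.einsum("ti,ij,tj->t", draws, D, draws) / (
        subsample_size * (subsample_size - 1)
    ) / pool.length
    return BootstrapDistribution(
        values=vals, subsample_size=subsample_size, trials=trials, seed=seed
    )


def bootstrap_statistic(
    pool: AlignedPool,
    stat_fn: Callable[[AlignedPool], float],
    subsample_size: int = 70,
    trials: int = 200,
    seed: int = 0,
    name: str = "stat",
) -> BootstrapDistribution:
    """Generic with-replacement resampling of sequences, recomputing an
    arbitrary pool statistic inside each resample.

    Used as the replicate unit for Welch contrasts (pN, Tajima's D).
    Trials whose statistic is undefined (None) are recorded as NaN.
    """
    if subsample_size < 2:
        raise ValueError("subsample_size must be >= 2")
    rng = np.random.default_rng(seed)
    seqs = pool.sequences
    vals = np.empty(trials)
    for t in range(trials):
        idx = rng.integers(0, len(seqs), size=subsample_size)
        sub = pool.replace_sequences([seqs[i] for i in idx], suffix=f"~b{t}")
        v = stat_fn(sub)
        vals[t] = np.nan if v is None else float(v)
    return BootstrapDistribution(
        values=vals, subsample_size=subsample_size, trials=trials,
        seed=seed, statistic=name,
    )


def rarefaction_pi(
    pool: AlignedPool,
    depths: list[int],
    trials_per_depth: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean and sd of pi at increasing resampling depths (with replacement)."""
    rng = np.random.default_rng(seed)
    hs = collapse_haplotypes(pool)
    D = hamming_matrix(hs).values
    rows = []
    for depth in depths:
        if depth < 2:
            raise ValueError("rarefaction depth must be >= 2")
        draws = rng.multinomial(depth, hs.frequencies, size=trials_per_depth)
        vals = np.einsum("ti,ij,tj->t", draws, D, draws) / (
            depth * (depth - 1)
        ) / pool.length
        rows.append(
            {"depth": depth, "mean_pi": vals.mean(), "sd_pi": vals.std(ddof=1)}
        )
    return pd.DataFrame(rows)


def paired_spearman_concordance(
    plant_dists: Mapping[str, BootstrapDistribution],
    nodule_dists: Mapping[str, BootstrapDistribution],
    threshold: float = 0.8,
    seed: int = 0,
) -> ConcordanceResult:
    """Randomly pair plant and nodule bootstrap pi values within each species,
    concatenate pairs across species, and test rank concordance.

    Pairing is a uniform random permutation per species under the seed.
    Degenerate rank data (all ties) is reported as rho = 0 with a flag.
    """
    if set(plant_dists) != set(nodule_dists):
        raise ValueError(
            f"species mismatch: {sorted(plant_dists)} vs {sorted(nodule_dists)}"
        )
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for sp in sorted(plant_dists):
        a = plant_dists[sp].values
        b = nodule_dists[sp].values
        if len(a) != len(b):
            raise ValueError(f"species {sp!r}: unequal trial counts")
        perm = rng.permutation(len(b))
        xs.append(a)
        ys.append(b[perm])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return ConcordanceResult(
            spearman_rho=0.0, n_pairs=len(x), threshold=threshold,
            is_monotonic=False, degenerate=True,
        )
    rho = float(stats.spearmanr(x, y).statistic)
    return ConcordanceResult(
        spearman_rho=rho,
        n_pairs=len(x),
        threshold=threshold,
        is_monotonic=bool(rho > threshold),
    )
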