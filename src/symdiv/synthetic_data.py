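"""Synthetic plant/nodule/soil pool triplets with controlled diversity
ranking, clade structure, codon-aware mutations and site-frequency skew.

The generator uses a star-with-jitter genealogy: clade founders form a
random-spaced divergence chain from a common ancestor, haplotypes radiate
from their founder, and haplotype frequencies are Dirichlet-distributed
with a concentration that decreases with `sfs_skew` (more skew -> more rare
variants -> lower Tajima's D). A neutral-coalescent mode (msprime) exists
solely for Tajima's D calibration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .seq_io import AlignedPool, collapse_haplotypes
from .selection import translate_codon

__all__ = [
    "SimulationConfig",
    "SyntheticSystem",
    "simulate_system",
    "simulate_collection",
    "diversity_ladder",
    "write_fixture_set",
    "neutral_coalescent_pool",
    "resample_upweight_rare",
]

_BASES = "ACGT"
_SENSE_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if translate_codon(a + b + c) != "*"
]

_SOIL_MODES = ("permuted", "copy_nodule", "mirror_plant")


@dataclass
class SimulationConfig:
    n_species: int = 1
    species: str = "sp1"
    seq_length_bp: int = 210
    plant_pool_size: int = 100
    rhizobial_pool_size: int = 3500
    n_clades: int = 3
    clade_frequencies: dict | None = None  # optional per-origin weight lists
    within_clade_divergence: float = 2.0
    between_clade_divergence: float = 10.0
    nonsyn_fraction: float = 0.5
    sfs_skew: float = 0.0
    topology_match: str = "matched"  # matched | mismatched
    nodule_private_clade: bool = False
    soil_mode: str = "permuted"
    haplotypes_per_clade: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seq_length_bp % 3:
            raise ValueError("seq_length_bp must be a codon multiple")
        if self.within_clade_divergence < 0 or self.between_clade_divergence < 0:
            raise ValueError("divergences must be >= 0")
        if self.topology_match not in ("matched", "mismatched"):
            raise ValueError("topology_match must be matched|mismatched")
        if self.soil_mode not in _SOIL_MODES:
            raise ValueError(f"soil_mode must be one of {_SOIL_MODES}")
        if not 0.0 <= self.nonsyn_fraction <= 1.0:
            raise ValueError("nonsyn_fraction must be in [0, 1]")


@dataclass
class SyntheticSystem:
    plant_pool: AlignedPool
    nodule_pool: AlignedPool
    soil_pool: AlignedPool
    outgroup: str
    truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# sequence machinery


def _random_coding_seq(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons)
    return "".join(_SENSE_CODONS[i] for i in idx)


def _mutate(
    seq: str,
    n_mut: int,
    rng: np.random.Generator,
    nonsyn_fraction: float,
) -> str:
    """Apply n_mut point mutations, each forced nonsynonymous with
    probability nonsyn_fraction; stop codons are never created."""
    s = list(seq)
    for _ in range(n_mut):
        want_nonsyn = bool(rng.random() < nonsyn_fraction)
        placed = False
        for _attempt in range(300):
            pos = int(rng.integers(len(s)))
            base = _BASES[int(rng.integers(4))]
            if base == s[pos]:
                continue
            ci = pos // 3
            old_codon = "".join(s[3 * ci: 3 * ci + 3])
            within = pos % 3
            new_codon = old_codon[:within] + base + old_codon[within + 1:]
            if translate_codon(new_codon) == "*":
                continue
            is_nonsyn = translate_codon(new_codon) != translate_codon(old_codon)
            if is_nonsyn == want_nonsyn:
                s[pos] = base
                placed = True
                break
        if not placed:
            raise ValueError(
                "infeasible mutation class request "
                f"(nonsyn_fraction={nonsyn_fraction}); no eligible site found"
            )
    return "".join(s)


def _poisson_at_least_one(rng: np.random.Generator, lam: float) -> int:
    if lam <= 0:
        return 0
    return max(1, int(rng.poisson(lam)))


def _clade_profiles(
    rng: np.random.Generator, cfg: SimulationConfig
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Per-clade haplotype mutation-count vectors and frequency vectors.

    Drawn once per system and shared between the plant and rhizobial gene
    families, so that under topology_match="matched" clade k of one family
    mirrors clade k of the other in haplotype spread (hence cluster sigma)
    and haplotype frequencies, not just in clade-level geometry.
    """
    jitter, freqs = [], []
    # Zipf-shaped haplotype frequencies with exponent sfs_skew: skew 0 is
    # uniform (balanced); larger skew keeps a common head plus a long tail
    # of rare haplotypes sampled as singletons -> excess rare variants ->
    # lower Tajima's D. Multiplicative lognormal jitter keeps draws distinct.
    H = cfg.haplotypes_per_clade
    for _c in range(cfg.n_clades):
        if cfg.within_clade_divergence <= 0:
            jitter.append(np.zeros(1, dtype=int))
            freqs.append(np.array([1.0]))
            continue
        # rarer haplotypes carry more private mutations (rare genotypes are
        # the divergent ones), so up-weighting them raises diversity
        jitter.append(np.sort(rng.poisson(cfg.within_clade_divergence, H)))
        q = np.arange(1, H + 1, dtype=float) ** (-cfg.sfs_skew)
        q = q * rng.lognormal(0.0, 0.2, H)
        freqs.append(np.sort(q / q.sum())[::-1])
    return jitter, freqs


def _gene_family(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    step_profile: np.ndarray,
    jitter: list[np.ndarray],
) -> tuple[list[list[str]], str]:
    """Clade-structured haplotypes for one gene.

    Returns (haplotypes per clade, ancestor). Founders form a divergence
    chain with deterministic per-step mutation counts from `step_profile`;
    each haplotype adds its clade's jitter-profile mutations at random sites
    (star-with-jitter genealogy). Both profiles are shared between families.
    """
    ancestor = _random_coding_seq(rng, cfg.seq_length_bp // 3)
    founders = []
    cur = ancestor
    for lam in step_profile:
        n_mut = max(1, int(round(lam))) if lam > 0 else 0
        cur = _mutate(cur, n_mut, rng, cfg.nonsyn_fraction)
        founders.append(cur)
    clades: list[list[str]] = []
    for founder, counts in zip(founders, jitter):
        clades.append(
            [
                _mutate(founder, int(k), rng, cfg.nonsyn_fraction)
                for k in counts
            ]
        )
    return clades, ancestor


def _sample_pool(
    rng: np.random.Generator,
    clades: list[list[str]],
    hap_freqs: list[np.ndarray],
    clade_weights: np.ndarray,
    n: int,
    pool_id: str,
    species: str,
    origin: str,
) -> AlignedPool:
    counts = rng.multinomial(n, clade_weights)
    seqs: list[str] = []
    for c, k in enumerate(counts):
        if k == 0:
            continue
        hap_counts = rng.multinomial(k, hap_freqs[c])
        for h_idx, hc in enumerate(hap_counts):
            seqs.extend([clades[c][h_idx]] * int(hc))
    rng.shuffle(seqs)
    return AlignedPool(pool_id=pool_id, species=species, origin=origin,
                       sequences=seqs)


def _default_clade_weights(n_clades: int) -> np.ndarray:
    w = 0.55 ** np.arange(n_clades)
    return w / w.sum()


def simulate_system(cfg: SimulationConfig) -> SyntheticSystem:
    """One plant/nodule/soil triplet, fully deterministic per seed."""
    rng = np.random.default_rng(cfg.seed)
    # heterogeneous chain spacing, shared across the two gene families, makes
    # clade-level geometry correspond (and breaks mirror symmetry)
    step_profile = cfg.between_clade_divergence * rng.uniform(
        0.8, 1.8, size=cfg.n_clades
    )
    jitter, clade_q = _clade_profiles(rng, cfg)
    plant_clades, _plant_anc = _gene_family(rng, cfg, step_profile, jitter)
    rhiz_clades, rhiz_anc = _gene_family(rng, cfg, step_profile, jitter)
    plant_q = rhiz_q = clade_q

    if cfg.clade_frequencies and "plant" in cfg.clade_frequencies:
        w_plant = np.asarray(cfg.clade_frequencies["plant"], dtype=float)
    else:
        w_plant = _default_clade_weights(cfg.n_clades)
    w_plant = w_plant / w_plant.sum()

    if cfg.clade_frequencies and "nodule" in cfg.clade_frequencies:
        w_nodule = np.asarray(cfg.clade_frequencies["nodule"], dtype=float)
        w_nodule = w_nodule / w_nodule.sum()
    elif cfg.topology_match == "matched":
        w_nodule = w_plant.copy()
    else:
        # cyclic shift: breaks the weight-to-position association without
        # being a mirror image (reflection is a legal Procrustes move)
        w_nodule = np.roll(w_plant, 1)

    if cfg.clade_frequencies and "soil" in cfg.clade_frequencies:
        w_soil = np.asarray(cfg.clade_frequencies["soil"], dtype=float)
        w_soil = w_soil / w_soil.sum()
    elif cfg.soil_mode == "mirror_plant":
        w_soil = w_plant.copy()
    else:
        w_soil = np.roll(w_plant, 1)
    if cfg.nodule_private_clade and cfg.soil_mode != "copy_nodule":
        # soil misses the clade most common in plant/nodule pools (rare in
        # soil, selected into nodules by the host)
        drop = int(np.argmax(w_nodule))
        if w_nodule[drop] == 0:
            raise ValueError("nodule lacks the designated private clade")
        w_soil = w_soil.copy()
        w_soil[drop] = 0.0
        if w_soil.sum() == 0:
            raise ValueError("soil weights degenerate after clade removal")
        w_soil = w_soil / w_soil.sum()

    sp = cfg.species
    plant_pool = _sample_pool(
        rng, plant_clades, plant_q, w_plant, cfg.plant_pool_size,
        f"{sp}_plant", sp, "plant",
    )
    nodule_pool = _sample_pool(
        rng, rhiz_clades, rhiz_q, w_nodule, cfg.rhizobial_pool_size,
        f"{sp}_nodule", sp, "nodule",
    )
    if cfg.soil_mode == "copy_nodule":
        soil_pool = AlignedPool(
            pool_id=f"{sp}_soil", species=sp, origin="soil",
            sequences=list(nodule_pool.sequences),
        )
    else:
        soil_pool = _sample_pool(
            rng, rhiz_clades, rhiz_q, w_soil, cfg.rhizobial_pool_size,
            f"{sp}_soil", sp, "soil",
        )

    outgroup = _mutate(
        rhiz_anc,
        _poisson_at_least_one(
            rng, 2.0 * cfg.between_clade_divergence * cfg.n_clades
        ),
        rng,
        cfg.nonsyn_fraction,
    )

    hap_clade = {
        h: c for c, haps in enumerate(rhiz_clades) for h in haps
    }
    truth = {
        "species": sp,
        "topology_match": cfg.topology_match,
        "soil_mode": cfg.soil_mode,
        "clade_weights": {
            "plant": w_plant.tolist(),
            "nodule": w_nodule.tolist(),
            "soil": w_soil.tolist(),
        },
        "rhizobial_haplotype_clades": hap_clade,
        "plant_haplotype_clades": {
            h: c for c, haps in enumerate(plant_clades) for h in haps
        },
        "nodule_private_clade": cfg.nodule_private_clade,
        "seed": cfg.seed,
        "config": asdict(cfg),
    }
    return SyntheticSystem(
        plant_pool=plant_pool,
        nodule_pool=nodule_pool,
        soil_pool=soil_pool,
        outgroup=outgroup,
        truth=truth,
    )


def simulate_collection(cfg: SimulationConfig) -> list[SyntheticSystem]:
    """n_species triplets with a geometric within-clade divergence ladder
    (species k gets within_clade_divergence * 3^k) so realized diversities
    rank identically in plant and nodule pools."""
    systems = []
    for k in range(cfg.n_species):
        sub = SimulationConfig(
            **{
                **asdict(cfg),
                "n_species": 1,
                "species": f"sp{k + 1}",
                "within_clade_divergence": cfg.within_clade_divergence * 3**k,
                "seed": cfg.seed + 1000 * k,
            }
        )
        systems.append(simulate_system(sub))
    return systems


def diversity_ladder(cfgs: list[SimulationConfig]) -> list[SyntheticSystem]:
    """Systems whose plant and nodule pools share a diversity ranking,
    produced from configs with increasing within-clade divergence."""
    if len(cfgs) < 2:
        raise ValueError("need at least 2 configs")
    return [simulate_system(c) for c in cfgs]


# ---------------------------------------------------------------------------
# fixtures


def _write_fasta(seqs: list[str], path: Path, prefix: str) -> None:
    with open(path, "w") as fh:
        for i, s in enumerate(seqs):
            fh.write(f">{prefix}_{i}\n{s}\n")


def write_fixture_set(system: SyntheticSystem, out_dir) -> Path:
    """FASTA per pool + outgroup FASTA + manifest TSV + truth JSON.

    Returns the manifest path. Appends to an existing manifest so several
    species can share one fixture directory.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sp = system.truth["species"]
    rows = []
    for pool in (system.plant_pool, system.nodule_pool, system.soil_pool):
        fasta = out / f"{pool.pool_id}.fasta"
        _write_fasta(pool.sequences, fasta, pool.pool_id)
        rows.append(
            "\t".join(
                [pool.pool_id, pool.species, pool.origin, fasta.name, "0",
                 f"{sp}_outgroup"]
            )
        )
    og_path = out / f"{sp}_outgroup.fasta"
    _write_fasta([system.outgroup], og_path, f"{sp}_outgroup")
    manifest = out / "manifest.tsv"
    header = "pool_id\tspecies\torigin\tpath\tframe_offset\toutgroup_id\n"
    if manifest.exists():
        existing = manifest.read_text()
        manifest.write_text(existing + "\n".join(rows) + "\n")
    else:
        manifest.write_text(header + "\n".join(rows) + "\n")
    with open(out / f"{sp}_truth.json", "w") as fh:
        json.dump(system.truth, fh, indent=2, sort_keys=True, default=str)
    return manifest


# ---------------------------------------------------------------------------
# calibration helpers


def neutral_coalescent_pool(
    n: int = 50,
    theta: float = 5.0,
    length: int = 999,
    seed: int = 0,
    pool_id: str = "coalescent",
    species: str = "sim",
    origin: str = "soil",
) -> AlignedPool:
    """Neutral Kingman-coalescent sample (msprime) with locus-wide
    E[pairwise differences] = theta. Not codon-structured; intended only
    for Tajima's D calibration."""
    import msprime

    ts = msprime.sim_ancestry(
        samples=n,
        ploidy=1,
        population_size=1.0,
        sequence_length=length,
        random_seed=seed + 1,
    )
    ts = msprime.sim_mutations(
        ts,
        rate=theta / (2.0 * length),
        model=msprime.JC69(),
        random_seed=seed + 2,
    )
    arr = np.full((n, length), "A", dtype="<U1")
    for var in ts.variants():
        pos = int(var.site.position)
        alleles = np.array(var.alleles, dtype="<U1")
        arr[:, pos] = alleles[var.genotypes]
    seqs = ["".join(row) for row in arr]
    return AlignedPool(pool_id=pool_id, species=species, origin=origin,
                       sequences=seqs)


def resample_upweight_rare(
    pool: AlignedPool,
    size: int | None = None,
    power: float = 0.0,
    seed: int = 0,
    suffix: str = "_upweighted",
) -> AlignedPool:
    """Resample a pool with haplotype probabilities proportional to
    count**power (power=1 reproduces plain bootstrap; power=0 samples
    haplotypes uniformly, strongly up-weighting rare ones)."""
    rng = np.random.default_rng(seed)
    hs = collapse_haplotypes(pool)
    probs = hs.counts.astype(float) ** power
    probs = probs / probs.sum()
    n = size if size is not None else pool.n
    counts = rng.multinomial(n, probs)
    seqs: list[str] = []
    for h, c in zip(hs.haplotypes, counts):
        seqs.extend([h] * int(c))
    rng.shuffle(seqs)
    return AlignedPool(
        pool_id=pool.pool_id + suffix,
        species=pool.species,
        origin=pool.origin,
        sequences=seqs,
    )
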