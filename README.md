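# symdiv

Analysis toolkit for **matched population diversity between interacting
symbiotic gene pools** — a plant receptor gene pool versus the rhizobial
symbiosis gene pools sampled from nodules and soil. It implements:

- **Pool ingestion & trees** (`symdiv.seq_io`): aligned FASTA pools,
  haplotype collapsing, Hamming distances, abundance-ordered greedy OTU
  picking at a percent-identity threshold, Saitou–Nei neighbor joining with
  outgroup rooting, and clade-majority ("biovar") pool filtering.
- **Diversity** (`symdiv.diversity`): per-site nucleotide diversity π,
  bootstrap/rarefaction resampling, and a Spearman concordance test that
  randomly pairs bootstrap π values between plant and nodule pools
  (ρ > 0.8 ⇒ monotonic relationship).
- **Selection** (`symdiv.selection`): Nei–Gojobori pN/pS with pathway
  averaging, Tajima's D, one-sided Welch contrasts on bootstrap replicates,
  and a permutation check for linkage between synonymous and nonsynonymous
  polymorphic sites.
- **Topological beta-diversity** (`symdiv.topology_beta`): the core novel
  statistic ΔG — frequency-weighted agglomerative haplotype clustering,
  median normalization with a zero-σ substitution rule, metric MDS (SMACOF)
  into K-dimensional space, isotropic Gaussian-mixture construction, and
  Procrustes superimposition (rotation + translation + mirror reflection)
  minimizing a normalized L2 distance between mixtures. Includes the
  joint-embed/split protocol for nodule/soil pools, bootstrap ΔG sets, and
  one-sided Mann–Whitney inference (exact for small samples).
- **Tanglegrams** (`symdiv.tanglegram`): face-to-face NJ trees over cluster
  sets with mutual k-nearest-neighbor edges in the aligned embedding.
- **Synthetic data** (`symdiv.synthetic_data`): plant/nodule/soil pool
  triplets with controllable diversity ranking, clade structure, topological
  matching, codon-aware mutations, site-frequency-spectrum skew, and a
  neutral-coalescent mode (msprime) for Tajima's D calibration.
- **Pipeline & CLI** (`symdiv.pipeline_cli`): orchestration with a single
  global seed fanned out per stage (crc32 of `"<seed>:<stage>"`).

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the property-based acceptance criteria
(oracle equivalences against brute-force implementations, NJ recovery on
additive matrices, ΔG closed-form vs. quadrature and rigid-transform
recovery, simulation-calibrated power/null rates for the concordance,
topology, and selection tests, and end-to-end determinism). The full suite
takes ~10–15 minutes; the topology power/null calibration dominates.

## CLI

Generate a synthetic fixture set and run the full analysis:

```bash
symdiv simulate --config sim.yaml --out fixtures/
symdiv run-all --manifest fixtures/manifest.tsv --out results/ --seed 7 \
    --m 10 --n-boot 100
```

Individual stages: `symdiv ingest`, `symdiv diversity`, `symdiv selection`,
`symdiv topology`. Outputs: `report.json` plus TSV/CSV/Newick sidecars
(per-pool π table, Table-1-style selection table with Welch p-values, ΔG
bootstrap CSVs, tanglegram Newick + edge lists).

Example `sim.yaml`:

```yaml
n_species: 3
plant_pool_size: 100
rhizobial_pool_size: 3500
n_clades: 4
within_clade_divergence: 2.0
between_clade_divergence: 12.0
haplotypes_per_clade: 6
topology_match: matched
nodule_private_clade: true
seed: 7
```

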