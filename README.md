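# indelflex

Tested, reusable pipeline for assessing a natural in-frame deletion in a
protein domain: indel discovery and population allele frequencies from
allelic coding sequences, per-residue conservation scoring with an
alignment-diversity summary, multi-condition molecular-dynamics trajectory
comparison statistics with FDR control, essential-dynamics PCA with
residue-subset exclusion, and exhaustive sliding-window in-silico deletion
scanning with a pluggable scorer. A seeded synthetic-data module generates
every input with known ground truth, so the whole pipeline is testable
offline.

## Modules

| module | role |
|---|---|
| `indelflex.synthetic_data` | Gaussian-fluctuation trajectory ensembles, diploid allele sets with planted deletion frequencies, MSAs with planted per-column conservation |
| `indelflex.variants` | affine-gap global alignment, HGVS-style indel calling (3'-most normalisation), per-population allele frequencies and homozygote counts |
| `indelflex.conservation` | length filter, greedy identity clustering, Henikoff-style sequence weights, entropy-based column scores, DOPS diversity |
| `indelflex.traj_core` | Kabsch superposition, Rg, RMSD/RMSF series, burn-in trimming, SEM-of-max-difference summaries |
| `indelflex.traj_compare` | sliding-window Cα-peak t-tests with Benjamini-Hochberg correction, resolution/consistency/direction flags, secondary-structure occupancy |
| `indelflex.traj_pca` | pooled covariance PCA, extreme-frame extraction, robust replicate-outlier flagging, loop divergence |
| `indelflex.indel_scan` | deletion-window enumeration, scorer contract, difference maps, ranking and classification |
| `indelflex.io` / `config` / `pipeline` / `cli` | plain-text formats (FASTA, sample-sheet TSV, multi-model PDB, CACOORDS container, SS label matrices), YAML config, end-to-end driver with a reproducibility manifest |

All residue and nucleotide coordinates are 1-based inclusive. Coordinates
are Å, times ps, durations ns.

## CLI

```sh
indelflex simulate --outdir sim --seed 1        # write synthetic inputs
indelflex variants sim/reference.fasta sim/haplotypes.fasta
indelflex conservation sim/msa.fasta --tau 0.70
indelflex scan domain.fasta --query 153 155
indelflex convert sim/wt_rep1.pdb sim/wt_rep1.cacoords
indelflex all --seed 1 --outdir run1           # full pipeline, demo inputs
```

`indelflex all` accepts a YAML config (`--config`) holding every threshold
(t-test alpha 0.05 with BH correction, 2.5 Å resolution filter, window 3 /
step 1, 400 ns burn-in, conservation threshold 0.70, identity clustering
0.70, length filter 0.2, per-residue impact flag −0.3). Identical
config + seed gives byte-identical numeric outputs; each run writes a
manifest with the seed, config hash and aggregate simulated time.

## Scorer plug-in

`indelflex.indel_scan.run_scan(sequence, scorer, window=3)` accepts any
callable returning `(scalar, per_residue_vector)` for a sequence — the
shipped reference scorer is additive Kyte-Doolittle hydropathy, and
`ExternalCommandScorer` adapts any command printing
`{"scalar": x, "per_residue": [...]}` JSON (e.g. a protein-language-model
predictor run out of process).
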