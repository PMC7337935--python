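# oxtraj

Analysis toolkit for coarse-grained nucleic-acid nanostructure simulations
stored in the plain-text oxDNA file format. It provides, as a library and a
unified CLI:

- **I/O** for oxDNA topology/configuration/trajectory files (lazy,
  byte-offset-indexed trajectory access), designed-pair lists, mutual-trap
  external-force files, index files, sequence CSV export and the three
  viewer-compatible JSON overlay formats (per-particle scalars, per-particle
  vectors, free arrow pairs).
- **Mean structures & flexibility**: SVD (Kabsch) superposition, trajectory
  alignment, mean structure, per-nucleotide RMSF (nm), centroid extraction,
  and an alternative mean structure from mean local contact distances via
  multidimensional scaling (SMACOF stress majorization with an L-BFGS
  polish), with a per-nucleotide local contact deviation overlay.
- **Duplex geometry**: automatic per-frame duplex detection from bonded
  pairs, axis fits for B-form (total-least-squares line through base-pair
  midpoints) and A-form (normal of the backbone-displacement plane) helices,
  interduplex angle statistics and inter-nucleotide distance series.
- **Energetics**: hydrogen-bond detection (geometric, or thresholded at
  −0.1 simulation energy units from an external per-interaction energy
  table), designed-pair occupancy overlays, mean per-nucleotide energy
  overlays, and pairs ↔ forces converters.
- **Motion modes**: covariance PCA of aligned trajectories, projections,
  scree tables and eigenvalue-weighted mode arrow overlays.
- **Clustering**: DBSCAN over arbitrary per-frame order parameters (PCA
  projections by default), per-cluster trajectory export and per-cluster
  centroids.
- **Rigid-body relaxation**: DBSCAN group identification, springs
  `f = c_spr (l − l_r)` at inter-group backbone bonds, linear centre-to-centre
  repulsion `f = max(c_rep (1 − d/(r_a + r_b)), 0)`, and damped rigid-body
  integration to a simulation-ready arrangement.
- **Synthetic fixtures**: ideal A-/B-form duplexes, gapped duplexes,
  Gaussian-perturbed trajectories, planted-mode and two-state trajectories
  with known ground truth — every analysis is testable without a simulator.

Internal math uses simulation length units; user-facing distances are
reported in nanometres (0.8518 nm per simulation unit).

## CLI

All commands run through a single entry point:

```sh
oxtraj --help
oxtraj --output-dir out generate --n-bp 20 --n-frames 50 --sigma 0.05
oxtraj --output-dir out mean out/synthetic.top out/synthetic.dat
oxtraj --output-dir out deviations out/synthetic.top out/synthetic.dat out/mean.dat
oxtraj --output-dir out mds-mean out/synthetic.top out/synthetic.dat
oxtraj --output-dir out bond-occupancy out/synthetic.top out/synthetic.dat out/synthetic_pairs.txt
oxtraj --output-dir out pca out/synthetic.top out/synthetic.dat --projections-out proj.tsv
oxtraj --output-dir out cluster out/synthetic.top out/synthetic.dat
oxtraj --output-dir out duplex-angles out/synthetic.top out/synthetic.dat 0 39
oxtraj --output-dir out relax structure.top structure.dat --eps 2.0
```

Global flags: `--parallel N` (chunked multi-process trajectory analysis),
`--seed`, `--units {nm,sim}`, `--output-dir`, `-v/-q`.

Overlay JSON files (`rmsf.json`, `occupancy.json`, `pca_modes.json`, …) are
loadable directly in oxDNA-ecosystem viewers as color/vector overlays.

## Interaction-table TSV schema

`energy-overlay` and energy-mode bond detection consume a whitespace-
delimited table with header `frame i j kind energy`: one row per interaction
per frame, ids 0-based, `kind` e.g. `HB` (hydrogen bond) or `STCK`, energies
in simulation units. Hydrogen bonds are those `HB` rows with energy below
−0.1.
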