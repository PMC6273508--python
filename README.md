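# brs3d

Shape-similarity profile descriptors for ligand-based virtual screening and
QSAR.

A small molecule is encoded as a fixed-length vector of 3D shape-similarity
scores: the molecule is flexibly superimposed onto each member of a diverse
library of rigid template ligands, and the best combined score (Gaussian
shape overlap + pharmacophore feature overlap, both in [0, 1]) against each
template becomes one element of the profile. The profile then serves as a
descriptor matrix for RBF-SVM discriminant/regression models, enrichment
analysis, random-forest-style permutation feature selection, and
receptor-subtype selectivity prediction.

## Layout

| module | role |
|---|---|
| `brs3d.molio` | SDF/MOL2/SMILES I/O, pharmacophore feature typing, conformer generation |
| `brs3d.shapesim` | Gaussian-overlap shape + feature similarity, rigid and flexible superimposition |
| `brs3d.templates` | diverse template library: self-similarity matrix, Pearson-row distance, greedy max-min selection |
| `brs3d.descriptor` | per-molecule similarity profiles, cached batch profiling, TSV persistence |
| `brs3d.modeling` | splits, imbalance strategies, grid-searched RBF-SVM with 10-fold CV, metrics (ACC/Precision/Recall/Specificity/MCC/AUC, RMSE/Q2/R2), enrichment factors, permutation feature importance |
| `brs3d.selectivity` | selectivity-ratio labeling (|SR| >= 1.3), Y-randomization, resampling stability, applicability domain |
| `brs3d.fixtures` | seedable toy molecules and synthetic descriptor datasets |

## CLI

```bash
# synthetic inputs
brs3d fixtures --kind molecules --seed 1 --n 20 --out data/
brs3d fixtures --kind classification --seed 42 --out data/cls/

# template library from a single-conformer SDF pool
brs3d build-library --pool data/molecules.sdf --k 10 --out library.sdf

# similarity profiles
brs3d profile --library library.sdf --in queries.sdf --out profiles.tsv \
    --top-n 10 --seed 42

# modeling
brs3d train --table profiles.tsv --labels labels.tsv --strategy weighted \
    --out model_report.json
brs3d select-features --table profiles.tsv --labels labels.tsv --out ranking.json
brs3d selectivity --table profiles.tsv --activities activities.tsv \
    --mode regression --out selectivity_report.json
```

## Notes

- Alignment scoring is a first-order (pairwise) Gaussian-overlap Tanimoto
  plus a per-feature-type point Tanimoto, combined with weight `w_shape`
  (default 0.5). The pose search runs in the shapes' intrinsic
  principal-axes frames, which makes profiles invariant to the input pose of
  a molecule.
- Template libraries, similarity matrices, and descriptor tables persist as
  plain text (SDF / TSV) and are exactly round-trippable.
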