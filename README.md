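# enzyph

Sequence-based discrimination of **acid-adapted** from **alkaline-adapted**
enzymes, for protein engineers and computational biologists who want a
transparent, testable implementation of the classic physicochemical-descriptor
pipeline — and of the striking result it supports: a *single* feature, the
content fraction of medium normalized-van-der-Waals-volume residues, carries
most of the class signal.

Enzymes whose catalytic optimum lies below pH 5 (acidic) or above pH 9
(alkaline) differ systematically in amino-acid composition. The pipeline:

1. **188D descriptor** — for a sequence of length *L*: the 20 amino-acid
   frequencies `n_i / L`, plus, for each of 8 physicochemical properties
   whose 3-group partition of the alphabet is configured in
   `enzyph.properties`, 21 features:
   3 group-content fractions, 15 positional-distribution values (relative
   positions of the first, 25%, 50%, 75% and last occurrence of each group)
   and 3 cross-group adjacent-pair ("bivalent") frequencies over `L − 1`.
   Property 2 is normalized van der Waals volume, so 1-based index 43 is the
   composition of its medium group `NVEQIL`.
2. **Cross-covariance (CC)** — for standardized residue indices u₁ ≠ u₂ and
   lag `lg`:
   `CC(u1,u2,lg) = Σ_{i=1}^{L−lg} (P_u1(R_i) − mean_u1)(P_u2(R_{i+lg}) − mean_u2) / (L − lg)`,
   giving `N(N−1)·LG` features (12 by default; 200 combined).
3. **MRMD feature ranking** — per feature, relevance `MR_i = |PCC(f_i, C)|`
   (Pearson correlation with the class vector) plus distance
   `MD_i = ED_i + COS_i + TC_i` (mean Euclidean, cosine and Tanimoto
   separation from the other columns); both min-max scaled and summed.
   A forward wrapper picks the smallest ranked prefix maximising stratified
   cross-validated accuracy.
4. **Evaluation** — pooled out-of-fold Sn, Sp, ACC, MCC and ROC/PR AUC under
   seeded stratified k-fold CV, with a 100-tree random forest and a
   lightly-regularised logistic model (positive class: alkaline).

A synthetic-sequence generator plants exactly this contrast (alkaline
sequences enriched in `NVEQIL` residues) with a closed-form binomial Bayes
accuracy, so every stage is testable end to end without any downloads.

Everything is exposed both as scikit-learn estimators
(`CTD188Extractor`, `CrossCovarianceExtractor`, `MRMDSelector` — pipeline
and `clone` compatible) and as plain functions (`extract_188d`,
`extract_cc`, `rank_features`, `cross_validate`, ...).

## Worked example

```python
from enzyph import PipelineConfig, SyntheticSpec, run_pipeline

cfg = PipelineConfig(
    synthetic=SyntheticSpec(seed=2),   # 54 acid / 68 alkaline, planted contrast
    seed=2, outdir="run",
)
report = run_pipeline(cfg)
print(report["dimensions"])
print(report["key_feature"])
```

prints

```
{'full': 200, 'selected': 3, 'single': 1}
{'name': 'normalized_vdw_volume.composition.2', 'index_0based': 42,
 'index_1based': 43, 'mrmd_rank': 2, 'acc': 0.9918032786885246}
```

Read: 200 extracted features (188 descriptor + 12 CC) were reduced to 3 by
MRMD forward selection, and the best single feature — the medium
normalized-van-der-Waals-volume composition, canonical 1-based index 43 —
classifies the 122 synthetic sequences with 99.2% cross-validated accuracy
(the planted effect here, 0.25 vs 0.40 medium-residue probability, is
deliberately strong and analytically tractable; real enzymes are harder).
The run directory contains the full feature matrix, the MRMD ranking table,
per-model metrics JSON, and a per-sequence export of the key feature's
values for scatter inspection.

The same analysis is scriptable from the shell:

```bash
enzyph synth --n-acid 54 --n-alkaline 68 --seed 2 --outdir data/
enzyph extract --acid data/acid.fasta --alkaline data/alkaline.fasta --out features.csv
enzyph select  --features features.csv --out ranking.tsv
enzyph evaluate --features features.csv --model rf --out eval.json
```

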