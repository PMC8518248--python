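# triomics

Multi-omic concordance analysis for a three-layer autoimmune-disease
cohort design: a serum protein panel (proximity-extension-assay style,
with a lower limit of detection), a peripheral-blood-cell (PBC)
transcriptome, and a skin transcriptome measured on the same subjects.
The package asks the question such studies ask: *does the serum protein
profile reflect molecular dysregulation in the diseased end-organ (skin)
or in the blood cells it floats among?* It answers it three ways, each
with a permutation null:

1. **Effect-size concordance.** Moderated, covariate-adjusted
   differential expression (disease vs control) is fit per layer;
   Spearman's ρ between serum-protein effects and the effects of their
   gene-mapped transcripts is tested by relabeling disease/control
   status at the subject level jointly across layers and refitting.
2. **Network proximity.** On a protein-protein-interaction graph, every
   node gets a WAP (Well-Associated Protein) score
   S(v) = Σ_{u∈N(v)} w_u, the sum of its neighbors' differential-
   expression weights, ranked against a weight-permutation null. The
   serum hits' WAP ranks in skin vs blood are compared against
   degree-matched random sets, and the count of edges between serum hits
   and the top-k transcripts is tested against its expectation under the
   random graph with given expected degrees (Chung-Lu null,
   e_exp = Σ min(1, d_a·d_b / 2m), Poisson tail p).
3. **Between-sample similarity concordance.** Per layer, the
   subject-by-subject matrix of Spearman correlations between full
   sample profiles; a Mantel permutation test (randomly re-assigning
   samples to subjects in one layer) for each group × layer-pair cell.

Because real cohorts of this design are rarely fully public, the package
ships a first-class synthetic-data generator (`triomics.simulate`) that
emulates the study conditions — 49 disease / 25 control subjects (serum
for 47/24), a 981-protein panel with 70 heavily left-censored analytes,
two transcript layers whose gene maps cover 314 and 448 of the 911
retained proteins, planted group effects with tunable cross-layer
coupling, a trait (severity-score) loading, a shared per-subject latent
factor, and a power-law PPI network with a planted proximity module —
so every statistic can be validated against a known ground truth.

## Worked example

The numbered scripts under `analysis/` run the full study on the
default synthetic cohort and write their tables under `results/`:

```sh
python analysis/01_simulate.py --seed 1
python analysis/02_preprocess.py
python analysis/03_differential_expression.py --seed 1
python analysis/04_cross_layer.py --seed 1
python analysis/05_network.py --seed 1
python analysis/06_concordance.py --seed 1 --n-perm 1999
```

With seed 1 this prints (abridged):

```
serum: 981 assayed -> 911 retained (70 excluded for >50% below LLOD)
protein-transcript pairs via shared genes, serum-pbc: 314
protein-transcript pairs via shared genes, serum-skin: 448
serum: 56 features at FDR<5% (27 up, 29 down)
multivariate group separation (PCA, k=2): T2=244.6, p=0.001
serum-skin effect correlation: rho=0.381, permutation p=0.048 over 43 pairs
serum-pbc effect correlation: rho=-0.141, permutation p=0.671 over 35 pairs
disease vs severity concordance: 57/59 sign-concordant among FDR<5% hits
WAP rank comparison over 52 serum-hit genes: median (blood rank - skin rank) = 1084.0, p=0.001
edges serum-hits x top-100 skin: observed 50, expected 13.3, ratio 3.77, Poisson p=1.02e-14
edges serum-hits x top-100 pbc: observed 19, expected 21.5, ratio 0.89, Poisson p=0.731
  disease  serum-skin: rho=0.324, p=0.0005 (n=47)
```

Reading it: the censoring filter retains exactly the 911 analytes that
are not heavily censored; the serum hits' effects correlate with their
skin (but not blood) transcript effects; the serum hits sit far closer
on the network to the skin perturbation (rank shift p = 0.001, edge
ratios ≈ 4 vs ≈ 0.9); and the between-sample similarity structure is
concordant across layers wherever the shared subject factor acts — all
matching what was planted in the generator.

The same end-to-end run is available programmatically:

```python
from triomics import RunConfig, run_pipeline
bundle = run_pipeline(RunConfig(seed=1, out_dir="results/run"))
```

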