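# hemigrad

Hemispheric asymmetry of functional connectome gradients, as a tested,
reusable Python pipeline.

Resting-state fMRI studies increasingly describe cortical organization
through *functional gradients*: eigencomponents of a diffusion operator
built from functional connectivity (FC), along which regions with similar
connectivity profiles occupy nearby positions. `hemigrad` asks how that
organization differs **between hemispheres** — and how that asymmetry
differs between clinical groups (the motivating application is major
depressive disorder vs. healthy controls). It takes parcellated region ×
time matrices with a homotopic parcellation (mirror-matched L/R region
pairs sharing a pair index and a Yeo-7 network label) and produces, per
subject:

1. **Denoised series** — FD/DVARS volume censoring with the
   1-forward/2-back neighbour rule, cubic-spline interpolation, linear
   detrend, first-order zero-phase Butterworth band-pass (0.01–0.1 Hz),
   confound regression orthogonal to filtering (optional GSR), z-scoring.
2. **Hemispheric FC blocks** — Fisher-z Pearson FC cut into LL, RR
   (intra-) and LR, RL (inter-hemispheric) pair-indexed blocks.
3. **Gradients** — per block: keep each column's top 10% strongest
   connections, form the normalized-angle affinity
   `A_ij = 1 − arccos(cos(p_i, p_j))/π`, embed by anisotropic diffusion
   maps (α = 0.5, λ/(1−λ) scaling), and Procrustes-rotate (no scaling)
   the first 10 components onto group templates built from cohort-mean
   blocks.
4. **Asymmetry index (AI)** — the homotopic difference of aligned scores,
   `AI_intra = LL − RR` and `AI_inter = LR − RL`, over gradients G1–G3
   (positive = leftward). With 200 pairs this is the 3 × 200 = 600-feature
   space all group statistics and prediction run on.
5. **Group comparison** — parametric empirical-Bayes ComBat harmonization
   across sites (age, sex, mean FD preserved as covariates), then a
   multivariate GLM per region pair (and per network): Hotelling's T² for
   the group effect jointly across G1–G3 via its exact F transform,
   BH-FDR across units, and per-gradient post-hoc t-tests at p < 0.05/3.
6. **Prediction** — nested-CV elastic net (100 random 4:1 splits,
   per-partition ComBat, inner 5-fold CV selecting the penalty with
   minimum MAE on a 20-point log grid in [1e-4, 1]) predicting BDI-II
   from the AI features, with a permutation null for the mean test r.

A first-class **synthetic cohort generator** supplies ground truth for
every stage: a latent gradient drives FC through a squared-exponential
kernel mirrored across hemispheres, asymmetry is planted as
latent-position offsets of left-hemisphere regions (so AI must re-emerge
through the entire pipeline), sites act as location/scale shifts on
Fisher-z edges, and BDI-II depends linearly on a sparse subset of the
latent asymmetry features.

## Worked example

```python
import numpy as np
import hemigrad as hg

parc = hg.make_parcellation(100, 7)           # 200 homotopic regions
truth = hg.default_ground_truth(parc, seed=0) # planted DMN/SVA effects
ds = hg.simulate_cohort(truth, parc, n_mdd=50, n_hc=50,
                        n_timepoints=240, seed=0)
res = hg.analyze_cohort(ds, hg.RunConfig(cohort_dir="", out_dir="",
                                         prep=False))
mv = res["region_intra_mv"]                   # Hotelling T2 per pair
affected = np.isin(parc.pair_networks,
                   ["DefaultMode", "SalienceVentralAttention"])
sig = mv["significant"].to_numpy()
print(f"detected {sig[affected].mean():.2f} of planted pairs, "
      f"{sig[~affected].mean():.3f} of unaffected pairs flagged")
print(res["network_intra_mv"][["unit", "T2", "p", "q"]].head(3))
```

Output from this exact snippet:

```
detected 0.86 of planted pairs, 0.070 of unaffected pairs flagged
              unit         T2         p         q
0           Visual   6.677312  0.096017  0.096017
1      Somatomotor  12.064104  0.010894  0.025420
2  DorsalAttention  10.770065  0.018349  0.025689
```

86% of the pairs carrying a planted group effect (per-gradient Cohen's
d ≈ 0.5) are recovered at FDR 0.05, with 7% of unplanted pairs flagged
in this cohort — unplanted pairs are not strictly null, because any
FC-level perturbation propagates through the global embedding (two
subjects were also dropped by the embedding quality-control rule; see
`docs/methods.md` for both phenomena).

## Command line

```bash
hemigrad simulate --n-pairs 100 --n-mdd 20 --n-hc 20 --seed 1 --out cohort/
hemigrad run --config config.yaml --seed 1 --out results/
```

Subcommands `prep`, `gradients`, `asymmetry`, `compare` and `predict`
chain the stages through plain TSV/CSV files; every output carries a
provenance header (seed + config hash).

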