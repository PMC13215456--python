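# ptmls

Multimodal survival stratification from routine cancer data: deep +
morphometric **pathomics** features extracted from H&E slide images are
fused with **PTM-related transcriptomics** (genes tagged by
post-translational-modification category) in an autoencoder latent space;
survival-informative latent dimensions drive a patient-level risk score and
Gaussian-mixture subtypes. A companion single-cell module builds a
gene-regulatory network by subsampled principal-component regression with
CP tensor denoising and simulates **pseudo-knockouts** by deleting a gene's
outgoing edges and ranking genes by their displacement in an aligned
network embedding.

The package is aimed at computational-oncology researchers who want a
fully seeded, testable re-implementation of this kind of pipeline, with a
synthetic-data module that generates every input with known ground truth.

## The model

**Pathomics.** Slides are tiled into non-overlapping 512×512 patches; an
Otsu luminance mask drops tiles whose tissue fraction does not exceed
0.80; retained tiles are Macenko stain-normalized (stain vectors from the
1st/99th percentile extreme directions of the optical-density cloud,
OD = −log₁₀((I+1)/256)). Deep features come from a convolutional encoder
whose final stage is a C×7×7 activation grid, max-pooled per channel to a
C-vector (C = 2048 in the release configuration) after ImageNet-style
standardization (mean [0.485, 0.456, 0.406], SD [0.229, 0.224, 0.225]) at
224×224. Eleven curated morphometric descriptors are computed from
hematoxylin/eosin unmixing, adaptive-threshold nucleus segmentation
(diameters 10–50 px) and distance-limited whole-cell expansion.

**Fusion and prognosis.** Expression (significant PTM DEGs: FDR < 0.05 and
|log₂FC| > 1 under Welch-t + Benjamini–Hochberg) and pathomics tables are
inner-joined per sample, split 7:3, z-scored with training statistics and
compressed by an autoencoder (encoder 128→64→32, ReLU hidden / linear
latent, dropout 0.1, batch 64, learning rate 0.001, 150 epochs, MSE loss).
Each latent dimension zⱼ is screened by univariate Cox proportional
hazards (Newton–Raphson on the Breslow partial likelihood); the risk score
is the linear predictor r = Σⱼ β̂ⱼ zⱼ over selected dimensions, and
patients split into high/low risk at the training-median r. Separation is
summarized by Kaplan–Meier curves, the log-rank test and the group hazard
ratio; Gaussian-mixture subtypes use the silhouette-maximizing component
count.

**Single-cell pseudo-knockout.** After QC (genes in ≥ 10 cells; cells with
200–5000 detected genes and ≤ 10% mitochondrial UMIs) and log1p-CPM
normalization, directed networks W (regulators × targets) are inferred per
cell subsample by PC regression, sparsified, stacked and denoised by
CANDECOMP/PARAFAC alternating least squares into a consensus network. A
pseudo-knockout zeroes the KO gene's outgoing row; wild-type and KO
networks are embedded jointly via a coupled graph Laplacian, and each gene
gets a displacement δ between its two embeddings with a χ²₁ tail p-value
and BH FDR < 0.05 gate.

## Worked example

```python
from ptmls import synthetic as syn, pipeline as pl

cohort = syn.make_cohort(n=400, k=4, beta_true=[1.1, 0, 0, 0],
                         noise_sd=0.2, censor_rate=0.3, seed=17)
expr, path, surv = pl.cohort_tables(cohort)
res = pl.run_multimodal(expr, path, surv, seed=17)
print(f"train HR {res.train_hr:.2f} (95% CI {res.train_hr_ci[0]:.2f}-"
      f"{res.train_hr_ci[1]:.2f}), log-rank p = {res.train_logrank_p:.2e}")
print(f"valid HR {res.val_hr:.2f} (95% CI {res.val_hr_ci[0]:.2f}-"
      f"{res.val_hr_ci[1]:.2f}), log-rank p = {res.val_logrank_p:.2e}")
```

prints

```
train HR 3.51 (95% CI 2.57-4.79), log-rank p = 1.19e-16
valid HR 1.95 (95% CI 1.27-3.00), log-rank p = 1.93e-03
```

A synthetic cohort of 400 samples carries four shared latent factors, one
of which drives an exponential proportional-hazards survival time
(log-hazard effect 1.1, 30% censoring). The pipeline recovers the planted
signal: high- vs low-risk patients (median split of the learned risk
score) differ strongly in survival on the 280-sample training partition
and reproduce on the held-out 120 samples, which see only
training-derived statistics (z-scoring, encoder weights, Cox betas,
median cutoff).

A thin CLI mirrors the library: `ptmls pathomics`, `ptmls deg`,
`ptmls fuse`, `ptmls scgrn` (see `--help` for options).

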