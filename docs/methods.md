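# Methods

This note documents the models, the numerical choices and the synthetic
study conditions behind `ptmls`, in enough detail to reproduce or audit
any stage.

## Pathomics

**Tiling and masking.** Tiles are non-overlapping 512×512 blocks in
row-major order; right/bottom remainders are dropped (partial tiles would
distort pooled statistics). The tissue mask thresholds luminance with
Otsu's method and takes the darker class as tissue; a constant image has
no separable classes and yields an empty mask with a warning. A tile is
retained iff its tissue fraction strictly exceeds 0.80.

**Stain model.** Optical density is OD = −log₁₀((I+1)/256); the +1 offset
avoids log(0) at I = 255 ⇒ OD ≈ 0. Macenko estimation drops pixels with
any-channel OD < β = 0.15, projects the rest on the top-2 eigenvectors of
the OD covariance and takes the 1st/99th percentile extreme angle
directions as stain vectors. Hematoxylin is the column with the larger
red/blue OD ratio: hematoxylin looks blue because it absorbs red, so its
red OD component dominates (for the canonical vectors, H = (0.65, 0.70,
0.29) vs E = (0.07, 0.99, 0.11)). Concentrations are exact nonnegative
least squares — for a two-stain basis the NNLS solution is either the
unconstrained one or the better of the two clipped single-stain boundary
solutions, so it vectorizes per pixel. Normalization rescales source
concentrations by the ratio of the 99th-percentile reference
concentrations and reconstructs through the reference basis.

The β filter has one consequence worth knowing: pixels close to pure
eosin can fall below β in the red channel (eosin barely absorbs red), so
the eosin direction is estimated from the strongly stained pixels that
survive the filter. Stain recovery is sharpest on images containing
near-pure, strongly stained pixels; the synthetic mixture generator
(`make_stain_mixture`) draws U-shaped Beta(0.3, 0.3) mixing fractions for
that reason, and recovery there is well under 1°.

**Deep features.** The backbone contract is any callable mapping a
3×224×224 standardized image to a C×7×7 activation grid. The bundled
`TinyResNet` is a seeded NumPy encoder — five stride-2 3×3 conv+ReLU
stages (224→7) and one residual block at the final resolution, He
initialization — used at C = 32 in tests; the release configuration is
C = 2048. Pooling is the per-channel spatial maximum; slide-level
aggregation is the element-wise mean over retained tiles, which makes the
slide vector invariant to tile duplication.

**Objects and morphometrics.** Nuclei are segmented on the hematoxylin
concentration channel: local-mean adaptive threshold (window 51 px,
offset 0.05), watershed split on the Euclidean distance transform with
peak markers, and an equivalent-diameter gate of [10, 50] px. Whole cells
are distance-limited nearest-nucleus expansion (`expand_labels`), which
guarantees disjoint cells containing their nuclei. The 11 descriptors are
nuclei_count, mean/sd nucleus area, mean perimeter, mean eccentricity,
mean solidity, mean hematoxylin intensity in nuclei, mean eosin intensity
in cells, 8-level 1-px 4-direction GLCM contrast of the hematoxylin
channel, nuclear density (nuclei per 10⁴ tissue px; full image area if no
mask is supplied) and the mean CV of intensity over 4 concentric
erosion-depth rings per nucleus. Zero-nucleus images report count 0,
density 0 and NaN object statistics.

## Differential expression

The screen restricts to the user-supplied PTM gene list, computes
log₂FC as the difference of group means on log2-scale values, tests with
Welch's t and adjusts with Benjamini–Hochberg over the tested PTM genes.
A gene is significant iff FDR < 0.05 **and** |log₂FC| > 1. This is a
deliberate self-contained decision rule: the thresholds, not a particular
moderated-variance engine, are what the downstream fusion consumes.

## Fusion autoencoder

Architecture: d→128→64→32 encoder, mirrored 32→64→128→d decoder, ReLU
hidden activations, linear latent and output. Training: per-column
z-scoring with training statistics (the validation path has no fit
method — leakage is structurally impossible), inverted dropout 0.1 on
hidden activations, plain mini-batch SGD (no momentum) with batch 64,
learning rate 0.001, 150 epochs, MSE loss; seeded Glorot-uniform init and
seeded shuffling give bitwise-reproducible weights and loss traces. The
latent space is the innermost 32-unit layer. These hyperparameters are
the pipeline's release configuration; convergence-focused tests may use
more epochs or a higher learning rate, which only the optimizer sees.

The end-to-end survival recovery does not require the autoencoder to
converge to a perfect reconstruction: any well-conditioned linear-ish
image of the input space preserves the prognostic factor, which the Cox
screen then finds. What the reconstruction objective adds is stability
and denoising of the latent basis.

## Survival screening and risk

`cox_fit` maximizes the univariate Breslow-ties partial likelihood by
Newton–Raphson (|Δβ| < 1e-8 or 50 iterations, step-halving above |Δβ| = 5,
|β| > 50 treated as monotone likelihood). Each latent dimension is
standardized before screening; α = 0.05. If nothing passes, the smallest-p
dimension is kept with a warning so the downstream risk score is always
defined. The risk score is the Cox linear predictor over selected
dimensions, using training-set means/SDs for standardization; the median
cutoff is computed on training risks only, and ties at the median go to
low risk. Subtypes come from a diagonal-covariance GMM (10 seeded
k-means++ restarts, covariance floor 1e-6) with k ∈ 2..6 chosen by mean
silhouette; exact ties prefer the smaller k. KM curves and the log-rank
test are delegated to lifelines; the group hazard ratio is `cox_fit` on
the high/low indicator with CI exp(β ± 1.96·se).

## Interpretation

Permutation importance: baseline Harrell C of the risk score, then per
feature permute its column (seeded), re-encode, re-score; importance is
the mean concordance drop over repeats. A feature the encoder ignores has
importance exactly 0; importances are not constrained to sum to anything.
Spearman maps use average-rank ties; constant columns give NaN with a
warning.

## Single-cell GRN and pseudo-knockout

**QC order** is fixed: genes first (detected in ≥ 10 cells), then cells
on the gene-filtered matrix (detected genes within [200, 5000],
mitochondrial fraction ≤ 0.10, mito genes by the configurable "MT-"
prefix). **pcnet**: for each target gene, PCA (top 20 PCs, reduced if
rank-deficient) of the other genes across cells, least-squares regression
of the target on the scores, coefficients back-projected through the
loadings to per-regulator weights; zero diagonal.

**Consensus**: each of n_nets subsample networks keeps its top_q fraction
of entries by |w|; the G×G×n_nets stack is decomposed by CP/ALS
(Kolda–Bader mode-n unfoldings, seeded Gaussian init, 100 sweeps or
relative fit change < 1e-6, error if the residual rises 5 consecutive
sweeps), reconstructed, averaged over the subsample mode and scaled to
max |w| = 1. The CP rank bounds the gene-space rank of the consensus
(the slice-averaged reconstruction is a rank-`cp_rank` matrix), so
`cp_rank` should be at least the expected rank of the true network plus
noise headroom; the signature default (3) suits large sparse networks,
while the 10-gene test fixtures use cp_rank = 10 ≈ min(G, n_nets) and
top_q = 0.2 (the planted edge density there is 7/90 ≈ 8%, so a 5% cut
would drop true edges by construction).

**Alignment**: both networks are symmetrized A = (|W| + |Wᵀ|)/2 and
coupled into a joint 2G×2G graph with μ = 0.9 × mean diag-free row sum on
the identity correspondence. The embedding uses the smallest nonzero
eigenvectors of the joint Laplacian *restricted to predominantly
symmetric modes* (‖a+b‖ ≥ ‖a−b‖ for the two copies' halves): purely
antisymmetric modes exist even for identical graphs (their eigenvalues
sit 2μ above the symmetric branch) and would report displacement
everywhere, and eigenvalue crossings mix them into the smallest set.
With the filter, aligning a network against itself is a zero map and
perturbation-localized asymmetry passes through. d_embed must be well
below the number of genes — only G−1 symmetric modes exist and the
highest ones carry subsample noise; the default 30 is sized for
genome-scale networks, and the 10-gene fixtures use 6. Displacements are
converted to p-values by the scaled-χ²₁ convention (δ²·G/Σδ² against
χ²₁'s upper tail, the KO gene excluded from the ranking and the scaling),
then BH with significance at FDR < 0.05. Enrichment of perturbed sets is
a one-sided hypergeometric upper tail per user-supplied set with BH
across sets.

## Synthetic study conditions

**Slides** render a smoothed-noise tissue blob thresholded at the exact
coverage quantile, smooth eosin concentration (1.0–1.8) with a small
hematoxylin floor (0.05), and non-touching elliptical nuclei (default
radii 5–12 px, axis ratio ≥ 0.7) that add 1.1 hematoxylin and displace
eosin (chromatin-dense nuclei), all pushed through the same Beer–Lambert
model the unmixing inverts, with the true stain matrix retained.

**Cohorts**: z ~ N(0, I_k), features = z·loadings + σ·N(0,1) per
modality, exponential event times with hazard 0.01·exp(zᵀβ)/day,
independent exponential censoring whose rate is solved numerically
(Brent) so the expected censored fraction equals the request. The
end-to-end condition is n = 400, k = 4, β = (1.1, 0, 0, 0), σ = 0.2, 30%
censoring, d_expr = 30, d_path = 20.

**Single cells**: per-cell SEM x = (I − Wᵀ)⁻¹ε with ε ~ N(0,1), Poisson
counts with rate exp(x + 2.0) scaled by lognormal(0, 0.3) library sizes
(mean ≈ 7 counts per unregulated gene, 10x-like); generation refuses
spectral radius ≥ 1. Planted QC violations (mito-flooded cells,
two-gene low-complexity cells) are recorded by index, and naturally
high-mito clean cells are trimmed below 80% of the QC cut so the planted
set is exactly the violating set. The planted network for recovery tests
is a 10-gene graph: one hub with five signed targets plus two isolated
edges (true rank 3).

What the generators deliberately do **not** emulate: histology texture,
scanner artifacts and batch effects; non-proportional hazards or
informative censoring; count overdispersion beyond
lognormal-library × Poisson, dropout/zero inflation, and cell-type
mixtures. Passing tests therefore demonstrate correctness of the
machinery and recoverability under well-specified conditions, not
robustness to those real-data complications.

## Problem sizes

Tests and the acceptance script run desk-scale versions of each analysis:
512² synthetic slides, cohorts of 400, 10-gene/400–500-cell single-cell
fixtures, 20-seed repetition for stochastic claims. These sizes were
chosen so every stochastic claim has enough replication to be stable
while the whole suite stays interactive.

## Known limitations

- The slide-level aggregation of tile vectors (mean) and the per-slide
  (not per-tile) morphometric averaging are choices the upstream design
  left open; both are flagged in the output metadata.
- The Cox screen is univariate by design; correlated latent dimensions
  can co-select, and the risk score makes no attempt at shrinkage.
- The displacement p-value law is a pragmatic calibration convention; its
  null behavior is enforced empirically (super-uniformity under
  edge-free knockouts) rather than derived.
- `pcnet` is O(G) SVDs per network; genome-scale use would need
  randomized PCA and sparse storage.
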