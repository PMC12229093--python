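# Methods

## Model

### Stage 1 — contrastive alignment with momentum distillation

Each spot couples an RGB patch `h_i` (center-cropped to 40×40 px at the spot
coordinate, zero-padded at slide borders, then resized to the encoder input
resolution) with a log-CPM expression vector over the HVG panel. Two
encoders map both into a shared `embed_dim = 512` space:

- **Image encoder** — a standard pre-norm vision transformer over
  non-overlapping pixel patches with a class token; the class-token output
  passes through a linear head to 512. The full-scale configuration is
  ViT-B/32-shaped (224 px input, 32 px patches, 12×12×768); the tiny profile
  is 32 px input, 16 px patches, depth 2, width 64.
- **Gene encoder** — each panel gene is a token: a learned gene-identity
  embedding plus a learned embedding of its binned expression value
  (`n_bins = 16` over [0, 14] ≈ [0, ln(1+10⁶)]). A transformer backbone
  (12 layers × 8 heads full scale; 2 × 4 tiny) refines the tokens; a
  1-channel 2-D convolution with kernel (7, 5) and padding (0, 2) runs over
  the token × embedding map; global average pooling over the token axis
  yields one vector; three fully connected layers with ReLU between and
  after, followed by dropout, produce the 512-d embedding. The final ReLU
  makes gene embeddings non-negative; image embeddings are unconstrained —
  cosine retrieval is unaffected.

Similarities are cosines of L2-normalized embeddings. The contrastive loss
is the mean over both retrieval directions of the cross-entropy between the
temperature-`τ` softmax similarity rows and pseudo-targets
`y = α·p_M + (1−α)·I`, where `p_M` comes from momentum copies of both
encoders updated by EMA with coefficient `β`. `ln p` is clamped at 1e-12.
Defaults: `β = 0.995`, `α = 0.4` (constant; a ramp schedule can be plugged
in), `τ = 0.07`, in-batch negatives only (the softmax normalizes over the
batch), and momentum copies include the embedding heads so momentum
similarities live in the same space as the primary ones.

The IGM head gives spot-level (rather than batch-level) supervision:
self-attention over the gene encoder's backbone tokens, cross-attention with
the image encoder's patch tokens (gene side as query, image side as
key/value, scaled by 1/√d_k), a residual feed-forward block — all post-norm
— then a 2-layer MLP on the first fused token producing one matching logit.
Negatives are mined from the detached momentum similarity matrix of the
current batch: for every expression profile the most similar non-matching
image, and symmetrically for every image the most similar non-matching
profile (the one-sided variant is a flag). The loss is mean binary
cross-entropy; it is added to the contrastive loss with weight
`lambda_igm = 1` and its gradient flows into both encoders (a stop-gradient
flag restricts it to the head). One optimizer step (AdamW, lr 1e-4, weight
decay 0.02 by default) is followed by the EMA update.

### Stage 2 — expression decoding

The frozen stage-1 image encoder supplies 512-d embeddings. Two linear
layers (ReLU between) lift them to `hidden_dim`; a learned linear map
reshapes the result into a short token sequence (8 tokens full scale, 4
tiny) with a learned positional embedding, because self-attention over a
single vector is degenerate. Post-norm transformer blocks
(attention → add & norm → FFN → add & norm) refine the tokens; the
mean-pooled sequence maps linearly to the target panel (300 genes full
scale, 50 tiny). Training minimizes the mean squared error between
predicted and true log-normalized expression; the implementation reports
the mean over entries so the loss is batch-size invariant (the raw
Frobenius-norm variant is available behind a flag). A fingerprint check
guarantees the encoder is bitwise unchanged by stage-2 training.

### Whole-slide inference

A slide is tiled without overlap (tile = 512 px by default). Per tile,
tissue fraction `T_t` is the share of pixels whose HSV saturation exceeds
0.08 (near-white background is unsaturated; Otsu's method is the fallback
when no threshold is given), and nuclei fraction `N_t` is the share whose
hematoxylin channel after color deconvolution exceeds 0.07 — a value chosen
once when the detector was built, between the deconvolved response of
unstained/eosin-only pixels (≈ 0) and of hematoxylin-stained nuclei
(≈ 0.15); both thresholds are arguments. Tiles with `T_t < 0.6` are
excluded (the boundary itself is kept — half-open convention); the rest are
ranked by `N_t · tanh(T_t)` with ties kept in raster order, and the top 20
are resized, encoded and decoded. The slide-level prediction is the
elementwise mean over the selected tiles; if fewer than 20 survive the
filter, all survivors are used and a warning is raised.

## Preprocessing

- **Normalization**: `ln(1 + 10⁶ · c_ij / Σ_j c_ij)`. The pseudo-count
  keeps zeros at zero and the transform defined everywhere; within-spot rank
  order is preserved and `Σ_j (e^x − 1) = 10⁶` per spot. All-zero spots are
  an error (they carry no signal and break CPM).
- **HVG panel** (encoder input, k = 2000 full / 128 tiny): top-k by
  dispersion = variance/mean of the log-normalized values, computed on the
  pooled training spots (per-slice selection is a flag), ties broken by gene
  name so selection is deterministic and permutation-invariant.
- **Target panel** (decoder output, k = 300 full / 50 tiny): top-k by mean
  log-normalized expression across all training spots, same tie rule.
- **Augmentation** (training only, fully seeded): random crop-and-resize,
  horizontal/vertical flips (p = 0.5 each), additive brightness and
  multiplicative contrast jitter within configurable bounds, in that order.
- Coordinates are pixel-space patch centers, 0-based, (x = column,
  y = row); border crops are zero-padded rather than dropped so the spot
  count is stable.

## Synthetic data

The generator plants a shared latent `z_i ~ N(0, I_d)` (d = 4) per spot on a
regular grid. Counts are `Poisson(depth · softmax(z_i W))` with a fixed
seeded loading matrix `W` (depth 5000, 200 genes by default; a
negative-binomial option adds overdispersion). Images are an analytic
linear render: per latent component a fixed low-frequency sinusoidal RGB
pattern, summed with weights `z_i` around mid-gray, plus Gaussian pixel
noise (sd 0.02 of the dynamic range). Because the image→latent map is
exact and linear, recovery failures indict the model code, not the data.

What this emulates: paired modalities with common low-dimensional structure,
Poisson count noise, CPM-scale totals, a spatial grid for adjacency
protocols. What it does not: histological texture, stain variation,
segmentation difficulty, spatial autocorrelation of expression, batch
effects, dropout beyond Poisson sampling. Passing recovery tests therefore
demonstrates that the objectives, encoders and pipeline plumbing work — not
that the model reaches any particular accuracy on real tissue.

The slide fixture paints saturated-pink tissue ellipses and dark-violet
nuclei disks (density increasing left to right so tile scores vary) on a
near-white background, and returns exact per-tile mask fractions, so the
classical tissue/nuclei detectors can be checked against ground truth.

## Problem sizes and numerical choices

- The desk-scale (tiny) profile used by the tests and the acceptance
  script: 320 spots (16×20 grid, 256 train / 64 held out), 200 genes → 128
  HVG / 50 targets, encoders depth 2 / width 64 at 32 px, 300 alignment
  steps and 200 decoder steps at batch 32, lr 1e-3, gene-encoder dropout
  0.1. These sizes were chosen so a full two-stage run finishes in a few
  minutes on one CPU while leaving a wide margin over chance; the full-scale
  defaults (2000/300 panels, 12-layer encoders, dropout 0.5, lr 1e-4)
  remain the configuration of record.
- Parameters and activations are float32; AdamW moments float64. The
  float64 path is used wherever tests compare against closed forms.
- Softmax and log-softmax subtract the detached row maximum (exact, stable);
  BCE-with-logits uses the `max(l,0) − l·y + ln(1+e^{−|l|})` form.
- Ties: hardest-negative mining and candidate adjacency break ties by
  smallest index; panel selection by gene name; tile ranking by raster
  order. Retrieval ties count as incorrect (conservative).
- Pearson of a constant vector is undefined: reported as NaN with a warning
  and excluded from means.
- Degenerate inputs are errors, not silent fixes: batches of one spot (no
  negatives), all-zero spots, k larger than the pool, slides smaller than a
  tile, unfrozen encoders in stage 2.
- Determinism: one global seed fans out to per-stage seeds via SHA-256;
  dropout and batch sampling draw from generators seeded per run, so two
  runs with the same config and seed are bitwise identical.

## Design choices where the design was open

- **Autodiff engine**: the models are built on a ~300-line reverse-mode
  tensor library over numpy written for this package. At the desk-scale
  sizes above, numpy matmuls dominate and a full training run costs minutes,
  which keeps the whole pipeline dependency-light and reproducible anywhere.
- **Gene tokenization**: bin-embedding plus identity-embedding (the scheme
  published for large single-cell transformer pretraining), trainable from
  scratch; pretrained-weight loading is an optional hook, never a
  requirement.
- **Convolution layout**: the (7, 5) kernel runs over the token × embedding
  map as a 1-channel image — the only layout consistent with that kernel
  and padding (0, 2), which preserves the embedding width.
- **Fusion dimensionality**: the fusion block operates at the encoders'
  backbone width (both encoders must agree), on token-level features rather
  than pooled embeddings, so cross-attention has a non-trivial key set.
- **"Previous round" negatives** are read statelessly as the current
  batch's momentum similarities (detached) — the closest interpretation that
  avoids a global feature cache.
- **Candidate pools** are the true partner plus k neighbors (pool k+1,
  chance 1/(k+1)); pool size is configurable, Euclidean adjacency on stored
  coordinates (hex-aware adjacency out of scope).

## Known limitations

- No stain normalization, nuclei segmentation learning, or spatial-context
  modelling (neighboring spots are treated independently).
- Batch effects are not modelled explicitly; nothing in the architecture
  disentangles them from biology.
- The gene encoder's final ReLU confines gene embeddings to the
  non-negative orthant; alignment works, but half the embedding space is
  unused on the gene side.
- Poisson counts understate the overdispersion of real UMI data unless the
  negative-binomial option is enabled.
- Pyramidal-TIFF slides are read at level 0 only; slides are assumed to fit
  in memory as arrays.
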