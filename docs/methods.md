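# Methods

`freqsr` implements a progressive-upsampling adversarial model for
single-image super-resolution (SISR) under a *real-noise* degradation
model, together with the degradation pipeline, losses, metrics and a
synthetic-fixture generator that make every stage testable on one CPU with
no external data. This note records the model, its assumptions, the
numerical choices, and what the desk-scale experiments do and do not show.

## Degradation model and noise pool

LR training inputs are synthesized from HR images as

    lr = clip( decimate_s( hr ⊛ K ) + n , 0, 1 )

where `K` is an anisotropic Gaussian kernel (covariance
`R(θ) diag(σ_major², σ_minor²) R(θ)ᵀ`, sampled on an odd integer grid and
normalized to sum 1), `decimate_s` keeps every s-th pixel after blurring,
and `n` is *real* noise resampled from a harvested pool. The pool is built
by scanning LR images with a d×d window (stride `sg`): a window P is
*smooth* when every dl×dl sub-window Q (stride `sl`) satisfies
`|Mean(Q) − Mean(P)| ≤ α·Mean(P)` and `|Var(Q) − Var(P)| ≤ β·Var(P)`
(population variance, means/variances pooled over pixels and channels).
Smooth windows, mean-subtracted per channel, become the pool; sampling
tiles a target with randomly drawn, randomly flipped patches.

Defaults `d=16, dl=8, sg=8, sl=4, α=β=0.1` follow the real-noise-collection
literature; the sources only constrain α, β ∈ (0,1), so all are
configurable. When `Mean(P)=0` (or `Var(P)=0`) the right-hand side
collapses to zero and the rule degenerates to exact equality; a tolerance
of 1e−12 is applied there because the relative form is ill-posed at zero.
Blur-then-decimate uses reflective padding; bicubic downsampling is
available as an ablation mode. Kernel estimation from unpaired data is out
of scope — an externally estimated kernel can be wrapped as a raw array.

## Frequency decomposition

`decompose` splits an image into `low = x ⊛ G(σ)` (per channel, reflective
padding) and `high = x − low`, so reconstruction is exact by construction.
Defaults σ=2.0, ksize=13 (≈6σ+1); the filter parameters are not fixed by
the method, and guided-filter and bilateral variants are provided behind
the same interface for the decomposition ablation. Decomposition is
applied once, to the LR input; the two streams are initialized from
shallow convolutions of the high/low components plus the trunk output.

## Generator

Channel-first `(3,H,W)` images in [0,1] throughout; all learnable
computation runs on an in-house reverse-mode autodiff engine over float32
numpy arrays (`freqsr.nn`) — convolutions via im2col/GEMM with the batch
folded into one matrix product, depthwise 3×3 via fused shifted adds,
depthwise large kernels via FFT. Every adjoint is checked against central
finite differences in the test suite.

Pipeline (×2; ×4 stacks two stages): shallow 3×3 convs on the LR input and
on its two frequency components → `n_rmb` residual multiscale blocks
(RMB) → high/low streams (trunk + shallow component features) → `n_cam`
collaborative attention blocks (CAM) → 1×1 merge → progressive sub-pixel
×2 stages (3×3 conv to 4C, pixel shuffle, PReLU, plus a bilinear ×2 skip)
→ 3×3 conv to RGB → global bicubic skip → clip.

*RMB* stacks three MPMS blocks with a dual residual (`out = in + y₁ + y₃`).
*MPMS* combines: dilated depthwise 3×3 convs (rates 1,2,3) concatenated
and fused by a 1×1 conv; a shared depthwise 27×27 branch (a dense 27×27
C→C conv is incompatible with a sub-million parameter budget); a
squeeze-and-excitation gate; and a pooling branch (1×1 conv, stride-1
3×3 average+max pooling, 3×3 conv, per-channel affine, channel
layer-norm) — the two branch outputs multiply elementwise. Pooling is
stride-1/same-padded because the branch sums pooled and unpooled maps.
*CAM* exchanges information between streams: the high branch applies
detail-preserving pooling (local-contrast-weighted 3×3 average, weights
∝ 1 + |x − local mean|), parallel CBAM-style spatial and channel
attention, and a norm+conv fusion; the low branch computes K-sparse
channel attention — mask the top-K1 channels of the mean-|x| score and
the top-K2 channels of the spatial-variance score, combine as
`0.1·s₁ + 0.3·s₂`, softmax over all channels (ties break to the lower
channel index; the selection is constant in the backward pass) — and the
streams multiply each other's transforms. "Linear" layers are 1×1
convolutions; MLPs are two 1×1 convolutions with a PReLU between.

Width defaults: C=16 base channels, K1=C/4, K2=C/2, SE reduction 8,
8 RMBs and 8 CAMs. These land the ×2 generator at 489,403 learned scalars
(×4: 498,699), inside a 500 k budget; wider variants grow quadratically
(C=32 measures 1.35 M).

**Initialization.** The network must start close to its bicubic skip, or
adversarial training begins from saturated garbage: He-initialised MPMS
products and the non-residual CAM stream otherwise amplify activations
~3× per block. Three numerical choices enforce a near-identity start:
the MPMS layer-norm gain starts at 0.1 (each RMB ≈ identity + small),
the CAM output projections start at gain 0.5 (stream magnitude preserved
per block), and the final RGB conv starts at gain 0.01. During training
the *unclipped* output is used — a clipped pixel has zero gradient and
would be permanently stuck at 0 or 1.

## Discriminator

VGG-style: shallow 3×3 conv + LeakyReLU(0.2), then stride-2
conv/batch-norm/LeakyReLU stages with doubling channels (capped at 8×
base), a final conv + batch-norm, global average pooling and a sigmoid
head, so any crop size ≥ the total stride is accepted. Batch-norm uses
batch statistics in training and running statistics at inference.
The discriminator step runs on one *mixed* batch of real and detached
generated crops: normalizing them separately lets the network separate
the classes through batch-level statistics alone, which collapses to
chance once running statistics are used at evaluation.

## Losses

* adversarial (generator): `Σ −log D(G(lr))`, non-saturating, summed over
  the batch; probabilities clamped to [1e−7, 1−1e−7].
* discriminator: `−Σ log D(hr) − Σ log(1 − D(G(lr)))`.
* spatial consistency: features of the SR output and of the bicubically
  upsampled LR input are partitioned into 4×4 cells; for each cell and
  each 4-connected neighbour, `(|Δ_out| − |Δ_ref|)²` of cell-mean features
  accumulates over channels and ordered neighbour pairs, divided by the
  number of cells.
* color constancy: gray-world penalty `Σ_{p<q} (J_p − J_q)²` on channel
  means.
* combined: `L_per = L_spa + 0.1·L_col + 1e−3·L_adv`.

The feature extractor is pluggable. A pretrained VGG19 (relu5-4) backend
can be requested but raises a clear error when no deep-learning runtime
provides it; the default backend is a fixed random conv stack — three 3×3
convolutions (16 channels) with LeakyReLU between, weights drawn once
from the run seed and never trained, *valid* padding so constant images
keep constant features. It is a synthetic stand-in for a perceptual
network: deterministic and nonlinear, but shallow and untrained, which
matters for what the desk-scale experiment can show (below).

## Metrics

PSNR is `10·log10(peak²/MSE)` over all pixels and channels (identical
images report `inf`). SSIM is the standard mean of local 11×11
Gaussian-weighted windows (σ=1.5, C1=(0.01·peak)², C2=(0.03·peak)²,
population statistics), averaged over RGB channels, with the half-window
border cropped; it matches `skimage.metrics.structural_similarity` within
1e−4 and that library serves as the independent oracle in tests — never as
the implementation. LPIPS-style perceptual distance is delegated to a
pluggable backend and is never silently zero; a seeded random-feature
backend (labelled synthetic) exercises the formula in tests. Metrics are
computed on RGB directly; no luma conversion.

## Training protocol

Adam(β₁=0.5, β₂=0.999, ε=1e−8) for both networks, learning rate 1e−4,
constant schedule. Per iteration: sample HR images, augment (rotation by
k·90°, horizontal flip, rescale by {0.7, 0.85, 1.0} — each enabled
augmentation fires independently with probability ½; rescales that would
drop below the crop size are clamped), crop 64×64, degrade per crop
(noise drawn per crop), then one discriminator update on the mixed batch
and one generator update on `L_per` with fresh discriminator
probabilities. All randomness — initialization, batch order, crops,
augmentation, noise — derives from the run seed; checkpoints store
parameters, optimizer moments, batch-norm buffers and the RNG state, so a
resumed run reproduces the uninterrupted run's losses exactly.

## Desk-scale study

The end-to-end experiment trains the ×2 model on 200 synthetic 64×64 HR
fixtures (a balanced mix of gradients, checkerboards, band-limited
textures and histology-like blob fields) for 1,500 iterations at batch 8
on one CPU, and evaluates on 32 held-out fixtures against bicubic
upsampling. Degradation: isotropic Gaussian blur σ=1.5 plus noise from a
pool harvested from 40 emulated real LR images (same blur + Gaussian
sensor noise σ=0.03, a mid-range consumer-sensor level). To keep the full
run near ten minutes of pure-numpy compute the study uses reduced widths:
C=16, one RMB, one CAM, discriminator base 16 with 3 stages. These sizes
were fixed from step-time measurements alone.

What the study shows — and does not. The fixtures exercise flat regions,
hard edges, periodic texture and blob morphology, but none of the optical
or compression characteristics of real photographs or scanners, and the
random-feature spatial-consistency loss is a much weaker semantic anchor
than pretrained VGG features. The study demonstrates the training
*mechanism* (stable alternating optimization, discriminator separation,
loss descent, exact resumability) at 1/40 of the published iteration
count and a fraction of the width; held-out PSNR relative to bicubic at
this scale reflects the equilibrium between the blurry-reference spatial
anchor and the weak (1e−3) adversarial pressure, not the capability of
the full-scale published configuration. A block-2 checkerboard under
σ=1.5 blur and ×2 decimation is essentially unrecoverable (≈6 dB for any
method) and is retained deliberately as an aliasing stress case.

## Known limitations

* No JPEG/motion-blur degradations; no unpaired kernel estimation.
* Scales limited to ×2 and ×4; no self-ensemble.
* The engine is CPU-only float32; wall-clock is minutes per thousand
  iterations at desk widths, so published-scale (60 k-iteration) runs are
  out of reach here by design.
* 16-bit output is TIFF-only (the installed PNG codec cannot write 16-bit
  RGB).
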