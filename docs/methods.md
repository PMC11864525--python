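# Methods

## Problem and approach

Magnitude MR images of sparse, line-like structures — plant roots in soil,
brain-vessel angiograms — lose fine detail when denoising networks are
trained with voxel-wise losses (L1/L2): thin tubes contribute almost nothing
to a voxel average and get smoothed away. `uperc3d` implements the
*untrained perceptual loss* (uPL) for 3D volumes: the training objective
compares feature maps of a frozen, **randomly initialized** 3D convolutional
network φ between the prediction ŷ and ground truth y,

    PL(ŷ, y) = Σ_j  1/(C_j·H_j·W_j·D_j) · ‖φ_j(ŷ) − φ_j(y)‖²₂ ,

where j runs over the extractor's activation tap points and C_j, H_j, W_j,
D_j are the channel and spatial dimensions of layer j. No pretrained 3D
feature network is needed: random convolutions already respond to local
structure (edges, tubes), which is what a denoiser of sparse curvilinear
images must preserve. The sum over j defaults to *every* ReLU output of the
loss network; a layer mask can restrict it.

## Loss networks

The default extractor is deliberately small: 3 convolutional layers, kernel
3³, 32 channels each, same padding, ReLU, no pooling. The full ablation
space is available: depth ∈ {3, 5, 7, 9, 13}, kernel ∈ {3, 5, 7, 9}, max
pooling (window 2) after any subset of layers, and five weight
initialization schemes — Kaiming uniform/normal, Xavier uniform/normal, and
a "default uniform" U(−k, k) with k = (C_in·∏ᵢKᵢ)⁻¹, the reciprocal of the
fan-in. That bound is implemented exactly as stated; because the
conventional variant uses the reciprocal *square root* of the fan-in, a
`legacy_sqrt_bound` flag provides it. Kaiming/Xavier biases are
zero-initialized (their standard convention); default-uniform draws biases
from the same band as weights. Xavier normal is the package default (in the
source study it was the best-behaving scheme, and fan-based schemes avoid
the vanishing activations the reciprocal-fan-in bound produces at depth).

3D translations of VGG19 and AlexNet convolutional stacks are available as
presets (channel progressions unchanged, 2D convs/pools → 3D). Their tap
points are capped at the first 8 activations by default to bound memory;
layers beyond the last tap are not built. With taps capped, the AlexNet
preset requires inputs of at least 31 voxels per axis (the strided stack
otherwise collapses below one voxel).

Extractors are frozen: every parameter is excluded from optimization, and
the training harness records a checksum plus a bit-identity check of the
full state before and after each run.

## Denoising networks

Three shape-preserving architectures map a (B, 1, D, H, W) volume to a
denoised volume:

* **DnCNN** — conv(64, k3) + ReLU, then 3 × [conv(64) + ReLU + batch norm],
  then conv(1): exactly five convolutions at defaults. The network predicts
  the clean image directly; `residual_output=True` switches to noise
  prediction (out = in − f(in)).
* **ResNet** — conv(64) + PReLU head; 5 residual blocks of
  [conv + batch norm + PReLU] with an additive identity skip per block;
  conv + batch norm + PReLU tail; final 1-channel projection conv. The
  width (64) and the final projection are this package's choices — a
  description ending at an activation cannot emit a 1-channel image — and
  per-block identity skips are the standard residual reading.
* **Transformer** — conv(8, k3) head; N = 4 sequential blocks of
  [MDTA channel attention → gated feed-forward]; conv(1) tail; no spatial
  down/up-sampling. MDTA computes queries/keys/values per channel (1×1×1
  convs), flattens space to length L = D·H·W, L2-normalizes each channel
  vector and forms a softmax attention matrix of shape channels × channels
  scaled by a learnable temperature — cost quadratic in channels, *linear*
  in voxels. The gated feed-forward expands through convs of width 16 then
  32 (kernel 3), multiplies the two 16-channel halves elementwise, and
  projects back to 8 channels so the residual connection type-checks. Block
  count (4), head count (1) and the gating algebra are package choices; the
  source description fixes only the conv widths.

Default parameter counts are regression-pinned: DnCNN 335 873, ResNet
668 232, transformer 71 453.

## Numerical engine

No deep-learning framework is assumed: `uperc3d.nn` is a small reverse-mode
autodiff engine on numpy. 3D convolutions are lowered to one BLAS matrix
product per layer (im2col); the input gradient of a stride-1 convolution is
computed as a single transposed-convolution GEMM rather than a scatter
loop; frozen layers skip weight-gradient work and drop their im2col buffer.
All gradients are verified against central finite differences in the test
suite. Training tensors are float32; the SSIM objective evaluates in
float64 so it agrees with the evaluation-side SSIM to ~1e−6.

## Synthetic phantoms and noise

Real root/MRA volumes are not redistributable at package scale, so training
and evaluation run on synthetic phantoms that emulate the two properties
that matter — sparsity and connectivity. Each phantom draws tubes as
persistent random-walk centerlines (step 0.5 voxels, per-step direction
perturbed by at most `curvature` radians, reflecting at the walls), dilated
to a random radius with a 1-voxel anti-aliased shell. Tubes avoid merging:
a new tube is re-drawn (up to 20 attempts) if it touches the dilated
foreground, mirroring the fact that distinct roots/vessels rarely fuse.
Each primary tube may spawn one child branch at 0.7× its radius. Defaults
(64³, 5 tubes, radii 1–2.5 voxels, intensities 0.6–1.0 on background 0.02)
give foreground fractions of 2–4%, comparable to the sparsity of root
scans. The phantoms do **not** model MR acquisition physics (k-space, coil
sensitivities, bias fields, partial-volume texture), so passing results
demonstrate the training machinery and the relative behavior of losses on
sparse tubular data, not clinical image quality.

Rician corruption uses the standard two-channel construction
out = √((v+g₁)² + g₂²) with g₁, g₂ ~ N(0, σ²). The noise level is a
fraction of the clean volume's peak intensity (σ = level × max v); since
the protocol's percentage levels (1%, 5%, 10%, 20%) are fractions of
*something* unstated, the peak is the simplest consistent reading, is
configurable via the `peak` argument, and makes the levels well defined
after per-volume max normalization. Volumes are normalized to [0, 1] by
their maximum (not a percentile): max normalization keeps the noise
fractions exact on the clean signal.

## Training protocol

Adam (standard betas), learning rate 0.001. The reference protocol is
30 000 iterations, batch 16, random 96³ crops (`TrainConfig.reference()`);
crops are drawn with uniformly random corners, identically for the clean
and noisy version of a volume. Each volume is corrupted once with a
per-volume derived seed, as in a fixed noisy acquisition. One experiment
seed derives independent sub-seeds (model init, crop sampling, noise) via
`numpy.random.SeedSequence`, so ablations vary exactly one factor; the loss
network's seed lives in its own config. Validation SSIM is computed every
50 iterations on full (uncropped) volumes, and the *final*-iteration
weights are returned (no early stopping or best-checkpoint selection —
the protocol states none, so the simplest rule is used). Batch-norm layers
use batch statistics in training and running averages in eval, momentum
0.1. A non-finite training loss aborts with the iteration number.

## Desk scale

CPU-feasible sizes, chosen once from the engine's measured FLOP throughput
and then fixed: 150 iterations, batch 2, 16³ crops, 64 training phantoms of
32³ voxels (3 tubes each), 4 validation phantoms, 10% noise, DnCNN at full
width (64 channels), uPL extractor depth 3 / kernel 3 / 32 features /
Xavier normal. One run takes roughly 1.5–2 minutes on a single CPU core.
The acceptance experiment trains this configuration with uPL and with L1
for three seeds each and requires the denoised validation SSIM to exceed
the noisy-input SSIM by at least 0.05 in at least two of three seeds (uPL),
with L1 also improving — a learning-signal property, not a reproduction of
the full-scale benchmark numbers.

## Evaluation

SSIM uses a Gaussian window (σ = 1.5), window 11³ where it fits, otherwise
the largest odd window ≤ the smallest axis; constants C1 = (0.01·r)²,
C2 = (0.03·r)² with data range r = 1.0 after normalization. Local
statistics are evaluated only where the full window fits, and the mean map
value is reported; window and constants are configurable because SSIM
values shift with them. PSNR is 10·log₁₀(r²/MSE), reported as infinity for
identical volumes and excluded from means with a warning. Evaluation
regions mirror the study protocol: root volumes use a 52³ cube at z offset
0 and in-plane offset 70 (the protocol's stated in-plane range 70–132 spans
62 voxels, which contradicts the stated 52³ cube; the cube size is taken as
authoritative and anchored at 70), MRA volumes a centered 68³ cube.
Aggregation reports mean/std both pooled over images and over seed means.

## Known limitations

* The phantom generator covers geometry, not MR physics; absolute SSIM/PSNR
  values on phantoms do not transfer to scanner data.
* Desk-scale runs are far shorter than the reference protocol; they
  demonstrate correct machinery and a learning signal, not converged
  denoisers, and uPL-vs-L1 rankings at this scale are noisy.
* The numpy engine is single-process and keeps im2col buffers for trainable
  layers; memory grows with batch × crop³ × channels × 27.
* U-Net-style encoder–decoders are deliberately out of scope (they degrade
  on very fine structures in the source study), as are 2D slice-wise
  denoising and k-space reconstruction.
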