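# Methods

## The two-stage model

Lumbar-vertebra segmentation in whole CT volumes is dominated by class
imbalance: the five vertebral bodies occupy a small fraction of the scan.
The pipeline therefore splits the problem:

**Stage 1 — heatmap localization.** The target is not a segmentation but a
smooth spatial likelihood: the union of the five vertebra labels,
binarized, convolved with an isotropic Gaussian (σ = 3 voxels by default)
and divided by its maximum so the peak is exactly 1. A five-level
fully-convolutional encoder–decoder regresses this heatmap from the
bone-windowed volume resized to 96×96×128. All encoder levels carry 64
channels (two 3×3×3 convolutions each, 2×2×2 max-pooling between levels),
giving maps at 96×96×128, 48×48×64, 24×24×32, 12×12×16 and a 6×6×8
bottleneck. Each decoder level upsamples the deeper map with a stride-2
2×2×2 transposed convolution and concatenates the channel slice
`[16, 48)` of the same-scale encoder map — a slimmed skip connection of 32
channels, read as a 0-based half-open interval — then fuses with two 3×3×3
convolutions back to 64 channels. A 1×1×1 convolution and a sigmoid
produce the single-channel heatmap in [0, 1]. Loss: mean squared error.

**Stage 2 — ROI cropping.** Deterministic: threshold the predicted heatmap
at 0.3× its global maximum (strict `>`, so a flat heatmap selects
nothing), keep the largest 6-face-connected component (the 3D analogue of
2D 4-neighborhood labeling; size ties break toward the component with the
lexicographically smallest box corner), take the tight per-axis bounding
box, and extend each side by `floor(0.1 × axis_length)`, clamped to the
grid. The box is computed at the localization resolution and mapped to
native voxel indices by per-axis scale factors, rounded outward so nothing
the low-resolution box covered is lost. A config switch
(`crop_source="hu"`) applies the same rule to the resized intensity volume
instead of the heatmap, which is the behavior one wants for, e.g., raw
bone thresholding; the heatmap is the default because model predictions
can contain several bright areas that the largest-component step must
arbitrate.

**Stage 3 — multi-scale XUnet.** The cropped, windowed volume is resized
to 64×64×128 and classified per voxel into 6 classes (background +
L1..L5). Encoder: three levels of two 3×3×3 convolutions (32, 64, 128
channels) each followed by 2× max-pooling, then a fourth level of one
convolution to 256 channels, a 2× max-pool, and a four-branch Inception
block. The block's two feature-extraction layers are wired in the
canonical pattern — 1×1×1 passthrough (64 kernels); 1×1×1 reduce (32) →
3×3×3 (128); 3×3×3 reduce (16) → 5×5×5 (32); 3×3×3 stride-1 max-pool →
1×1×1 (32) — the only wiring for which the concatenated output matches the
published 256 channels. Decoder: three fusion levels that gather named
encoder/decoder maps, rescale each to the level's resolution (repeated 2×
max-pool down, repeated stride-2 transposed convolution up) and fuse with
two 3×3×3 convolutions:

| level | inputs (rescaled)             | concat ch | output          |
|-------|-------------------------------|-----------|-----------------|
| 1     | X2↓, X3, X4↑↑                 | 448       | 128 @ 16×16×32  |
| 2     | X1↓, X2, X3↑, Y1′↑            | 352       | 64 @ 32×32×64   |
| 3     | X1, X2↑, Y2′↑                 | 160       | 32 @ 64×64×128  |

A 1×1×1 head and per-voxel softmax finish the segmentation. Loss: voxel
cross-entropy plus mean foreground soft-Dice. The general decoder formula
(concatenating downsampled, same-scale, and upsampled maps at every level)
admits four inputs per level; the per-level enumeration above is taken as
authoritative where the two disagree.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| window level / width | 400 / 1800 HU | bone window; clips and maps HU affinely to [0, 1], level ↦ 0.5 |
| heatmap σ | 3 voxels | Gaussian std of the localization target; peak-normalized to 1 |
| threshold fraction | 0.3 | heatmap cut as a fraction of its maximum, strict inequality |
| expansion fraction | 0.1 | per-side box padding as a fraction of each axis length |
| localization input | 96×96×128 | axes must be divisible by 2⁴ (four poolings) |
| segmentation input | 64×64×128 | axes must be divisible by 2³ |
| n_classes | 6 | background + L1..L5 |
| optimizer | Adam, lr 1e-3 | both stages; losses as above |

The window's output scale ([0, 1]) and both losses are this package's own
choices; only the level/width constants, the 0.3/0.1 crop constants, the
channel/kernel counts and the input scales are fixed by the published
architecture. Activation (ReLU), conv→batch-norm→ReLU ordering, sigmoid
heatmap head, and 2×2×2 stride-2 transposed-convolution upsampling are
likewise design choices where the source names only "activation",
"deconvolution" and "upsample". Where a convolution feeds a batch norm its
bias is omitted (normalization would cancel it; keeping it would leave
parameters that provably receive zero gradient). At encoder level 4 the
published description places "a convolution and an Inception block"
between the 8×8×16 input and the 256-channel 4×4×8 output without saying
where the halving happens; here the order is convolution → 2× max-pool →
Inception block.

## The numpy network engine

Both networks run on a small reverse-mode autodiff engine written for this
package (`lumbarseg.nn`): tensors over numpy arrays, a topologically
sorted tape, and exactly the primitives the two architectures need.
Convolutions are stride-1 "same" and evaluated as chunked im2col + BLAS
matmul; chunks are depth slabs bounded at 256 MB of column workspace, so
the largest forward pass (96×96×128 at 64 channels) stays within a few
hundred MB. Upsampling uses a 2×2×2 stride-2 transposed convolution, which
maps each voxel onto a disjoint 2×2×2 block and therefore reduces to a
single einsum. Max-pooling records argmax indices for exact gradients.
Batch normalization uses batch statistics in training (batch size 1 makes
this per-volume normalization) and running estimates in inference. Every
primitive's analytic gradient is tested against central finite differences
at tolerance 1e-4 in float64.

All computation is deterministic for fixed seeds: parameter initialization
(He normal) and example sampling derive from `numpy.random.default_rng`
seeded from the training config, and the forward/backward path contains no
stochastic operator, so loss traces and inference outputs reproduce
run-to-run on the same platform.

## Synthetic phantoms

`generate_phantom` emulates just enough CT structure to exercise the
pipeline: five ellipsoidal bodies (flattened 25% along the stack axis,
radii drawn from 6–9 voxels at the default 64×64×96 shape) with a small
posterior box protrusion, stacked with 3-voxel gaps along the longest
axis, labeled 1..5 in stacking order; one bone-range HU value (300–1200)
per vertebra, one soft-tissue value (−100..100) for the background, and
additive Gaussian noise (σ = 20 HU). It does **not** emulate cortical/
trabecular texture, intervertebral discs, ribs or pelvis, partial-volume
effects, scanner artifacts, metal, or pathological anatomy. Passing tests
on phantoms therefore demonstrate that the architecture, cropping
algorithm, metric suite and training loop are implemented correctly and
can fit data of this geometry — not that the trained weights transfer to
clinical CT.

## Problem sizes used by the tests

Training at the published widths is impractical on a desktop CPU, so the
learning checks run the same topologies at reduced width on 32³ phantoms:
the localization net with 8 channels and skip slice `[2, 6)`, the XUnet
with encoder widths (8, 16, 32, 64) and proportionally scaled Inception
branches (output 64). With these sizes, 200 MSE steps on one phantom cut
the heatmap error to well under 25% of its initial value, and 300
Dice+cross-entropy steps reach mean foreground DSC above 0.95 on the
training phantom. The full-width networks are exercised with random
weights for the exact per-level shape contracts at 96×96×128 and
64×64×128. The end-to-end pipeline test trains both stages briefly (120 /
150 steps) on two 64×64×96 phantoms — enough for a containing ROI and
deterministic inference, not for clinical-grade accuracy.

## Numerical and degenerate-case conventions

- Indices are 0-based, intervals half-open; volumes are reoriented to the
  nibabel closest-to-RAS canonical order on load, and all shape statements
  refer to that order.
- `argmax` ties in label decoding go to the smaller class index, so a
  perfectly uniform posterior yields background.
- An empty mask yields an all-zero heatmap (no division by the maximum);
  an all-zero grid thresholds to an empty mask (0 > 0 is false); an empty
  mask raises an explicit empty-ROI error rather than producing a
  degenerate box. A *network-predicted* heatmap is sigmoid-valued and
  never exactly zero, so the guaranteed empty-ROI path is intensity-based
  cropping (`crop_source="hu"`) on a volume with nothing above the window
  floor (e.g. all air): it windows to identically zero and fails the
  strict threshold everywhere. Note the threshold is *relative* (frac ×
  maximum): any uniform positive grid keeps all voxels, since each value
  exceeds 0.3× itself.
- Overlap metrics are undefined (error, not zero) when a label is absent
  from both masks; such rows are flagged invalid and excluded from means.
  A label present in only one mask has DSC 0 and FND (or FPD) 2 but
  undefined surface distances (NaN). FND and FPD range over [0, 2], not
  [0, 1]: their shared denominator halves only the TP term.
- ASD averages the pooled multiset of directed nearest-neighbor distances
  from both surfaces; averaging the two directed means instead is
  available via `asd_mode="directed_means"` (the two conventions differ
  when the surfaces have different sizes).
- Surfaces are 6-connectivity border voxels; distances are Euclidean
  between voxel centers in mm (anisotropic spacing respected). Voxels at
  the grid edge count as border.
- `resize_to_shape` uses trilinear interpolation for continuous grids and
  nearest-neighbor for labels (label set closed under resampling).

## Known limitations

- No GPU path; full-width training is out of reach (inference at full
  width takes a few minutes per volume on one core).
- The localization heatmap is whole-spine, not per-vertebra; cases where
  L1–L5 must be disambiguated from adjacent thoracic/sacral vertebrae are
  beyond the phantom's scope.
- Volumes are resized anisotropically to the fixed network inputs rather
  than resampled to a common physical spacing; surface metrics, computed
  in mm on the native grid, are unaffected, but extreme spacing ratios
  will distort network inputs.
- Batch statistics with batch size 1 make batch norm equivalent to
  instance norm during training; running averages are still tracked for
  inference.
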