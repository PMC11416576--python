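# Methods

## Problem and model

The package segments six structures of the optic nerve head in color
fundus photographs: background (0), optic disc (1), optic cup (2), blood
vessels (3), PPA beta zone (4) and PPA alpha zone (5). Two model
families are implemented on a shared encoder–decoder core.

**Custom 6-class U-Net.** Encoder: four blocks of
Conv3×3–Dropout–Conv3×3 (ReLU, size-preserving padding) with filters
8, 16, 32, 64, each block after the first preceded by 2×2 max-pooling;
centre block with two 128-filter convolutions and a 2×2 stride-2
transposed convolution back to 64 channels. Decoder: four blocks of
Concatenate(skip)–Conv–Dropout–Conv with filters 64, 32, 16, 8, joined
by 2×2 stride-2 transposed convolutions, and a final 1×1 convolution to
6 channels with softmax. Input sizes must be divisible by 16; the
default is 512×512×3. The full layer table (41 rows, 485 862
parameters) is emitted by `architectures.layer_table` and verified
row-by-row against the packaged CSV transcription. One reference row is
known to be internally inconsistent — the second 3×3 convolution of the
first encoder block is listed with 284 parameters, while the shape
formula kh·kw·C_in·F + F gives 584 (the identical layer in the last
decoder block is listed as 584) — so that row is excluded from the hard
check and reported separately.

**MSU-Net / BU-Net (multi-label disc + cup).** Disc/cup segmentation is
posed as a multi-label problem: independent binary targets per class,
because cup pixels are also disc pixels. MSU-Net adds a mean-pooled
image pyramid whose level d is concatenated channel-wise before encoder
block d+1 (default: 3 levels, encoder depth − 1), and replaces the head
with a 1×1 convolution with an independent sigmoid per class (K = 2).
BU-Net attaches M auxiliary 1×1 sigmoid heads to the decoder stages,
each nearest-neighbour up-sampled to full resolution; the training
objective adds the fused side losses Σ_m a_m L_s^(m) to the final-layer
loss. Default M = 4 with a_m = 0.25 each, so the fusion weights sum
to 1. At inference only the final head is used; the side heads exist to
carry gradient to the early decoder layers.

**Loss.** The 6-class model trains with mean per-pixel categorical
cross-entropy; the multi-label models with the class-weighted Dice loss

    L_s = 1 − Σ_k 2 w_k (Σ_i p_(k,i) g_(k,i)) / (Σ_i p²_(k,i) + Σ_i g²_(k,i) + ε)

with Σ_k w_k = 1 (default w = 0.5, 0.5) and smoothing ε = 1e-7 so a
class empty in both prediction and truth contributes a well-defined
term. For K = 1 the loss is exactly 1 − soft-Dice. Its gradient is
closed-form,

    ∂L_s/∂p_(k,i) = 2 w_k [ −g_(k,i)/D_k + 2 p_(k,i) (Σ_i p g)/D_k² ],
    D_k = Σ_i p² + Σ_i g² + ε,

and three independent routes are required to agree in the tests: this
expression, central finite differences of the loss, and the reverse-mode
gradient of the loss built from autodiff primitives.

## Polar transformation

The polar module resamples an image about the optic-disc center into
(angle, radius) coordinates: row b, column s sample the source at angle
rotation + 2πb/B and radius r_max·s/(S−1). Defaults: B = 400 angular
bins, rotation −90°, and S = 400 radial samples — the radial count is
not externally prescribed, so a square polar raster was chosen for
symmetric resolution. Coordinates are (u, v) = (column, row), 0-based,
pixel-center sampling; interpolation is `scipy.ndimage.map_coordinates`
with configurable order (nearest for masks). The inverse transform pads
the angular axis cyclically before interpolating so values wrap
correctly at the 0/2π seam, and leaves pixels beyond r_max at the
caller's fill value. The disc center is an explicit input; a fallback
detector returns the brightness centroid of pixels above mean + k·σ
(the disc is the brightest large structure). In polar space the nested
disc/cup becomes a layered structure, the cup is enlarged by
interpolation (countering the cup/background imbalance), and a rotation
of the Cartesian image is exactly a cyclic shift of polar rows — a
cheap, label-preserving augmentation.

## Preprocessing and ground truth

Contour thresholding uses mean + k·σ with the population standard
deviation (k typically 1–3; strict inequality, so a constant image
yields an empty mask). Polygon filling uses the even-odd rule on pixel
centers. Alpha compositing is the exact convex combination
source·α + destination·(1−α) with scalar or per-pixel α; RGBA→RGB
flattening is (1−α)·background + α·color with α normalised to [0, 1].
Resizing goes through scikit-image with explicit order; integer masks
must use order 0 (anything else raises, since interpolation would invent
class ids). Min-max normalisation maps each raster to [0, 1], constants
to zero. Ground-truth composition merges five binary structure masks
with the fixed precedence cup > vessels > disc > beta > alpha: the cup
is inside the disc, vessels are visible where they cross the disc, the
beta zone abuts the disc boundary and the alpha zone lies outside beta.
The train/test split shuffles with a fixed seed (default 42) and takes
round(n·0.2) test items.

## Training protocol

Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8) at learning rate 1e-4, batch
size 1, no shuffling within or between epochs, a fixed seed (default 42)
controlling initialisation, dropout streams and epoch order. Weights
use He-normal initialisation (Glorot for linear/sigmoid heads); the
classifier head is then re-initialised at the class base rates — zero
weights, log-prior biases for softmax, prior log-odds for sigmoid — so
training starts from calibrated marginal predictions rather than random
confident ones. This is standard practice for class-imbalanced dense
prediction and measurably accelerates early convergence; it can be
disabled with `head_init="random"`. Dropout rate defaults to 0.1
(light regularisation consistent with the small filter counts; the rate
is not externally prescribed). Histories record per-epoch training and
validation loss, pixel accuracy and foreground Jaccard.

Patch-based protocols: 48×48 patches at uniformly random valid offsets
(default 9500 per image, 90/10 train/validation), sampling permitted
outside the field of view; sliding-window prediction at stride 5 with
the final window clamped to the border and per-pixel probabilities
divided by the cover count, which keeps border averaging unbiased. The
FOV mask thresholds the red channel at mean + k·σ and keeps the largest
connected component. Probability maps become masks by argmax (ties to
the lowest class id) or by a per-class 0.5 threshold (multi-label). The
disc/cup pipeline runs ROI → polar → model → inverse polar → threshold →
largest-component + hole-fill cleanup → cup clipped to the disc.

## Synthetic phantoms

The generator emulates the anatomical structure the method assumes, not
photorealism: a bright elliptical disc (radius 12–16 % of the short
side, eccentricity 0.85–1.15) containing a brighter concentric-ish cup
(CDR uniform in 0.2–0.7, center jitter bounded so the cup stays inside
the disc), 2–6 dark random-walk vessel trees with one branch each
emanating from the disc, a pale beta annulus hugging the disc boundary
and a paler alpha annulus outside it (widths ≈ 3–4.5 % and 2.5–4 % of
the short side), on a dark-red background carrying low-frequency texture
(±15 %) and radial illumination falloff (35 %); mild global blur
(0.2 % of the short side) and Gaussian pixel noise (σ = 6 on the 0–255
scale) finish the render. Shading and texture modulate the background
tissue only; structures keep their palette colors. The label mask is
composed with the same precedence as the ground-truth module, so image
and mask are registered by construction. All randomness flows through
`numpy.random.default_rng(seed)`; a fixed (config, seed) pair is
byte-reproducible across platforms.

What phantom results show: that the implementation can learn the
stereotyped color-and-geometry mapping and that every pipeline stage
composes correctly end-to-end. What they do not show: performance on
real fundus photographs, whose appearance varies in ways the phantom
does not model (pathology, camera optics, inter-subject anatomy,
annotation ambiguity).

## Numerical choices and problem sizes

* Empty∪empty IoU and 0/0 Dice are defined as 1.0, keeping macro mIoU
  meaningful when a class is absent; the reported `iou` is
  micro-averaged (frequency-weighted) and `mean_iou` is the unweighted
  macro mean, so `iou ≥ mean_iou` on imbalanced scenes.
* Argmax ties resolve to the lowest class id; sliding windows clamp at
  borders; the multi-label threshold defaults to 0.5.
* Training and inference run in float32; gradient checks run in float64.
* Tests and the acceptance script use desk-scale problem sizes chosen to
  exercise every code path on one CPU: 32–64 px phantoms, 30-epoch
  training runs, 400-bin polar grids. At the 30-epoch desk budget the
  smallest structures (vessels ~1 % of the short side wide, thin PPA
  annuli) remain under-segmented — they are learned last — so macro
  mIoU on held-out phantoms sits well below what longer training
  achieves, while pixel accuracy and the large-structure IoUs are
  already high.

## Known limitations

* The autodiff engine implements exactly the operations these networks
  need (stride-1 same-padding convolution, 2×2 stride-2 transposed
  convolution, 2×2 pooling, nearest up-sampling, concatenation,
  dropout, fused softmax cross-entropy); it is not a general framework
  and has no GPU path.
* The backbone registry ships one compact residual encoder; named
  ImageNet architectures and pretrained weights are out of scope.
* The phantom does not simulate specific pathologies or camera optics;
  PPA annuli are full rings rather than temporal crescents.
* Disc-center detection is a brightness centroid fallback, not a
  learned detector; the polar pipeline expects a reasonable center.
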