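# Methods

`craniomsp` estimates the midsagittal plane (MSP) of a skull volume in four
stages: skull segmentation (3D U-Net), rotation-offset classification (one
small 3D CNN per anatomical plane), centroid extraction (3D geometric
moments), and plane construction. A synthetic skull-phantom generator with
analytically known symmetry supplies ground truth for every stage.

## Coordinate and rotation conventions

Array axes are (x, y, z) = (subject left→right, posterior→anterior,
inferior→superior); voxel indices are 0-based and world position =
`origin + index * spacing` (mm, voxel-center convention). The coronal
angle is a rotation about y, the transverse angle about z, composed as
`R = R_z(transverse) @ R_y(coronal)`. For the ±5° range of the classifier
grid the commutator of the two factors is far below voxel scale, so the
order is pinned purely for reproducibility.

## Phantom generator

A phantom is an ellipsoidal cranial shell (outer semi-axes ~24–28 mm at the
64-voxel reference scale, thickness ~4 mm) with two spherical orbital
holes, an anterior nasal slot, and suture-like surface corrugations —
three orthogonal harmonic checkers modulating the outer radius
(`ridge_amp`, default 0.10 of the radius; fixed frequencies). Every term
depends on x only through |x|, so a noise-free, undeformed phantom is
*exactly* mirror-symmetric about the central sagittal voxel plane
x = (nx−1)/2. Optional features: a one-sided bulge (`Deformation`) that
emulates craniofacial asymmetry, and salt-and-pepper voxel noise.

The corrugations are not decorative. A smooth ellipsoid carries almost no
boundary structure at desk resolution: adjacent 0.5° rotation classes
would differ in 0–8 voxels and become indistinguishable after the
classifier's first 5³ max-pooling. Real skull surfaces carry dense
centimetre-scale structure; the corrugations restore that property at
phantom scale. Their amplitude and frequencies were fixed by measuring the
generator's intrinsic adjacent-class distinguishability (a classifier-free
statistic), not by tuning against any model.

### Rotation: analytic rendering vs. grid resampling

Two rotation paths exist and are deliberately different:

- `rotate_volume` resamples an existing voxel grid (nearest neighbor,
  fill 0, shape preserved). This matches how one rotates a volume one only
  has voxels for — but at 32³ a nearest-neighbor rotation by less than
  about 1.5° is the *identity map*: adjacent 0.5° classes produce
  bit-identical volumes. (The original workflow avoided this by rotating
  512³ CT data before reducing to 128².)
- `render_rotated` evaluates the phantom's implicit geometry on
  inverse-rotated coordinates — the digital analogue of physically
  rotating the object in the scanner. It preserves sub-voxel rotation
  information at any grid size, and is therefore the path
  `build_rotation_dataset` uses for `PhantomSpec` bases.

`render_rotated` also offers two partial-volume modes: `supersample=k`
stores the occupied fraction of each voxel (box-filter partial volume,
evaluated at k³ sub-voxel points), and `soft_edge_mm=w` evaluates a smooth
sigmoid edge profile of width w — the point-spread blur of an acquisition.
The rotation dataset defaults to the soft edge (0.6 mm): boundary
intensities then shift *continuously* with rotation, which is what lets
the 0.5° signal survive the classifier's aggressive first pooling at desk
resolution — a binary mask at 32³ does not carry enough boundary
information for sub-degree discrimination, whereas clinical data rotated
at native 512³ resolution before reduction does. Thresholding either
partial-volume render at 0.5 recovers the binary geometry.

## Rotation dataset

`build_rotation_dataset(bases, grid)` enumerates every (base, coronal,
transverse) combination lazily in deterministic order; a default
−5…5° × 0.5° grid gives 21 labels per plane and 441 samples per base
(44 541 for 101 bases). `default_phantom_specs(n)` jitters the geometry by
up to ~8 % per parameter to emulate inter-subject variation while keeping
each phantom exactly symmetric.

## Rotation classifiers

Preprocessing resizes the volume in-plane to `input_side` (nearest
neighbor; z likewise by default) and keeps the anterior-left quarter with
full z extent — for a bilaterally symmetric skull the other quarters are
redundant, and the crop quarters the voxel count. The network is the fixed
stack: pointwise conv (3 filters) → BN/ReLU → five conv/BN/ReLU blocks of
8, 16, 32, 64, 128 filters (cubic kernels 5, 7, 5, 5, 1) interleaved with
stride-2 poolings (max 5, 5, 3, 2; average 2), then fully connected layers
of 25, 50 and `n_labels` units with softmax. Two independently trained
instances handle the coronal and transverse labels.

Numerical choices:

- **'Same' (ceil-mode) pooling.** With valid (unpadded) pooling the desk
  input (side 32, quarter 16×16×32) collapses to 1×1 in-plane after two
  poolings and the network cannot fit even its training set. Ceil-mode
  windows (output ceil(n/2), borders padded with −inf for max / excluded
  from the mean for average) keep the spatial ladder 16→8→4→2→1,
  matching the stack's behaviour at the reference input side 128.
- **Desk-scale batch size.** The reference mini-batch of 128 on a 40 k
  dataset yields thousands of optimizer steps; on the desk-scale 3 528
  samples it would give ~25 steps per epoch and the optimizer starves.
  Training uses the same Adam optimizer with `batch_size` chosen so the
  total step count is comparable (desk default 24, about 2 600 steps over
  a 20-epoch run); 128 remains available in the config.
- **BatchNorm recalibration.** Small batches leave exponentially-averaged
  BN running statistics noisy enough to break eval-mode inference (loss
  falls while eval accuracy stays at chance). After each epoch the running
  statistics are replaced by population statistics over a fixed
  calibration subset (cumulative-average schedule): 1 024 samples between
  epochs, 2 048 for the final model. Subsets of a few hundred samples
  leave the estimates noisy enough to cost several accuracy points.
- **Learning-rate schedule.** Adam at 3e-3 with cosine decay to zero over
  the run; the decaying tail is what closes the last few accuracy points
  on the ±0.5° discrimination. A constant schedule remains available.
- Stratified 90/10 train/holdout split with a fixed seed; argmax decoding
  with ties broken toward the smaller |angle|, then the smaller index.
- Study runs train each plane's classifier for 20 epochs (the transverse
  angle typically converges a few epochs sooner, consistent with the
  original report).

## Segmentation U-Net

Encoder-decoder with `encoder_depth` levels (default 4); each encoder
level is conv(5³)/BN/ReLU then 2× max pooling, with filter counts doubling
from 6; the decoder mirrors with nearest-neighbor upsampling, skip
concatenation, and a conv block; a final 1³ conv yields voxelwise 2-class
logits trained with softmax cross-entropy and Adam (initial learning rate
1e−2). Input dimensions must be multiples of 2^depth (inference pads and
crops automatically). Patches are sampled randomly per volume per epoch
(`patches_per_image`, default 4). The desk default `batch_size` of 2
patches per step replaces the reference 128, which targets large-memory
GPU training.

## Moments and centroid

M_pqr = Σ x^p y^q z^r f(x,y,z) over voxel indices (integer-exact for
masks); the centroid is (M100, M010, M001)/M000, with a separate
conversion to world mm. An all-zero volume raises rather than returning
NaN. On any volume equal to its own x-reflection the centroid x̄ is exactly
the reflection-plane coordinate; a one-sided deformation drags the
centroid toward the deformed side monotonically in the deformation
amplitude — the documented failure mode of moment-based centering on
asymmetric anatomy.

## Midplane construction and symmetry score

The plane through the centroid with normal
`R_z(transverse) @ R_y(coronal) @ (1,0,0)` is reported both in aligned
space (centroid computed after undoing the detected rotation; normal
(1,0,0)) and in the original volume's coordinates. The symmetry score of
(volume, plane) is the Dice overlap between the mask and its reflection
across the plane (nearest-neighbor resampled). Scores carry resampling
loss for thin corrugated shells at 32³ (a perfectly recovered plane scores
~0.75–0.8 on a rotated phantom, 1.0 on an unrotated one, because the
reflection of a tilted plane resamples off-grid); end-to-end checks
therefore compare the recovered plane's score against the ground-truth
plane's score on the same volume, where resampling loss cancels.

## Metrics

DSC = 2TP/(2TP+FP+FN) (two empty masks score 1 by convention); SVD = 1 −
DSC; Hausdorff distance is the symmetric max-min Euclidean distance
between boundary-voxel sets, in mm (spacing applied) or voxels.
Sensitivity/specificity/PPV/NPV come from confusion counts; multiclass
inputs are reduced one-vs-rest and macro-averaged, skipping undefined
rates. The nine full-reference image-quality indices follow their direct
formulas (reference first): AD, MD, MSE, NAE, NK, SC; LMSE uses the
6-neighbor Laplacian on interior voxels; IQI is the universal quality
index over a single global window; SSIM uses uniform 7-voxel windows with
constants (0.01 L)² and (0.03 L)², L the joint data range. Identical
volumes produce the exact ideal values (0, 1, 0, 0, 0, 0, 1, 1, 1).
Ratios with zero denominators are reported as explicit `None` markers.

## Training core

No deep-learning framework is assumed: `_nn` implements the needed layers
in numpy/numba — convolution as one BLAS GEMM per layer over a
channels-first patch matrix, analytic backward passes (verified against
central differences), Adam, and the BN recalibration pass described above.
All randomness flows through seeded `numpy.random.Generator`s; identical
seeds give identical training histories.

## Desk-scale problem sizes

Phantoms default to 32³ voxels (1 mm isotropic); the classifier study uses
8 jittered symmetric phantoms × 441 rotations = 3 528 samples per plane at
input side 32 (quarter 16×16×32), trained for 20 epochs per plane; the
segmenter capacity study uses 6 noisy phantoms
(flip rate 0.02) at 32³ and converges well within its 15-epoch budget
(the acceptance check trains 8). These sizes were chosen so the full
pipeline trains and evaluates on a single CPU core in minutes while
preserving every structural property under test; the reference
parameterization (input side 128, batch 128) remains available through
the configs.

## What passing tests do and do not show

The phantom generator supplies exactly symmetric, noise-controlled,
geometry-known inputs. Passing tests therefore demonstrate the pipeline's
correctness properties — codec exactness, moment/centroid identities,
metric identities, angle recovery on clean symmetric data, end-to-end
plane recovery relative to ground truth — under the generator's
conditions. They do not demonstrate segmentation accuracy on real CT
graylevels (phantoms are binary or partial-volume fractions, without
Hounsfield calibration, beam hardening, or dental-filling artifacts), nor
angle recovery under real anatomical asymmetry, where the centroid shifts
toward the deformed side by construction.

## Known limitations

- Rotation in index space is rigid in world space only for isotropic
  spacing (the phantom default).
- The moment centroid is not robust to asymmetry; deformed-phantom
  behaviour is characterized, not corrected.
- The hand-written training core is single-threaded; reference-scale
  (input 128) training is available but slow.
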