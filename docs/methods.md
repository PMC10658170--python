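# Methods

## The model

`sparsevox` implements a sparse convolutional encoder–decoder for binary
voxel occupancy grids, aimed at two cranial-shape tasks: **shape completion**
(predict the full skull from a defective one; the difference is the implant)
and **binary shape super-resolution** (refine an up-scaled coarse shape into
its high-resolution counterpart).

A volume is represented as a sparse tensor: the N×3 matrix 𝒞 of occupied
voxel coordinates plus an N×N_F feature matrix ℱ (task inputs are binary, so
N_F = 1 and all features are 1). All layers are phrased as coordinate-set
transformations plus gathered/scattered feature arithmetic:

- **Sparse convolution.** For each output coordinate D′ and kernel offset k,
  the input coordinate D = D′ + k·t (t the input tensor stride) contributes
  W[k]·ℱ(D) if occupied. The pairing is the *kernel map*, built by
  coordinate lookups in a hash table keyed by FNV-1a 64-bit hashes of the
  serialized coordinates, with exact-comparator chaining so correctness is
  independent of hash quality. For small bounded coordinate boxes the
  manager also keeps a dense O(1) index table; both routes return identical
  results (asserted by a dual-route test).
- **Tensor stride.** Coordinates always live on the original input lattice;
  a stride-2 convolution floors coordinates to the coarser lattice and
  doubles the tensor stride, so encoder/decoder coordinates reconcile
  exactly with ground truth at every level.
- **Generative transposed convolution.** The output coordinate set is the
  kernel-span expansion {c + t′·k} of the input coordinates on the output
  lattice — the decoder can create points absent from its input, which is
  what makes completion possible. Expansions are clipped to the volume
  bounds: a coordinate outside the grid can never be part of a valid
  occupancy, and without clipping an untrained decoder over-generates
  geometrically (the "false out-of-memory" failure mode of generative
  sparse decoders).
- **Pruning.** Each decoder stage carries a 1×1 scoring convolution whose
  single-channel output is the prune score; points with score < τ (default
  τ = 0) are dropped. During training, points present in the ground truth
  at that stage's stride are kept regardless (teacher forcing), so the
  supervision never loses its positive targets; at inference only the τ
  rule applies. Scores are supervised with per-point binary cross-entropy
  against the ground truth block-max-downsampled to the stage's stride.

### Architecture

A 7-element channel list ch[0..6] parameterizes the network: a kernel-3 stem
(1→ch[0]), six encoder blocks of [kernel-2 stride-2 convolution,
kernel-3 convolution] walking ch[0]→…→ch[6], six decoder blocks of
[generative transposed convolution upsampling ×2 (kernel 4 first, kernel 2
after), kernel-3 convolution, scoring convolution + pruning] walking back
ch[6]→…→ch[0], and a final 1×1 projection to a single logit channel read
through a sigmoid. Every convolution except the final projection carries
per-channel affine normalization (batch statistics over the point rows).
This normalization convention is not optional decoration: the analytic
parameter count N_param = Σ Ks³·C_in·C_out + C_out (+2·C_out per normalized
layer) reproduces the reference totals — 0.435 M for
ch1 = [8, 8, 16, 16, 32, 32, 64] and 18.14 M for
ch2 = [22, 32, 32, 128, 156, 256, 388] — only when normalization parameters
are included; the pure-convolution sum gives 0.434 M / 18.13 M. The six
scoring convolutions add 118 / 632 parameters respectively, below the
printed rounding. `count_parameters` is asserted against exact enumeration
of every built tensor.

### Losses and optimization

The sparse network minimizes binary cross-entropy: one term over the final
predicted coordinates (target = membership in the ground-truth occupancy)
plus one pruning-supervision term per decoder stage, all weighted 1.0 by
default. Ground-truth points the sparse output never reached carry their
signal through exactly the stage terms — a sparse output has no value "at" a
missing coordinate, and the stage where the point was pruned is where the
positive-label penalty lives. The dense baseline uses the two-class
squared-denominator Dice loss (−2 at a perfect match). The optimizer is
Adam (β = 0.9/0.999, lr 10⁻³ default; the choice is this package's — no
optimizer is prescribed by the task). All gradients are hand-derived per
layer and verified against central finite differences (tolerance 10⁻⁴
relative per layer, 10⁻³ on the full completion loss).

### Initialization

Fan-in-scaled uniform convolution weights, zero biases, normalization scale
1. Three deliberate exceptions, all serving "the untrained net must not
collapse": scoring-convolution bias +0.5 and final-projection bias +0.1 (an
untrained net keeps/predicts rather than pruning everything), and
normalization shift +0.1 (freshly standardized features are often exactly
zero — constant columns, one-row bottleneck batches — and a zero shift
parks every ReLU on its kink, killing the gradient). Normalization of a
single-row batch applies only its affine part: standardizing one row would
erase the bottleneck content entirely.

## Desk-scale study conditions

Everything is exercised on synthetic data at desk scale (CPU, minutes); the
published experiments at 512²×Z on real MRI/CT skulls with GPU training are
out of scope, and their reported values (completion DSC ≈ 0.99, the memory
and wall-clock tables) are **not** reproduced here — the analytic cost
models and the desk-scale behavioural properties stand in for them.

### Synthetic data

Real skull data are thin closed shells at ≤ ~10% occupancy with a cranial
vault. The generator emulates exactly that: rotated two-surface ellipsoid
shells (semi-axes ~0.32–0.44 of the grid, thickness ~2 voxels at a 64³
reference, scaled with resolution) with sinusoidal radial surface detail
(amplitude 0.03–0.08, frequency 4–8) that coarse grids cannot carry —
giving the super-resolution task its premise. Defects are spheres or boxes
(default radius fraction 0.25 of the mean outer radius) centered on a shell
voxel in the upper third of the occupied z-range, mimicking craniotomy;
defective ∪ implant = complete and defective ∩ implant = ∅ hold exactly.
Default occupancy at 64³ is ~3–9%, one 26-connected component.

Completion datasets downsample by block-max (occupancy-preserving: a thin
shell never disappears). The super-resolution coarse path instead uses
fractional-coverage downsampling (block mean ≥ 0.3) and shells 2.5× thicker,
and up-scaling is sample-aligned trilinear interpolation thresholded
strictly above 0.5: with tie-inclusion or block-max coarsening, voxel-thin
shells roughly double in apparent thickness and the up-scaled input would
systematically carry ~50% more voxels than the target, where the real
multi-resolution data show statistically equal counts. Under the chosen
rules the up-scaled input and target agree to within ±10% in count and
share ≥ half their coordinates.

What the generator does **not** emulate: anatomical bone morphology, CT
noise and acquisition artifacts, irregular real craniotomy defects,
inter-subject anatomy variation beyond affine + low-order surface detail.
Passing the desk-scale benchmark therefore demonstrates that the engine and
pipelines learn and generalize on sparse shell geometry — not clinical
performance.

### The desk-scale recipe

The benchmark trains ch1 = [8, 8, 16, 16, 32, 32, 64] on 60 shells (20
held-out) at 32³ for completion and 16³→32³ for super-resolution. At this
scale the published architecture has a degenerate bottleneck: six stride-2
levels collapse a 32³ grid to a *single* coordinate, whereas at 512²×Z the
bottleneck retains an 8×8×(Z/64) spatial map. Without a spatial bottleneck
no sample-specific geometry reaches the decoder, and measured behaviour
confirms it (completion plateaus at the input's own DSC; super-resolution
degrades below the interpolation baseline as training progresses). The
desk-scale recipe therefore enables the parameter-neutral additive
encoder–decoder skips (a config flag; default remains off to match the
published table) — they restore the spatially resolved information path
that scale itself provides in the published setting. Completion
predictions are united with the input coordinates (the task's output is
defined to contain the input); super-resolution predictions are not, since
that task must prune input voxels. Training runs 60 epochs (completion;
learning rate dropped ×0.1 after 40) and 24 epochs (super-resolution),
batch size 1, with Adam warm restarts every 4 epochs (moments and shuffling
stream reset — the restarts measurably escape the late-training basin where
continuous runs stall just below the input baseline). Completion training
additionally applies random orientation augmentation (one of the 48
axis-permutation/flip grid symmetries per sample per step): without it the
network largely memorizes the training defects — near-perfect implant
recovery on the training split, chance-level on held-out shells — whereas
augmentation forces the orientation-independent rule ("continue the
interrupted surface") and roughly triples held-out implant recovery while
cutting false positives. Annealing teacher forcing and snapshot ensembling
over the restart cycles are implemented and available in the training
configuration but are not part of the default recipe (measured: no benefit
on held-out shells at this scale). Budgets are chosen to fit a few
CPU-minutes per task; histories and checkpoints record the seed.

## Numerical choices

- Feature arithmetic in float64; training is bit-reproducible for a fixed
  seed on one platform.
- Even kernel sizes use the positive-biased offset cube
  {−Ks/2+1, …, Ks/2}³ (the symmetric formula is only integral for odd Ks);
  one function (`kernel_offsets`) owns the convention.
- BCE is computed via softplus (safe at extreme logits); an empty
  coordinate union yields loss 0 with a warning.
- The activation-size model reports the published linear estimate
  (N + 2p − Ks)/s *and* the conventional ⌊(N + 2p − Ks)/s⌋ + 1 per layer —
  they differ by one, and the discrepancy is surfaced rather than silently
  fixed. FLOPs per layer are N_f · Ks³ · C_in · C_out (the kernel touches
  Ks³ positions).
- Metric conventions: DSC of two empty masks is 1; HD95 of two empty masks
  is 0, of one empty mask the grid diagonal (flagged); RE is a percentage
  of all grid voxels, and back-computing a count from a printed percentage
  truncates. Border DSC uses a Chebyshev-radius-2 dilation band around the
  ground-truth implant boundary — the challenge's exact band definition is
  external to this package, so the band radius is always reported next to
  the value.
- Grids are read binarized (any nonzero → 1, logged); NRRD is canonical,
  NIfTI-1 accepted with spacing from the affine diagonal (orientation
  handling beyond spacing is out of scope).

## Known limitations

- Batch size is 1 end to end (as in the published measurements); the batch
  dimension of the coordinate format is supported in the data model but not
  exercised by the pipelines.
- The dense baseline is forward-only plumbing for cost/af comparison and the
  Dice loss; it is not a trained competitive dense segmenter.
- GPU execution, mixed precision, dilation, grouped or non-cubic kernels
  are out of scope.
- The bDSC band and HD95 boundary extraction operate on voxel surfaces, not
  meshes; values at very coarse resolutions are correspondingly coarse.
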