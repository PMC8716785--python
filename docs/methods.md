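# Methods

## The problem

Cerebral microbleeds (CMB) appear on susceptibility-weighted MRI (SWI) as
small, roughly spherical hypointense spots. Detector training is
data-starved: markers are expensive, prevalence is low, and vessel
cross-sections mimic lesions. `cmbforge` synthesizes CMB as
**multiplicative partial-volume masks**: an 11×11×11 patch `G` with values
in [0, 1] and a unit border, such that `background * G` implants a lesion
anywhere in a healthy scan without blending artifacts. Two generators share
this output currency, the common volume bookkeeping being

    V(G) = Σ (1 − G_ijk) · dx·dy·dz   [mm³]

with the default voxel size 0.93 × 0.93 × 1.75 mm (1.513575 mm³).

## Analytical lesion model

A lesion is a randomly rotated anisotropic 3D Gaussian attenuation profile
`a(x) = A exp(−½ xᵀ R diag(σ⁻²) Rᵀ x)`, rasterized on a supersampled grid
(factor 4 per axis by default) and block-averaged to acquisition
resolution, which reproduces partial-volume intensity gradients at the
lesion boundary. Per-axis spreads are drawn uniformly in ratio [1, 2]
(normalized to unit geometric mean) and the rotation is Haar-uniform. The
spatial scale is calibrated by Brent root-finding so the realized V(G) of
the final mask (unit border enforced) matches the requested volume to
0.1 %; targets below the smallest extent-reachable volume are met exactly
by scaling the amplitude `A`, which makes the target→0 limit the identity
mask. The core may reach 0 (fully attenuating); `min_intensity` and an
optional darkness jitter are exposed but default off.

## Lesion-volume model

A 7×7×7 patch around a marked lesion is modelled as a two-component
intensity mixture: tissue ~ N(μ, σ), outliers ~ U(0, 255), with mixing
weight `w` estimated by EM (the uniform density makes the model a proper
density only with an explicit weight, so `w` is introduced and estimated;
initialization μ, σ from median/MAD, w = 0.9; σ floored at 0.5 intensity
units to prevent collapse). The EM log-likelihood trace is recorded and
asserted nondecreasing.

Lesion volume uses a two-compartment partial-volume model: voxels
MAP-classified as outliers and darker than μ form the core; the core is
grown into its 26-connected hypointense halo (voxels below μ − 1.5 σ),
because partial-volume halo voxels are individually too mild for the MAP
rule yet carry a large share of the attenuated volume. Each lesion voxel
contributes `clamp((μ − I)/(μ − I_core), 0, 1)` of a voxel volume, with
`I_core` the darkest core intensity. The halo threshold 1.5 σ was fixed by
closed-loop calibration against implanted analytical lesions of known
volume (median relative error ≈ 15 %, versus ≈ 36 % for the MAP-core-only
sum); it trades halo capture against flooding through noise.

Cohort volumes are smoothed into a sampling distribution on [0, 80] mm³
(80 bins of 1 mm³): Gaussian KDE (Silverman bandwidth unless overridden)
evaluated on the bin grid, floored at 0.5 % per bin, renormalized. The
floor guarantees generators are trained over the whole volume range even
when the cohort clusters tightly. Sampling is inverse-CDF with uniform
jitter within a bin.

## Conditional lesion GAN

The generator maps `z ∈ R¹⁰⁰ ~ N(0, I)` plus conditions — the target
volume normalized by 80 mm³ and the normalized background patch — to an
11³ mask. Wiring (channel counts Ch1=6, Ch2=1, Ch3=8):

1. `Linear(z ⊕ v → 8·2³)`, ReLU, reshaped to an 8-channel 2³ grid;
2. transposed-conv ladder 2→5→11: a learned `ConvT3d(8→6, k3, s2)` with
   batch norm and ReLU, then a **fixed** triangle-kernel (trilinear)
   transposed convolution to 11³ — a bilinear-init deconvolution that is
   never updated. Making the last upsampling stage fixed keeps the
   per-step cost of training on a single CPU roughly 4× lower while the
   learned stages below and above it carry the shape information;
3. at full resolution the 6 feature maps are concatenated with the
   background patch and a broadcast volume channel (6+1+1 = 8 channels)
   and fused per-voxel: `Conv(8→8, k1)`, BN, ReLU, `Conv(8→1, k1)`,
   sigmoid. The sigmoid hard-guarantees the [0, 1] range for any weights.
   The final bias is initialized to +4 so a fresh generator starts near
   the identity mask (≈0.98 everywhere) — the natural origin for a
   multiplicative mask — rather than at 0.5, which would start training
   from a grossly over-attenuating mask.

Conditioning modes: `none` (plain GAN, model M2), `volume` (CGAN, M3),
`volume+background` (the full lesion GAN, M4).

The discriminator scores 11³ patches (real lesion patches versus
`background × G`): two stride-2 convolutions (6 then 8 channels,
LeakyReLU 0.2), a 32-unit hidden linear layer and a sigmoid output. By
default it sees patches only; a flag can append the volume condition.

Losses. The discriminator maximizes `log D(real) + log(1 − D(fake))`. The
generator minimizes the sum of three terms (unweighted by default, weights
exposed):

* adversarial `log(1 − D(G(z, c)))` — the literal minimax term; a
  non-saturating `−log D(G(z, c))` variant is available behind a flag;
* volume loss `(1/N) Σ |V_fake − V_in| / V_in`, computed in normalized
  units (÷ 80 mm³; the ratio is scale-invariant). Target volumes fed to
  the generator are clamped at one voxel volume (1.5 mm³): sub-voxel
  lesion requests are unresolvable at acquisition resolution, and because
  the loss divides by the target, near-zero draws from the floored
  distribution would otherwise contribute unbounded, heavy-tailed
  gradients that turn the volume calibration into a seed-dependent random
  walk;
* border loss: mean `|1 − G|` over the outermost one-voxel shell
  (602 voxels for 11³), which makes implanted lesions blend seamlessly.

Training uses Adam (lr 2·10⁻⁴, β₁ 0.5, β₂ 0.999) for both networks, batch
64. Logs record all four loss components per epoch. One master seed fans
out to named substreams (weight init, z, volume targets, shuffling), so
runs are bit-reproducible. Log arguments are clamped at 10⁻⁷. Non-finite
losses abort with the offending component named.

## NumPy layer library

All networks run on `cmbforge.nn`, a minimal CPU layer library:
Conv3d/ConvTranspose3d (im2col + BLAS GEMM; the unfold/scatter loops are
numba-compiled with a pure-NumPy fallback asserted equal in tests),
BatchNorm3d, MaxPool3d (floor mode), Linear, Dropout (inverted), ReLU /
LeakyReLU / Sigmoid, and Adam. Activations are channels-last
`(N, D, H, W, C)`, which makes the channel axis contiguous for the GEMM
contraction. Transposed convolution is computed as zero-dilation followed
by a stride-1 convolution with the spatially flipped kernel (exact
adjoint, verified in tests). Every backward pass is checked against
central finite differences in float64; training runs in float32.

## Screening (3D fast radial symmetry transform)

For each radius n ∈ {1, 2, 3, 4} (voxel units), every voxel with a nonzero
central-difference gradient votes for the location a dark blob's center
would occupy — `p − round(n·ĝ)`, against the gradient, since intensity
increases away from a hypointense center. Only dark-polarity votes are
counted by default (CMB are dark; this halves the votes that bright
structures would cast). Orientation counts O_n and magnitude sums M_n
combine as `F_n = (M_n/k_n) · (|O_n|/k_n)^α` with α = 2 and k_n the
per-radius maximum of O_n (self-normalizing; classic fixed constants are
2D-calibrated), then each F_n is smoothed with a Gaussian of σ = 0.8
voxels and the radii are averaged. Candidates are 26-connectivity local
maxima above mean + `threshold_sd`·sd of the in-mask map, sorted by score.
The vectorized voting is asserted equal (1e−8) to a literal per-voxel
re-implementation on small grids.

## Classifier

Three conv blocks (kernel 3, same padding, 16/32/64 feature maps, each
conv→BN→ReLU→max-pool 2, spatial path 11→5→2→1), then fully connected
layers of 10, 70 and 30 units (printed order; a flag offers the sorted
order) with 50 % dropout, sigmoid output. Binary cross-entropy, Adam;
the BCE+sigmoid gradient is fused for numerical stability. Predictions
average an ensemble of networks trained from distinct derived seeds.
Cross-validation folds partition subjects, never patches.

## Evaluation

Patch-level: trapezoidal/rank AUC (asserted equal to the Mann–Whitney
pair statistic). Whole-scan: candidates are matched to truth lesions by
greedy nearest-first one-to-one matching within a 3 mm hit radius (the
matching rule is this package's choice; 3 mm ≈ the lesion scale given the
1–4 voxel screening radii). FROC curves sweep thresholds from high to
low, reporting false positives per scan and lesion sensitivity; operating
points report sensitivity, specificity and FP/scan at the highest
threshold reaching a target sensitivity (default 95 %).

## Phantom data and study conditions

Phantoms are ellipsoidal "brains" with smooth Gaussian texture
(mean 120, sd 8 on a [0, 255] scale), additive noise (sd 4), and dark
(intensity 40) curvilinear tubes of radius 0.9–1.6 mm mimicking vessels —
the dominant false-positive source. Vessels are kept inside the brain and
pairwise disjoint so component-level assertions are exact. The phantom
contains no MR physics or anatomy; passing phantom studies demonstrates
pipeline correctness and the relative value of augmentation strategies,
not clinical performance.

The standing desk-scale studies (in `cmbforge.experiments`) fix:

* cohort lesion volumes ~ Gamma(shape 2, scale 6) mm³ capped at 80
  (mode 6 mm³, between the principal modes reported for clinical SWI
  cohorts), smoothed with the 0.5 % floor;
* GAN training: 2,000 lesion patches (analytical lesions implanted into
  phantom backgrounds from 8 scans of 64×64×40 voxels), 400 epochs,
  batch 64 — about 12,500 generator/discriminator steps;
* fidelity regression: 1,000 generated masks, volumes from the smoothed
  distribution;
* detection study: 600+600 M4 training patches, classifier ensemble of 2,
  60 epochs at lr 3·10⁻⁴ (a desk-scale compression of the full-scale
  200-epoch/10⁻⁵ recipe: far fewer samples and steps need a larger step
  size to converge), 3 held-out lesioned scans with 6 implants each,
  against a no-augmentation baseline trained on 50 real positives;
* optional training schedules (cosine learning-rate decay, late
  adversarial-weight annealing) are available in the GAN config but
  default off — the standing studies need neither once generator targets
  are clamped at one voxel;
* GAN training in the studies uses the non-saturating generator objective
  (−log D instead of log(1 − D)). At desk scale the discriminator wins
  early and the literal minimax term then passes its gradient through the
  discriminator's saturated sigmoid — the generator receives essentially
  no adversarial signal and converges to diffuse, barely-attenuating
  masks that satisfy the volume loss but do not look like lesions. The
  non-saturating form (standard since the original GAN formulation)
  restores the pressure and yields dark, volume-dependent cores.
* classifier-study negatives: half uniform in-brain, half at
  radial-symmetry candidate locations of lesion-free scans. Phantom
  vessels occupy a much smaller volume fraction than vessels in real SWI,
  so uniform sampling alone would give the classifier almost no mimic
  negatives — unlike real-cohort negative patches, which contain vessels
  simply because brains do.

## Numerical choices and degenerate inputs

* Patches have odd side length; even sizes are rejected (exact centering).
* Coordinates are 0-based voxel indices in array order; physical position
  = index × spacing. Marker CSVs: columns `scan_id,x,y,z`.
* Analytical calibration: Brent on the Gaussian scale, relative tolerance
  1e−4, closed-form seed `(V/(A(2π)^{3/2}))^{1/3}`.
* EM: tolerance 1e−6 on the log-likelihood, max 200 iterations.
* Constant patches, empty candidate sets, single-class training sets,
  unreachable sensitivity targets and overlapping implants raise explicit
  errors naming the violated constraint.
* RST gradient threshold 1e−6 (below it a voxel casts no vote).

## Known limitations

* The phantom's vessel mimics are geometric tubes, not flow/susceptibility
  artifacts; absolute AUC/FROC numbers on phantoms overstate clinical
  performance by construction.
* The GAN at desk scale learns volume conditioning, dark volume-dependent
  cores and border blending, but its shape diversity is limited by the
  small training set; the full-scale recipe (2,500 epochs, clinical patch
  counts) gives the adversarial term far more opportunity to enrich
  appearance.
* The EM mixture assumes one lesion per 7³ patch.
* Bias-field correction and cross-scanner histogram matching are expected
  to happen upstream; only a light quantile-matching utility is included.
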