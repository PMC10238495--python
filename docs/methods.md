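# Methods

`ridgemetrics` quantifies actin microridges — the laterally elongated,
actin-filled protrusions that tile the apical surface of squamous epithelial
(periderm) cells in labyrinthine patterns.  The toolkit covers the whole chain
from 4D fluorescence stacks to biophysical numbers: slice filtering,
cell/ridge segmentation (classical and CNN), skeleton geometry and
persistence length, Fourier pattern wavelength, optic-flow strain rates, and
actin-cluster dynamics.  This note records the models, the parameters that
matter, and the numerical choices made where the design was genuinely open.

## Slice filtering and projection

Periderm slices of a confocal z-stack show sparse bright ridges on dark
background; basal-epidermis slices below are densely textured.  Slices are
classified by global Shannon entropy — base-2, over a 256-bin histogram of
the image after min–max scaling to [0, 255]; a constant image maps to a
single bin and 0 bits.  Slices with entropy at or below a per-movie threshold
(held constant across time points) are kept; within kept slices, pixels whose
3×3 local entropy (replicate-padded borders) exceeds a second threshold are
zeroed before the per-timepoint mean projection.  Zeroing, rather than
excluding pixels from the mean, was an open choice; zeroing keeps the
projection a linear operation on a fixed set of slices.  Thresholds are
config inputs, not auto-tuned: in practice they are set by inspecting the
entropy profile of each movie.

## Membrane segmentation and cell extraction

The projected frame is denoised with a Gaussian (σ = 0.7 px), high-pass
filtered with a Butterworth transfer function H = 1/(1 + (D0/D)^{2n}) on the
centered spectrum (defaults n = 1, D0 = 3; H(D0) = ½, DC removed, H(0) := 0,
centered symmetrically on both axes), Otsu-binarized, and morphologically
closed with a disk (default radius 2 px; a config parameter because the
required radius tracks image contrast).  Note a closing cannot bridge a gap
in a 1-px line — the background wraps around it — so membranes must be about
as thick as the structuring element, which they are after imaging blur.
Complementing the closed mask yields candidate cells; regions touching the
image border are dropped explicitly, as are regions failing area/solidity
cutoffs.  Each surviving cell is extracted as the bounding-box crop of the
grayscale frame multiplied elementwise by the region's convex image, so
pixels outside the convex mask are exactly zero.

## Tracking

Cells (cutoff 2.5 µm) and individual ridges (cutoff 2.3 µm) are linked frame
to frame by a linear assignment problem on the centroid distance matrix,
padded Jaqaman-style with birth/death slots costing just above the cutoff.
The assignment maximizes the number of admissible links and, among those,
minimizes total linked distance; it coincides with greedy nearest-neighbor
linkage whenever that is unambiguous, and is verified against brute-force
enumeration on all small matrices in the tests.  No gap closing across
skipped frames and no division handling.

## Ridge labeling (classical)

For one extracted cell: Gaussian smoothing (σ = 0.7 px) → gradient by
derivative-of-Gaussian (σ_g = 0.7 px) → Laplacian as the trace of the second
derivative of the gradient image (derivative-of-Gaussian applied twice, not
finite differences) → rectification keeping L ≤ 0 (bright ridge crests are
intensity maxima, where the Laplacian is negative) → logistic sigmoid
S = 1/(1 + exp(−√|L|)), mapping background to exactly 0.5 → Otsu
binarization.  Because the chain starts from derivatives, the label is
invariant to constant intensity offsets.  On noisy synthetic stripe patterns
at SNR 5 rendered at the post-resize pitch (0.098 µm/px, wavelength
0.66 µm, ridge σ 0.15 µm) the label reaches Jaccard ≈ 0.83–0.84 against the
generator stencil; on labyrinthine patterns with variable ridge width it
under-segments flat-topped junctions (≈ 0.70) — the known weakness that
motivates the CNN.

## CNN segmentation

A convolutional encoder–decoder (U-net: double 3×3 conv + ReLU per level,
2× max-pool down, nearest-neighbor up, skip concatenations, 1×1 output conv,
two classes) implemented directly in NumPy with im2col convolutions and
analytic gradients, trained by SGD with momentum 0.9 on weighted pixel-wise
softmax cross-entropy.  Channel widths double from a configurable base
(default 8) — the reference recipe (depth 6, 256² input, learning rate 1e-4,
mini-batch 6, hundreds of epochs) is expressible in `NetConfig` but needs
GPU-scale resources; tests and acceptance run the reduced regime: depth 2,
64² inputs, 200 synthetic stripe pairs, 30 epochs, ≈ 1.5 min on one CPU,
reaching mean IoU ≈ 0.97 on held-out data.  The learning rate for the
reduced regime is 0.05: the loss is normalized per pixel-weight sum, so the
full-scale 1e-4 is far below the useful range here, and rates ≳ 0.2
destabilize the float32 SGD into the uniform-prediction fixed point.

"Median pixel image normalization … to balance foreground and background" is
ambiguous between intensity normalization and loss weighting; both are
implemented: each image is divided by the median of its nonzero pixels, and
classes are weighted by median-frequency balancing (w_c = median class
frequency / class frequency).  Augmentation applies identical rotations,
reflections and integer translations to image and label.  Mean IoU is the
average of per-class intersection-over-union over classes present (empty
unions excluded).  After prediction on the 256²-resized cell, the physical
pitch is restored from the original cell size: Δx = x_o·psz/256 (e.g. a
127-px cell at 0.1977 µm/px → 0.098 µm/px).

## Persistence length from curvature statistics

Each branch of the skeletonized ridge mask (branch points removed; ≥ 10
coordinate points; loops skipped and counted) is traced endpoint to
endpoint.  The trace is smoothed by a Gaussian-weighted local *linear* fit
(window 5 points, σ = 1 point): unlike a plain truncated moving average this
reproduces straight traces exactly, endpoints included.  The prescribed
orientation search — rotate by each of 21 angles spanning [−π, π], smooth,
score by mean standardized Euclidean distance to the raw trace (coordinates
standardized by the raw trace's per-axis standard deviation), keep the best,
rotate back — is implemented literally; because the smoother acts
parametrically on both coordinate series it commutes with rotation, so all
angles tie and the first minimum is kept.  A parametric natural cubic spline
on cumulative chord length (knots sampled exactly, `factor`× densified)
interpolates the smoothed trace.

Along the contour: spacings Δs_k, tangent angles θ_k (four-quadrant),
turn angles φ_k wrapped to (−π, π], curvature κ ≈ 2φ/(Δs_{k−1}+Δs_k), and
the rescaled curvature κ_s ≈ 2φ/√(Δs_{k−1}+Δs_k), which removes the
segment-length dependence of the Gaussian width.  For a 2D worm-like chain
the pooled κ_s is Normal with variance 2/L_p,

    P(κ_s) = √(L_p/4π) · exp(−L_p κ_s²/4),

giving the moment estimator L_p = 2/⟨κ_s²⟩ and a histogram least-squares fit
of the same form (81 bins; the fit is preferred when it converges, the
moment estimate is the fallback).  Flexural rigidity EI = L_p·k_B·T (T
defaults to 300 K) and the Euler critical buckling force of a protrusion of
length L is f_c = π²·k_B·T·L_p/L², reported in pN.  The synthetic worm-like
chain generator draws turn angles from Normal(0, step/L_p) — the exact
discretization inverse to the estimator — and parameter recovery at
L_p = 1–20 µm with ≥ 10⁵ segments is within a few percent.

## Pattern wavelength and branch lengths

The characteristic wave number of a segmented binary pattern is the Fourier
moment wn = √(∫∫ |k|² |I_fN| dk_x dk_y) with I_fN = |I_f|/√(∫∫|I_f|), where
I_f is the continuous-transform approximation (DFT × Δs²/2π) on frequency
axes spanning [−K, K], K = π/Δs; integrals are Riemann sums, the DC bin is
excluded, and λ = 2π/wn.  The integrand is |I_fN| as printed, not its
square; this was implemented literally and is cross-checked against an
independent brute-force transcription (direct O(N⁴) DFT) to 1e-6 relative.
Two consequences are documented rather than "corrected": the statistic is
weakly amplitude-dependent, and because binary edges contribute 1/k spectral
tails weighted by |k|², wn grows with the band limit — λ scales linearly
with Δs.  Values are therefore comparable only at fixed sampling, which is
how the per-cell medians are used (all cells resized to 256² and a common
pitch).  The √2·K band bound is enforced as a warning, not an error, since
broadband images legitimately exceed it.

Branch lengths are skeleton-component pixel counts × Δs after branch-point
removal, with no diagonal √2 weighting (the literal pixel-summing reading);
the per-cell mean ⟨B_l⟩ is the arithmetic mean over branches.

## Optic flow and strain rates

Velocities between registered frames solve the brightness-constancy
constraint ΔI/Δt = −v·∇I per pixel by Lucas–Kanade least squares: spatial
derivatives by derivative-of-Gaussian (σ = 1.5 px), the temporal difference
smoothed at the same scale (consistent operator scales remove a systematic
speed bias), aggregated over a 5×5 box window by default.  Rank-deficient
local systems get zero velocity and are flagged.  Displacements are
converted to µm/min by the pixel pitch and frame interval.  Velocity
components are smoothed with the 3×3 box kernel (1/9)·𝟙 before derived
quantities.

Divergence 𝒟 = ∂v_x/∂x + ∂v_y/∂y uses central differences with physical
spacing.  Pixels with 𝒟 beyond ±0.12 min⁻¹ mark events — growth (𝒟 < 0,
inflow: elongation/merging) and shrinkage (𝒟 > 0, outflow:
fragmentation/splitting) — and the mean velocity *magnitude* over each set
is reported (the averaged quantity is not specified beyond "velocity
magnitudes"; the magnitude is used).  The strain-rate tensor is the
symmetric part S = (V + Vᵀ)/2 of the velocity gradient (the antisymmetric
part is discarded), with shear γ^S = S_xy, closed-form eigenvalues
Λ₁ ≥ Λ₂ (tensile/compressive), and the exact decomposition
S = S^area + S^dev, S^area = ½tr(S)·I, so tr(S^dev) = 0 and
tr(S) = 𝒟 hold to 1e-9 on every field.  The overall principal-strain
magnitude is √2‖S‖_F (Frobenius norm — the √2 prefactor makes a pure shear
of eigenvalues ±s read 2s), averaged over ridge pixels with nonzero
divergence, then over time.

One estimator subtlety is documented for users of the derived fields: the
pointwise *gradients* of a window-aggregated flow estimate carry a
texture-dependent bias (the window's gradient-energy centroid wanders at the
texture correlation scale), so recovering a spatially uniform divergence to
better than ~20% RMS needs the aggregation window to span many texture
correlation lengths.  `optic_flow(..., gaussian_window=σ)` provides the
wide Gaussian-weighted window; the divergence-recovery test runs at
σ = 8 px over a fine speckle texture.  Speed itself is accurate (a few
percent median error) at the default window.

## Flow-scene fixtures

`make_flow_scene` renders a speckle texture of many Gaussian blobs
(σ = 1.5 px — fine enough for gradient-rich flow estimation, coarse enough
that bilinear warping is faithful) and advects it by a named analytic field
(translation, source, shear, rotation) with bilinear backward warping per
frame; brightness constancy under the same warp holds to < 2% RMS, and
displacements ≥ 3 px/frame are clamped with a warning, keeping fixtures
inside the estimator's small-displacement regime.

## Cluster dynamics

Ridge components (8-connected, intensity-weighted centroids) are tracked at
the 2.3 µm cutoff.  Each ridge's axis is the principal eigenvector of the
intensity-weighted coordinate covariance (sign fixed e₁ ≥ 0; near-equal
eigenvalues are flagged isotropic).  The 1D profile sums pixel intensities
per bin of δ_l = x_p e₁ + y_p e₂ at one source-pixel pitch; binning
conserves total intensity exactly.

Gaussian curvature treats intensity as height z(x, y) (scaled to [0, 1],
coordinates in µm): first/second fundamental forms of the Monge patch with
E = 1+z_x², F = z_x z_y, G = 1+z_y², L = z_xx/W, M = z_xy/W, N = z_yy/W,
W = √(1+z_x²+z_y²), and K = (LN−M²)/(EG−F²), with derivatives by
derivative-of-Gaussian at σ = 1.2 µm (no extra pre-smoothing).  Two
numerical safeguards: the mean height is subtracted before differentiating
(the sampled second-derivative kernel is not exactly zero-sum, so a large
offset would leak into z_xx), and the kernel is truncated at 8σ so its
moments are accurate to machine precision.  Coincidence analysis intersects
the strong-curvature sets (|K| > 5 by sign, threshold configurable) at
frame t with the strong-divergence sets (|𝒟| > 0.12 min⁻¹) for t → t+1 and
reports the four pairing counts plus the positive-K fraction.

## Synthetic data: what it does and does not emulate

The generators provide known ground truth for every estimator: turn-angle
law for the chains, stencil masks and exact spatial periods for the
patterns, analytic velocity fields for the flow, separable slice entropies
for the stacks, and cell-label images for the sheets.  Defaults follow the
imaging regime the toolkit targets: pixel pitch 0.098 µm (the post-resize
pitch of a typical extracted cell), pattern wavelength 0.66 µm, ridge
profile σ 0.15 µm (≈ 0.3 µm ridge width), additive Gaussian noise
(amplitude 0.2 = SNR 5 in the fidelity tests).  Not emulated: microscope
PSF anisotropy, Poisson photon statistics, 3D ridge height, cell
deformation and neighbor exchange, photobleaching.  Passing tests therefore
demonstrate correctness of the computations and recoverability under
realistic geometry and noise amplitude — not robustness to every real-world
artifact; the per-movie thresholds and morphology radii exist precisely
because real contrast varies.

## Reduced problem sizes

Tests and the worked examples use desk-scale sizes chosen as the package's
own validation conditions: 128²–256² scenes, ≥ 10⁵ chain segments for
parameter recovery, 200 training pairs at 64² for the reduced CNN run, 96²
flow scenes.  The full-scale recipe (1500+ cells, 256² inputs, hundreds of
epochs) is configurable but not exercised here.
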