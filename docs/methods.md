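# Methods

`opticorr` models how a viewer with uncorrected refractive error perceives a
specific emissive display, and inverts that model: it optimizes the displayed
image so that the *simulated retinal image* — in cone-activation (LMS) space —
matches the cone response the intended image would ideally evoke. This note
records the model, its assumptions, the numerical choices, and what the
synthetic test bench does and does not demonstrate.

## 1. Display and cone model

A display emits light through three primaries with relative emission spectra
φ_R, φ_G, φ_B(λ); the retina encodes light through three cone classes with
sensitivities ℓ(λ), m(λ), s(λ). For a linear-light pixel value
(I_R, I_G, I_B), the cone activation is

    [I_L, I_M, I_S]ᵀ = A · [I_R, I_G, I_B]ᵀ,
    A[k, c] = Σ_λ cone_k(λ) · φ_c(λ) · Δλ ,

evaluated on a uniform wavelength grid (default 400–700 nm at 1 nm). The Δλ
weight makes the sum a Riemann integral, so the matrix is invariant under
grid refinement; at Δλ = 1 nm it reduces to the plain sum over samples.

Only relative spectra matter: all curves are peak-normalised, and `A` is
scaled by a single scalar so that full white (1,1,1) maps to cone activations
with maximum 1. Ratios are unchanged, and the unscaled overlap matrix is
retained (`LMSMatrix.raw`) for oracle work. No absolute photometric units are
modelled.

A colour-opponency recoding ((M+S)−L, (L+S)−M, achromatic) is available as an
alternative loss space. The achromatic channel is the arithmetic mean of
L, M, S by default (a sum is a config option); either choice keeps the
transform exactly invertible.

**Spectral fitting.** Raw spectrometer samples are turned into smooth curves
by a shape-preserving piecewise-cubic (PCHIP) interpolant — deterministic,
monotone-safe, no ringing — normalised to peak 1 and clipped at zero. A
one-hidden-layer MLP (64 tanh units, L-BFGS training) is provided as an
alternative backend; both satisfy the same contract (mean absolute error
≤ 0.02 at the sample wavelengths on the normalised scale). L-BFGS rather
than stochastic updates because the sample sets are a few dozen points and
the requirement is interpolation quality.

**Built-in fixtures.** The synthetic display has Gaussian primaries at
620/530/460 nm (σ = 15 nm), representative of LED-backlit panels; the
built-in cone fundamentals are asymmetric Gaussian lobes peaking at
565/540/445 nm with realistic overlap ordering (L and M strongly overlapping,
S well separated). These are qualitative stand-ins: they reproduce the
overlap *structure* that makes the LMS pipeline differ from per-channel RGB,
not any individual's measured sensitivities. Measured fundamentals can be
supplied as CSV for fidelity work.

## 2. Wavefront and point spread functions

A sphero-cylindrical prescription (S, C, axis; diopters/degrees, TABO axis
convention) is converted through the power vector M = S + C/2,
J0 = −(C/2)cos 2a, J45 = −(C/2)sin 2a to ANSI second-order Zernike
coefficients over the pupil radius r (metres), in micrometres:

    c(2,0) = −M·r²/(4√3),  c(2,2) = −J0·r²/(2√6),  c(2,−2) = −J45·r²/(2√6).

Higher-order coefficients may be supplied directly. Zernike polynomials use
OSA/ANSI single indexing and ANSI (unit-RMS) normalisation.

The monochromatic PSF is |FFT of the complex pupil function|²,
P = A(ρ)·exp(i·2πW/λ), with an area-antialiased aperture edge. The same
wavefront W (in µm) is reused at every wavelength — wavelength enters only
through the 2π/λ phase scaling and diffraction. Ocular longitudinal
chromatic aberration and spatial PSF variation across the field are
deliberately out of scope.

**Sampling geometry.** PSFs live on a uniform angular grid of `grid_px`
pixels with pitch = field_extent/grid_px. Internally, the pitch is refined
by an integer factor B so the aperture's *intensity* spectrum is
Nyquist-sampled at the shortest wavelength (internal pitch ≤ λ_min/2D), the
FFT grid is `pad_factor`× the output for field headroom, and the fine result
is box-binned back to the output pitch. Two details matter:

- the per-wavelength pupil-plane pitch is λ/(M·δ), so all wavelengths land
  natively on one common output grid (no resampling between wavelengths);
- the bin partition is centred on the optical axis (the DFT centre sample
  falls in the middle of a bin, not on a bin edge). Without this, a
  diffraction-limited near-delta PSF is split across two output pixels —
  a spurious half-pixel blur that measurably corrupts no-aberration
  baselines.

A `SamplingError` is raised when less than 99% of the diffracted energy
falls inside the output grid, with the contained fraction attached.

**Defaults.** Human preset: 4 mm photopic pupil, 128² grid, 1.375° field —
sized so a ±1.5 D blur disc occupies a quarter of the field. The camera
testbed preset (13 mm aperture) is provided separately and is not the
default. One display pixel is assumed to subtend one PSF pixel; i.e. the
default geometry corresponds to ~93 display pixels per degree of visual
angle.

**Spectral kernels.** The per-primary PSF is the emission-weighted mean of
monochromatic PSFs (weights renormalised to sum to 1 per primary). The
rank-4 LMS kernel is built wavelength-resolved,

    K[c, x, y, k] = Σ_λ φ_c(λ) · cone_k(λ) · PSF_λ(x,y) · Δλ  (then scaled),

which weights each wavelength by the cone sensitivity *at that wavelength*;
the aggregated mode (`kernel_mode="aggregated"`) applies the matrix A to the
already spectrally averaged per-primary PSFs instead. The two coincide
exactly when the PSF is wavelength-independent, and the resolved form is the
physically consistent generalisation. In both modes the kernel's
per-(primary, cone) spatial mass is pinned to the corresponding entry of A
(the pinning correction is a ~1e−15 relative rescale of FFT round-off), so
energy bookkeeping is exact by construction and verified to 1e−9 in tests.

## 3. Differentiable retinal simulation

The retinal image is

    retina[·,·,k] = Σ_c image[·,·,c] ⊛ K[c,·,·,k],

where ⊛ is 2-D cross-correlation (kernel applied unflipped — the convention
is pinned by brute-force oracle tests) with reflect padding and "same"
output. Reflect padding avoids the dark vignette zero padding would inject
into the loss at image borders. Images are treated as linear light; an
optional sRGB decode/encode at load/save is off by default.

Gradients are computed with the exact adjoint operator: the adjoint of
valid-mode correlation is full-mode convolution, and the adjoint of reflect
padding folds the padded margins back onto their source pixels. A cached
implementation (`RetinaOperator`) precomputes the nine kernel-slice OTFs
once per (kernel, image shape) so each forward or adjoint application costs
six real FFTs; it agrees with the direct path to ~1e−15 and with central
finite differences to better than 1e−7 in practice (contract: 1e−4).

## 4. Precorrection solvers

Proposed method:  s′ = argmin_{s∈[0,1]}  mean‖K⊛s − A·t‖²  (LMS space, or
the opponency recoding of both sides). Conventional baseline: independent
per-channel deconvolution, argmin_{s∈[0,1]} mean‖PSF_c⊛s_c − t_c‖², the
assumption that display channels map one-to-one onto retinal channels.

The feasibility constraint is implemented as projection onto [0,1] after
every step (a sigmoid reparameterisation is available). Initialisation is at
the target image, which — together with best-iterate tracking — guarantees
the returned loss never exceeds that of displaying the target unmodified.
Divergence (loss > 10× initial for 50 consecutive iterations, with a small
absolute floor so an exactly-recovered identity case cannot trip it) raises
an error carrying the trace.

Three solvers:

- **adam** (default, 200 iterations, lr 0.02): adaptive-moment projected
  descent, matching the approach the forward model was designed around.
- **sgd**: plain projected gradient.
- **fista**: accelerated projected gradient with step 1/L (L estimated once
  by seeded power iteration) and adaptive restart. The objective is a convex
  box-constrained quadratic, and FISTA reaches markedly deeper optima per
  unit time; the comparison suite uses it for *both* methods at an equal
  iteration budget (400), because near-converged comparisons are otherwise
  dominated by solver race effects rather than by the models being compared.

All solvers are deterministic given seed and config; loss traces are
bit-reproducible.

**Metrics.** PSNR in dB over the joint channels with unit data range
(so a uniform offset of 0.1 gives exactly 20 dB), and SSIM with the standard
constants per channel, averaged. Identical images report PSNR = inf,
SSIM = 1. FLIP is an interface slot only.

## 5. The five-condition comparison

The simulated evaluation runs five refractive conditions built from ±1.5 D
components — myopia (−1.5 S), hyperopia (+1.5 S), simple myopic astigmatism
(−1.5 C), simple hyperopic astigmatism (+1.5 C at 90°), and a mixed case
(−1.5 S / +3.0 C at 45°, meridians −1.5 and +1.5 D) — against three 256²
structured fixtures (slanted-edge/bar chart, text-like stroke pattern,
smooth colour gradient), chosen to span high- and low-frequency content.
Kernels use a 64² grid at the default field (half the default resolution,
same physical geometry) so the whole table runs in ~6 minutes on one CPU.
For every cell the table reports uncorrected, RGB-baseline, and LMS-proposed
variants scored against the ideal cone response.

Observed behaviour (recomputed by `scripts/acceptance.py`): retinal PSNR
improves over the uncorrected display in all 15 cells, and the proposed
method's LMS-space L2 is never worse than the RGB baseline's. SSIM improves
in 14 of 15 cells; the exception is the binary edge chart under simple
astigmatism — the mildest blur of the five — where the L2-optimal clipped
solution introduces low-amplitude ringing into large saturated flat regions
that SSIM's structure term penalises even as MSE-based metrics improve.
This is a loss/metric mismatch specific to saturated binary content;
photographic mid-tone images do not exhibit it.

Because the wavefront is wavelength-independent, the ±1.5 D sphere
conditions produce identical PSF intensities (defocus sign symmetry), so
myopia and hyperopia rows agree exactly; modelling the chromatic or
higher-order asymmetries that break this tie is listed as future work.

## 6. Learned surrogate

The iterative solver is distilled into a U-Net-style encoder–decoder:
double 3×3 convolutions and 2×2 max pooling on the contracting path,
bilinear ×2 upsampling with skip connections on the expanding path, ReLU
activations, and a zero-initialised 1×1 *residual* head under a
hard-sigmoid bound — the untrained network is the identity map, so training
only has to learn the correction field, and the bounded-linear head keeps
unit gradients across the displayable range (a logistic head stalls on
near-binary targets). One model is trained per (prescription, display)
pair; checkpoints embed the kernel fingerprint and prediction refuses a
mismatched kernel unless forced.

Because no GPU framework is assumed, the network runs on a small
reverse-mode autodiff engine (`opticorr/_nn.py`): tape-based scalar-loss
backward over numpy arrays, im2col convolutions, and exact adjoints for
pooling/upsampling — gradients verified against finite differences through
the entire network (≤ 1e−4 relative, observed ~1e−7). The default preset
(depth 3, 16 base channels, Adam lr 2e−3, batch size 1, 150 epochs) trains
on one CPU in ~2 minutes at 64²; `paper_preset()` exposes the full-size
channel schedule (92 → 1472, lr 1e−4) for accelerated hardware.

The distillation demo overfits five fixture pairs under a mild −0.5 D
kernel: at this scale the MSE drops ≥ 40× from the identity start,
training-set predictions reach ≥ 34 dB against the teacher labels, and on
every meaningfully blurred pair (uncorrected retinal MSE ≥ 1e−3) the
prediction lands closer to the ideal cone response than the unmodified
image. (For smooth images under this mild blur the unmodified display is
already essentially optimal — uncorrected retinal MSE ~1e−4, below the
surrogate's own fit floor — so no corrector can improve those cells.)
Under heavy blur (−1.5 D) the teacher labels are ringing-dominated
and a CPU-scale network cannot memorise them to 30 dB in minutes; the demo
is therefore a sanity check of the distillation pathway, not a statement
about capacity at production scale.

## 7. What the synthetic bench does and does not show

The bench demonstrates internal correctness (oracle agreement, energy
conservation, exact gradients, determinism) and the *relative* ordering of
the two precorrection models under controlled conditions. It does not
calibrate to any physical display or observer: spectra and cone curves are
synthetic, there is no chromatic aberration of the eye, no spatial PSF
variation, no photometric calibration, and no human-subject or camera
validation. Absolute metric values therefore characterise the fixtures, not
real-world performance.

## 8. Numerical choices, in brief

- Wavelength grid 400–700 nm at 1 nm; coarser grids are used in unit tests
  (10–50 nm) where only oracle equality is at stake.
- PSF energy containment threshold 99%; antialiased aperture edge; internal
  Nyquist refinement and centred binning as in §2.
- Convolutions pick direct evaluation for small kernels (so a delta kernel
  is bit-exact) and FFT for large ones; the solver path always uses the
  cached-OTF operator.
- Optimizers: defaults above; stopping on a fixed budget, with optional
  relative-improvement tolerance; a loss ≤ 1e−14 stops immediately (the
  identity case would otherwise random-walk on round-off noise through the
  adaptive-moment update).
- All randomness (jitter, random init, power iteration, training shuffles)
  flows from explicit integer seeds; two equal-seed runs are bit-identical.
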