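# Methods

## Model and assumptions

A droplet at rest in a microchannel is in mechanical equilibrium: the
Laplace pressure jump ΔP = P_in − P_out equals γ(κ_∥ + κ_⊥) everywhere on
its surface, with γ the interfacial tension and κ_∥, κ_⊥ the principal
curvatures in and out of the imaging plane. When a cell presses on the
droplet with a normal stress Δσ_NN, local equilibrium becomes
ΔP + Δσ_NN = γ(κ_∥ + κ_⊥). Three assumptions let us isolate Δσ_NN from a
single imaging plane:

1. **ΔP is uniform and steady.** The droplet interior is at a single
   pressure, and part of the interface always faces plain medium, so the
   excess pressure is set by the medium/oil interface at every time point.
   Subtracting the resting from the deformed state cancels it.
2. **κ_⊥ does not change.** The channel is about half as high as it is
   wide; a pancake droplet is held flat by floor and ceiling and the cell
   squeezes past it in the imaging plane. The out-of-plane term is treated
   as time-constant and drops out of the difference.
   `mean_curvature_sum` exists for diagnostics (e.g. estimating the
   resting ΔP with κ_⊥ ≈ 2/h for channel height h) but plays no role in
   the stress estimate.
3. **γ is uniform.** The tension of the cell-facing interface is taken
   equal to the medium-facing one; the absence of a visible contact angle
   where cell, droplet and medium meet supports this.

The stress estimate is then

Δσ_NN = γ (κ_∥,rest(θ*) − κ_∥,def(θ*)),

with θ* the angle of minimal curvature of the *deformed* profile inside a
configurable contact window (default: the upper half-plane, the side the
cell approaches from). With γ in mN/m and κ in µm⁻¹, the product times
1000 is in Pa, and numerically identical in pN/µm².

A compressive contact (flattening, κ_def < κ_rest) gives Δσ_NN > 0. A
concave indentation gives negative κ_def and a larger positive stress;
both are permitted by the sign conventions (counter-clockwise contours,
positive curvature = locally convex).

## Parameters

| Parameter | Default | Units | Meaning |
| --- | --- | --- | --- |
| `pixel_size_um` | 0.1 | µm/px | physical pixel size of the input images |
| `upscale` | 10 | – | nearest-neighbour subdivision before the snake |
| `median_radius_px` | 1 | px | light denoise homogenizing the droplet fill |
| `snake_alpha` / `snake_beta` | 0.015 / 10 | – | snake elasticity / rigidity weights |
| `snake_n_iter` | 500 | – | iteration cap |
| `snake_convergence_tol_um` | 0.01 | µm | per-iteration mean displacement at which the fit is converged |
| `snake_smoothing_sigma_px` | 1.5 | original px | Gaussian pre-smoothing that widens the gradient ring |
| `snake_n_points` | 512 | – | snake vertices |
| `resample_n` | 512 | – | uniform-arclength samples before filtering (power of two) |
| `fft_harmonics` | 16 | – | low-pass cutoff on the x(s), y(s) signals |
| `contact_window_rad` | (0, π) | rad | angular window searched for the contact |
| `gamma_mN_per_m` | 8.4 | mN/m | interfacial tension of soybean-oil droplets in culture medium |
| `window_um` | 700 | µm | invasion counting window from the loading well |

The snake weights put the fit in a stiff, smooth-blob regime appropriate
for droplets; they are exposed because other objects (or other
magnifications) may need different values. The 16-harmonic default keeps
every shape feature of a two-lobed deformation (harmonics ≤ 3 carry the
pear family exactly) while discarding pixel-scale ripple; the stress
estimate is required to be stable over cutoffs 8–32 and the validation
suite checks that it is, within 10%.

Curvature error amplifies as m² for a coordinate perturbation at harmonic
m, which is why the pipeline is engineered around keeping sub-pixel
coherent error small: the 10× upscale lets the snake settle between
camera pixels, and the pre-smoothing (1.5 original pixels) suppresses
grid-locking of the snake onto the upsampled blocks.

## Interfacial tension

`tension` implements the aspiration estimator. For suctions below
critical, the tongue cap obeys 1/R_C = ΔP/(2γ) + 1/R_D; entry happens at
ΔP_c = 2γ(1/R_P − 1/R_D). The critical pressure is bracketed between the
last non-entered and first entered ramp step and assigned to the midpoint
(unbiased under uniform stepping), with half a step as uncertainty. Entry
at the very first step leaves only an upper bracket; such ramps are
flagged and excluded from cohort averaging rather than silently biasing
it. When a ramp carries no explicit entry flags, entry is inferred from
the recorded cap radius reaching the pipette radius (or the measurement
disappearing); with measurement noise on R_C this inference can trigger
early because the cap radius approaches R_P slowly near criticality, so
explicit flags are preferred when available. Cohort pooling is an
unweighted mean with the sample standard deviation over droplets.

## Invasion statistic

Cells in a channel are classified against the *first* droplet within the
counting window (700 µm from the loading well). Channels qualify with one
to three droplets in the window: none leaves the before/after partition
undefined, four or more makes attribution to a single obstacle ambiguous.
Cells within one cell radius (default 6.5 µm) of the obstacle are in
mechanical contact with it and are counted separately ("at obstacle")
instead of being forced to a side. Channels are the unit of analysis;
condition comparisons default to a seeded two-sided permutation test on
per-channel percentages (distribution-free, reproducible), with Welch's
t-test and Mann–Whitney available.

## The phantom generator

`phantoms` provides every input type with closed-form ground truth:

* **Polar contour family** r(θ) = R0(1 + a1 cos(θ−φ) + a2 cos 2(θ−φ)).
  This is the minimal smooth family producing one flattened contact
  region; its curvature follows the polar formula in closed form. It is a
  *stand-in* for the deformed droplet shapes seen in experiments, not a
  mechanical reconstruction: it does not conserve droplet area between
  rest and deformation, and its flattening is symmetric while a real cell
  contact need not be.
* **Pancake contours** (disc truncated by walls at ±w/2) with exact
  curvature 0 on flats and 1/R on arcs.
* **Image rendering.** Interior 200 counts on a 20-count background,
  8-bit. The indicator of the contour is sampled on an 8× supersampled
  grid, blurred there (σ = 1 original pixel by default, emulating the
  optical PSF), and averaged over each pixel — i.e. the *continuous
  scene* is blurred and then integrated, as a camera does. Rasterizing
  first and blurring afterwards leaves an orientation-dependent edge bias
  of order 0.01 µm which the m² curvature amplification turns into stress
  errors of tens of percent; scene sampling removes it. With
  `blur_sigma=0` the scene is sampled point-wise and the image is exactly
  two-valued. Gaussian noise (default SD 2 counts, a bright-staining
  confocal regime) is added last and clipped.
* **Aspiration ramps** following the spherical-cap equilibrium with the
  entry flag switching at ΔP_c, optional Gaussian noise on R_C.
* **Channel layouts** with uniform droplet/cell positions; an optional
  bias parameter places a fraction of cells before the first droplet to
  emulate a blocked population.

What passing on phantoms does *not* show: robustness to uneven
illumination, dye bleaching, neighbouring objects touching the droplet,
partial occlusion by the cell (real Nile-Red images show the droplet only;
the cell is dark), or out-of-focus drift. Those failure modes need real
data and fall to the user to control.

## Numerical choices

* **Derivatives are spectral.** After low-pass filtering the contour is
  band-limited by construction, so differentiation in Fourier space is
  exact for the retained harmonics; finite differences would re-introduce
  discretization error. The curvature formula is parameterization
  invariant, so exact uniform arclength is not required — uniform
  *sampling* of a smooth closed curve is.
* **Resampling** is linear interpolation along the polygon at uniform
  arclength, n a power of two ≥ 128. It preserves the perimeter of a
  densely sampled smooth contour to <0.1%; a polygon with vertex-scale
  zigzag is shortened (corner cutting), which is intended — that zigzag
  is segmentation noise.
* **Snake convergence** is probed by running ten extra iterations and
  measuring the mean per-iteration displacement; above tolerance the
  result carries `meta['converged'] = False` and a warning, never an
  exception.
* **Tie-breaks.** Equal-area components at initialization: brighter mean
  intensity wins. Equal minimal curvature in the contact window: smallest
  |θ| wins; a profile flat over the whole window is flagged
  `no_distinct_contact`.
* **Degenerate inputs.** Zero-perimeter contours, vanishing
  parameterization speed, windows with fewer than 8 samples, empty ramp
  sets and channels without classified cells all raise (or, for the
  channels, are excluded with a logged warning) rather than propagating
  NaNs.
* **Angles** are measured about each contour's own area centroid, θ = 0
  along +x (the channel axis as imaged). Pairing rest and deformed frames
  by centroid-relative angle assumes the deformation moves the centroid
  little; on phantoms the shift is ≲2% of the radius. This is a
  documented approximation, not an invariant.
* **Minimum-statistic bias.** θ* is the argmin of a measured curve; for
  shallow deformations the curvature valley is broad and the minimum
  picks up the most negative residual wiggle, biasing Δσ slightly
  upward. With the default pipeline the residual curvature wiggle is
  ~0.002 µm⁻¹, so stresses below ~100 Pa (Δκ < 0.012 µm⁻¹) approach the
  noise floor of the method at these imaging parameters.

## Validation problem sizes

The validation suite and `scripts/acceptance.py` use: 512-point contours;
a 3×3 (γ, Δκ) grid with γ ∈ {5, 8.4, 12} mN/m and Δκ ∈ {0.03, 0.06,
0.09} µm⁻¹ (stresses of 150–1080 Pa, bracketing the ~500 Pa scale of
interest) rendered at 0.1 µm pixels; 100 random smooth contours for the
conservation law; a 36-point (γ, R_P, R_D) grid plus 100 noisy seeds for
the tension round trip; 1000 random layouts against brute-force counting
and 30-channels-per-condition comparisons for the invasion statistic.

## Known limitations

* Single droplet per frame; multi-droplet scenes are segmented by
  largest-component selection only, and tracking across frames is
  nearest-centroid.
* No 3D reconstruction: κ_⊥ is never measured, only assumed constant.
* The stress is a point estimate at θ*; the full Δκ(θ) profile is
  available on the measurement objects for inspection but the headline
  number is the minimum-curvature point.
* Quasi-static analysis: viscous stresses during fast deformations are
  neglected in both the stress inversion and the aspiration estimator.
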