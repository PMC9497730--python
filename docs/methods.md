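# Methods

## Physical model

The core process is 1-D Fickian diffusion of an iodinated, cationic
contrast agent from a well-stirred bath into an articular cartilage layer:

    dc/dt = D d²c/dx²,   x in [0, L],

with boundary conditions

* `c(0, t) = κ · c_bath(t)` at the articular surface — local partition
  equilibrium with the bath. κ > 1 models the electrostatic attraction of
  the positively charged agent to fixed negative glycosaminoglycan charge;
  it is a lumped equilibrium description, not a Donnan or binding-kinetics
  model.
* `dc/dx(L, t) = 0` at the tidemark — subchondral bone treated as
  impermeable on the experiment's timescale.
* Finite bath (default): `V_bath · dc_bath/dt = −(V_cart/L) · j(0, t)`,
  i.e. the bath depletes by exactly the flux entering the cartilage, so
  total iodine mass `V_bath·c_bath + (V_cart/L)·∫c dx` is invariant.
  An infinite-bath mode holds `c_bath` constant.

The mass convention: κ acts at the interface (surface concentration is
κ·c_bath) and cartilage iodine content is the plain volume integral of c.
This is the simplest model that yields an above-unity equilibrium
cartilage-to-bath ratio while conserving mass; the equilibrium follows
algebraically from `V_b·c_b + V_c·κ·c_b = V_b·c_0`.

## Default parameters (the simulated bench conditions)

| parameter | default | units | rationale |
|---|---|---|---|
| L (cartilage thickness) | 2.0 | mm | typical bovine tibial/femoral plug cartilage |
| V_bath | 0.5 | mL | bath volume poured over the plug |
| V_cart | 0.157 | mL | 10 mm plug × 2 mm layer |
| c_bath0 | 10 | mgI/mL | mid-range immersion concentration |
| κ | 6.3412 | – | set so the equilibrium plateau is 21.2 mgI/mL under the mass balance above |
| D | 0.6 | mm²/h | ≈1.7·10⁻⁶ cm²/s, the order of small-solute diffusivities in cartilage; puts the fitted saturation time at ≈2.1 h |
| acquisition times | 2 min … 26 h (17 points) | h | ragged bench grid |
| microCT pixel | 0.01152 | mm | planar detector pitch |
| clinical voxel | 0.32 × 0.32 × 0.625 | mm | in-plane pixel × slice thickness |
| planar noise | 5 | GL | additive Gaussian detector noise |
| clinical noise | 40 | HU/scan | SNR ≈ 5.7 on a 10 mgI/mL enhancement |

Note that with a finite bath the uptake curve saturates much faster than
the infinite-bath time constant `4L²/(π²D)` suggests: early on the bath is
still full, so the surface is held at a high concentration. D was therefore
chosen against the *finite-bath* fitted time constant.

## Solver numerics

Space is discretized vertex-centered with half-cells at both boundaries
(finite-volume form), which makes the trapezoidal rule the quadrature under
which the semi-discrete system conserves mass *exactly*; the bath is an
extra compartment merged with the surface half-cell and the coupled system
is symmetrized by a diagonal similarity transform. Time propagation is the
exact matrix exponential of the semi-discrete operator, evaluated through
one symmetric eigendecomposition per grid: unconditionally stable, no
time-stepping error, and arbitrary ragged output grids come free. Spatial
accuracy is raised to fourth order by Richardson extrapolation over a
node-doubled grid (the returned field stays on the requested `nx` nodes;
the depth integral combines the two grids' conservative quadratures, so
reported masses remain exact to roundoff). At `nx = 200` the depth-mean
uptake agrees with the closed-form eigenseries to ~3·10⁻⁹ relative over
θ = Dt/L² ∈ [0.01, 2].

The closed-form series `U(θ) = 1 − Σ 8/((2n+1)²π²)·exp(−(2n+1)²π²θ/4)` is
kept in the package as the independent oracle. At θ = 0 the undamped series
converges only algebraically (~10⁻³ at 200 terms), so the exact limit 0 is
returned directly there.

Degenerate inputs: non-increasing time grids, `nx < 10`, non-positive D, L
or volumes are rejected at configuration time; κ < 1 is allowed but warned
(it would mean the cartilage equilibrates *below* the bath).

## Intercept conventions

Both measured calibrations have a nonzero intercept, and how that intercept
should interact with baseline-*subtracted* signals is genuinely ambiguous.
Two conventions are implemented end to end and must be used consistently on
the forward (simulation) and inverse (analysis) sides:

* `affine` (default): contrast-bearing pixels gain `a + b·c`; subtracted
  signals are inverted with the full affine map `(Δ − a)/b`. This mirrors
  applying a measured calibration curve directly to subtracted images.
* `slope_only`: pixels gain `b·c` and the inverse is `Δ/b` — the physically
  linear difference-signal reading.

Pixels with `c = 0` are never offset, so a zero-concentration rendering
equals the baseline under either convention.

## Kinetic fits

Uptake: nonlinear least squares of `A(t) = a(1 − e^(−t/τ))`, initialized at
`a₀ = max(values)` and τ₀ = earliest time the signal passes `(1 − 1/e)·a₀`
(fallback `t_max/3`), with bounded restarts at 0.5× and 2× τ₀; a fit that
still fails raises `FitConvergenceError` carrying the attempted starts —
never a silent fallback. The t = 0 baseline point is excluded by default
(its subtracted signal is identically zero by construction). The fitted
curve passes 63.2% of its plateau at t = τ; uptake reports conventionally
round this to "65%". The saturation time is reported as `τ95 = 5τ` by
convention even though `1 − e⁻⁵ = 0.993`, with the mathematically exact
`ln(20)·τ ≈ 3.0τ` available behind an `exact` flag; both conventions are
preserved rather than reinterpreted.

Washout: `c(t) = a_w·e^(−b_w t)`, initialized by log-linear regression
(exact on noiseless data, so three points recover the truth exactly);
non-positive concentrations trigger a direct NLS fallback. Constant inputs
return a fit flagged `degenerate` (b_w = 0, infinite washout time) with a
warning. `washout_time(fit, ref)·b_w = ln 20` exactly when `ref = a_w`.

## Volumetric pipeline choices

* Registration maps the post scan into the pre (baseline) frame; the
  fitted transform is the least-squares proper rigid motion (Kabsch/Wahba,
  reflections excluded) over ≥3 non-collinear fiducials, with the RMS
  fiducial registration error reported.
* Resampling is trilinear; voxels whose interpolation stencil touched any
  out-of-domain (or previously invalid) source voxel are masked invalid and
  excluded downstream.
* Segmentation replaces an irreproducible manual cleanup:
  `segment_iodine_mask` is the literal contract (threshold, then drop
  26-connected components below a size floor, default 27 voxels). The
  pipeline layer chooses the threshold automatically: the difference volume
  is Gaussian-smoothed (σ = 1 voxel) for segmentation only, and the
  threshold is iterated to half the median supra-threshold enhancement
  (isodata-style fixed point, seeded at 3× the robust MAD noise floor).
  Half-plateau thresholding keeps the boundary of a blurred step unbiased,
  which a fixed 3σ threshold does not: at SNR ≈ 5 the latter either floods
  the blurred shell or punches ~14% noise holes in the interior.
* Concentration mapping uses the *unsmoothed* difference inside the mask;
  VOI statistics for concentration recovery use cylinders seated in the
  interior 60% of the local layer so partial-volume boundary voxels do not
  bias the mean.
* Thickness is the longest contiguous masked run per column along the
  declared transversal axis (robust to speckle for non-convex masks),
  averaged per VOI, then mean ± sd across VOIs. Volume is voxel count ×
  voxel volume.

## Statistics

Cohen's d uses the pooled standard deviation and is reported as a magnitude
in the tissue table (a signed variant exists); zero pooled sd with unequal
means is signalled as infinite. Mann–Whitney and two-sample KS are
two-sided; `method="auto"` (default) uses exact null distributions for
small samples — where the exact Mann–Whitney p provably matches full
enumeration of group assignments — and asymptotics with midrank tie
correction otherwise. The default is auto rather than always-asymptotic
because the asymptotic two-sample KS is noticeably conservative at n ≈ 50
and would distort the tests' stated 5% level. The one-sample normality
check defaults to the estimated-parameter (Lilliefors) reference, with the
fixed-standard-normal variant selectable; the variant used is always
reported in the output.

No multiple-testing correction is applied across the three tissue pairs;
that matches how such tables are conventionally reported and is a deliberate
non-goal.

## What the synthetic data does and does not emulate

Emulated: finite-bath Fickian uptake with partitioning, Beer–Lambert-linear
attenuation with additive Gaussian detector noise, banded plug radiographs,
a three-tissue CT phantom with smoothly varying cartilage thickness
(1.8–2.8 mm), a known rigid repositioning between scans, exact fiducials,
and near-iso-attenuating soft tissues pre-contrast. The phantom keeps a
2.5 mm air margin so a repositioned scan stays inside the field of view,
and stacks the cartilage layer along the 0.32 mm axis so the default
thickness spans 6–9 voxels.

Not emulated: polychromatic beam/beam-hardening, Poisson photon statistics
(no exposure model), scatter, depth-varying glycosaminoglycan gradients
(the default iodine map is uniform; a linear depth gradient is available),
cartilage heterogeneity across samples, bath convection or temperature
effects, and marker localization error in the phantom (tests inject it
explicitly where needed). Passing tests therefore demonstrate correctness
of the *analysis chain* under its stated model, not robustness to every
physical confounder of real acquisitions.

## Known limitations

* The single-exponential uptake surrogate fits the finite-bath simulation
  imperfectly (r² ≈ 0.91 noiseless): the true curve rises faster early
  (full bath, high surface concentration) and settles slower. Fitted τ95
  is still a stable summary, and against the infinite-bath solution the
  surrogate reaches r² > 0.98.
* Three-point washout sampling makes the washout time a wide-variance
  estimate (roughly ±30% at 5% measurement noise); that is a property of
  the design being simulated, not of the fitter.
* The equilibrium partition coefficient is concentration-independent; real
  electrostatic partitioning saturates with bath concentration.
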