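# Methods

`bioconvect` implements the quantitative machinery for studying
bioconvection in suspensions of up-swimming, bottom-heavy microalgae
(*Chlamydomonas*-like swimmers): synthetic data generation, image-based
pattern and density quantification, single-cell motility statistics,
cell-flow velocimetry, and the gyrotactic continuum theory that predicts
when coherent flows emerge. This note records the models, the defaults
and why they were chosen, the numerical decisions, and the known limits
of what the synthetic round trips demonstrate.

## 1. Single-cell models

### Run-and-tumble motility

Cells move ballistically at speed `u` along a body axis `p` and
reorient completely at Poisson rate `1/τc` (tumble angles uniform on
the circle; the turn-angle distribution of real cells is not well
constrained, and complete randomization is the canonical choice that
yields the exponential velocity autocorrelation `Cv(t) = v² e^(−t/τc)`
exactly). Optional rotational diffusion `Dr` adds angular white noise
between tumbles. Integration is Euler–Maruyama on the body angle, so
`|p| = 1` holds to machine precision; the default step is 1/30 s,
matching video-rate acquisition. Defaults for the low-light anaerobic
plateau are `u = 46 µm/s`, `τc = 15 s`; the aerobic/high-light state is
`u = 92 µm/s`, `τc = 2.4 s`.

Walls are reflective in position with the orientation unchanged — a
cell pressed against a wall keeps jittering there until its orientation
carries it away, which is what bottom-heavy algae do at interfaces.
Passing `domain=None` simulates free space, with initial positions
spread at ~800 cells/mm² (the areal density of the motility assays):
this emulates tracking in a field of view far from compartment walls,
which is how motility data are actually taken — in a bounded box the
wall-trapped subpopulation contributes near-zero displacement samples
that belong to the wall rule, not to the assay being emulated.

### Gyrotactic orientation

Bottom-heavy swimmers right themselves against gravity on a timescale
`B` while the local flow vorticity `ω` rotates them. In 2D the body
angle θ (from vertical) obeys

    dθ = [ −sin θ/(2B) + ω/2 ] dt + sqrt(2 Dr) dW.

A uniform vorticity with `Bω < 1` gives the tilted equilibrium
`sin θ = Bω` (verified to 1e-3 in the tests); `Bω ≥ 1` gives
continuous tumbling, which is allowed, not an error. The linearized
relaxation rate toward vertical is `1/(2B)`, so reaching a residual
tilt of 1e-6 from horizontal takes ≈ 29·B, not 20·B.

In a closed column, upward drift balancing diffusion produces the
inverse sedimentation profile `n(z) ∝ exp(v z/D)`. For an active
particle this flux balance only holds when the orientation decorrelates
over distances short compared with the decay length; the confined-column
test therefore uses a weak-alignment regime (`u = 20 µm/s`,
`Dr = 0.125 rad²/s`, `B = 20 s`, von Mises concentration κ = 0.2,
persistence ≈ 160 µm) in which an independent simulation of the
orientation process gives `v_z = 1.97 µm/s` and `D_z = 1.55e3 µm²/s`,
predicting a decay length of 788 µm; the package's confined simulation
reproduces it within 10%. With strong alignment and large effective
diffusivity (persistence ≳ column height) the local description fails
and the measured decay is correspondingly longer — a physical statement
about active transport, not a numerical artifact.

### Image formation

Transmitted-light frames follow the Beer–Lambert law per pixel:
`IT = I0 · exp(−a·k)` with `k` the projected cell count in the pixel
column and `a` a single lumped attenuation per cell (attenuation
coefficient × path length; it is never measured separately, so it is
one parameter). PSF blur, Gaussian or Poisson noise, and bit-depth
quantization are applied in that order. Rasterization is a histogram of
positions, so the total projected count equals the number of cells in
every frame.

The growing-stripe generator produces the canonical pattern-formation
time series: uniform frames before an onset time, then a sinusoidal
modulation of amplitude `A0·e^(ω(t−ton))` saturating at a plateau.
Defaults are the observed values of a convecting suspension — λ =
1.7 mm, ω = 0.04 s⁻¹, ton = 220 s — on a 12.8 mm field at 100 µm/px,
2 s frames, 16-bit, noise σ = 2 counts. `A0` defaults to 2% so the
pattern is detectable from its first frame: for exponential growth from
a sub-noise amplitude, any detector necessarily reports the later
noise-crossing time rather than the programmed onset, so a fixture that
wants the programmed onset to be the measurable onset must start above
the noise floor.

## 2. Pattern spectroscopy

Each frame is mean-subtracted, multiplied by a Hamming window (to limit
spectral leakage of the non-periodic field of view), Fourier
transformed, and normalized by the scalar window gain ΣH. The window
normalization is a scalar, not a pointwise division by the window's
transform: pointwise division is singular away from DC and the peak
location is unaffected. Mean subtraction matters in practice: the DC
pedestal (incident intensity ~10³ counts) otherwise leaks through the
window sidelobes (−42 dB) into the low-q bins at an amplitude well above
the noise floor, producing spurious low-q "patterns" in homogeneous
stacks and biasing onset detection late.

Top-view data use the azimuthally averaged 2D spectrum `S(q, t)`;
side-view data are first averaged over depth into a 1D lateral signal.
Wavenumbers are cycles per length, so the pattern wavelength is
`λ = 1/qmax` identically. The peak search band excludes
`q < 2/(image width)` (window leakage) and `q > Nyquist/2`; a peak must
exceed 4× the in-band median to count as a pattern, otherwise the stack
is classified homogeneous.

Dynamics: `Smax(t)` is the in-band spectral maximum. Onset is the first
time `Smax` exceeds (baseline mean + 5·SD) for 5 consecutive frames
(baseline = first 10 frames; all three constants configurable — no
standard rule exists). The growth rate is the least-squares slope of
`log Smax` from onset to the first crossing of half the final plateau,
which confines the fit to the exponential regime before nonlinear
saturation. Round trips on the stripe fixture recover λ within one
q-bin, ω within 10%, and onset within two frame intervals.

## 3. Densitometry

With a constant incident intensity over the analysis region, the
relative cell density in attenuation units is

    (n − n0)/α = ⟨log IT⟩ − log IT,

which needs neither `I0` nor `α`, is exactly zero-mean over the mask,
and is invariant under any global intensity rescaling (both properties
are tested exactly). Natural logarithms are used; `α` absorbs the base.
Pixels quantized to zero are clipped to 0.5 counts with a warning
rather than discarded. No scattering correction is applied, so dense
regions are systematically underestimated — accepted as a property of
the method. Vertical profiles are row means over mask and frames, with
z measured upward from the compartment bottom; the sedimentation length
is a nonlinear exponential fit on the reconstructed density
`n0 + α·value` (with `α` treated as unit), returning the length and R².
A flat profile returns an infinite-length marker; a non-monotone one is
fitted anyway with R² as the quality flag.

## 4. Motility measurement

Cells are detected by the circular Hough transform over radii
2.6–5.5 µm (edge map from a Canny filter, non-maximum suppression,
normalized accumulator threshold 0.35). Detections are linked
frame-to-frame by the Hungarian assignment minimizing total
displacement with a hard 7 µm per-link cap — the cap, not any speed
estimate, is authoritative; links beyond it end the track and unmatched
detections start new ones. Hungarian assignment was chosen over greedy
nearest-neighbor for determinism; both satisfy the same contract.

The velocity autocorrelation pools the dot products of frame-to-frame
velocities over all cells *and all time origins within each track*
(sample-weighted): the process is stationary, and origin-pooling only
reduces variance relative to averaging over cells at a single origin.
The computation is FFT-based (O(T log T) per track), and `Cv(0)` equals
the mean squared speed of all velocity samples by construction. The fit
`Cv = v² e^(−t/τc)` uses lags up to 3× an initial τc guess from the 1/e
crossing, uniform weights. The diffusion constant is reported two ways
— the closed form `v²τc/2` (2D) and the Green–Kubo trapezoid of the
measured Cv — with a flag when they disagree by more than 10%. Across a
3×3 grid of (u, τc) at 1500 tracks × 60 s, recovery bias is <5% in
speed and <15% in correlation time.

## 5. Cell-flow velocimetry

PIV uses the swimming cells as tracer texture, so it measures the cell
flow (fluid flow + mean swimming drift), not the pure fluid velocity.
Frames can be preprocessed with CLAHE on 1.5 mm tiles. The correlator
is multi-pass FFT cross-correlation with progressive window refinement
(0.24, 0.19, 0.15 mm; steps 0.12, 0.10, 0.07 mm — the third step is
read as 0.07 mm, since a step larger than its window cannot tile),
integer window offsetting between passes, a three-point Gaussian
subpixel fit, and local-median replacement of low peak-ratio vectors.

A final refinement pass then re-extracts each interrogation window in
frame B with an 8 px margin at the rounded integer offset, Fourier-shifts
it by the fractional remainder, crops, and measures the residual by
upsampled-DFT cross-correlation, iterating to a fixed point. This is
first-order (uniform per-window) deformation, and it exists because
integer-only offsetting provably cannot meet a 0.1 px contract: edge
truncation of the windows pulls the measured subpixel displacement
toward zero by ~18% of the residual for 24 px windows (worse for
smaller windows), i.e. up to ~0.1 px at a half-pixel displacement. At
the fixed point the windows are aligned and the bias vanishes; the
synthetic-shift test recovers a (3.0, −1.5) px displacement to better
than 0.05 px in the mean.

The density–velocity coupling pools co-located samples of vertical cell
flow and relative density over frames and bins them by density. The
caption bin width of 0.5 is kept as the default for fidelity even
though it is coarse relative to the observed density range (±0.4);
resolved curves use 0.05. Empty bins report NaN and zero counts, never
synthetic zeros, and the curve is invariant to frame ordering. In
saturated plume states the coupling is negative — gyrotaxis focuses
cells into downwelling flow — and the tests verify both the pooled
correlation and the binned slope signs.

## 6. Continuum theory

Nondimensionalizing the standard gyrotactic continuum model (Boussinesq
momentum with cell buoyancy `−n vc (Δρ/ρ) g ẑ`, cell conservation with
advection + directed swimming + diffusion, quasi-static orientation)
by depth `h`, time `h²/D` and mean density `n0` yields

    R  = g φ (Δρ/ρ) h³ / (ν D)     (Rayleigh number)
    w  = v h / D                    (scaled swimming speed)
    G  = B D / h²                   (gyrotaxis number)
    Sc = ν / D                      (Schmidt number)

For the printed 3D-experiment parameters (g = 9.8 m/s², φ = 0.021,
Δρ/ρ = 0.05, h = 1 mm, ν = 1e-6 m²/s, D = 1.6e4 µm²/s) R evaluates to
643 → 640 at two significant figures. The printed speed range
5.8–11.5 for w is reproduced exactly with the 2 mm quasi-2D height
(46·2000/1.6e4 = 5.75, 92·2000/1.6e4 = 11.5); the 2 mm attribution is
documented here rather than assumed silently elsewhere. B is unknown
for these cells; the default 3 s used in stability computations is an
arbitrary literature-scale placeholder and is flagged as such.

The base state is the mean-normalized inverse sedimentation profile
`n̄(z) = w e^(wz)/(e^w − 1)`.

### Linear stability

Normal modes `∝ e^(iqx+σt)` about the base state give a generalized
eigenproblem in the stream-function amplitude Φ and cell amplitude N,
with no-slip walls (Φ = Φ' = 0) and zero perturbation cell flux
(wN = N'). Discretization is second-order finite differences on a
uniform vertical grid (default 96 intervals) with boundary-row (tau)
treatment for the flow block. The cell block is solved in symmetrized
form `N = e^(wz/2) M`, which turns the advection–diffusion operator
into the self-adjoint `∂²_z − w²/4` with Robin walls closed by
ghost-point elimination. This matters: the plain non-normal form
develops spurious *unstable* discrete modes on steep base states
(w ≳ 8) at practical resolutions, which corrupt every threshold
computed from it; the symmetrized form is clean at 96 points (the
leading cell mode at R = 0 correctly tends to the near-neutral
horizontal redistribution mode, σ → −q²). Interface wavenumbers are
cycles/mm (λ = 1/q, matching the spectral module); steep profiles need
~16 grid points per unit of w.

The critical Rayleigh number bisects R (relative tolerance 1e-3) at
each wavenumber of a log-spaced scan band (default 0.1–20 cycles/mm)
and minimizes over the band; an undestabilizable band returns the
explicit stable marker `(inf, nan)`.

Verified properties: R = 0 decays at all q; destabilization is
monotone in R (bisection well-posed); the reported critical point is
neutral to tolerance; Rc increases monotonically with w over the
experimentally relevant range w = 5.75–11.5; and the linear growth
rate's sign agrees with the nonlinear solver on seeded single modes.
At R ≈ 10·Rc and w = 5.75 the fastest-growing wavelength is ≈ 0.57·h
— ~1.1 mm for the 2 mm chamber, which is the observed side-view
pattern scale.

Two frequently quoted asymptotic statements are *not* properties of
this finite-depth, mean-normalized model, and the package does not
reproduce them: (i) the deep-layer scaling Rc ∝ w⁴ — converged
min-over-q thresholds here grow far more slowly (doubling w multiplies
Rc by ~1.3–3.6 depending on regime, bracketed by the sublayer argument
Rc ∝ w² and a nearly w-independent long-wavelength
column-redistribution branch); and (ii) near-w-independence of the
fastest-growing wavelength at fixed R (here it shortens roughly with
the sublayer scale as w grows). Both originate in the cited literature
under different normalizations/limits. The closed-form reduction
factor `(w_high/w_low)⁴ = 15.5 → 15`, which is how the light-switching
argument is actually used, is implemented as stated.

### Nonlinear solver

The 2D solver advances cell density on a uniform grid (periodic
laterally, no-flux walls) with a conservative finite-volume update:
upwind advective fluxes for `n(u + w p)`, central diffusive fluxes,
zero wall flux — total cell number is conserved to machine precision
by construction. Orientation is the quasi-static gyrotactic
equilibrium `px = clip(G ω, ±1)`. Momentum uses the quasi-static
large-Schmidt Stokes limit: each step solves `Δ²ψ = −R ∂n/∂x` with
no-slip walls (spectral in x, dense solve in z, precomputed
factorizations). At Sc ≈ 60 the viscous relaxation time is far below
any transport time, and retaining explicit vorticity dynamics with
Thom wall values is numerically unstable unless dt ≲ dz²/Sc — two
orders of magnitude below the transport-stability step — for no
physical gain; inertia is retained in the eigensolver, where the
cross-check against this solver runs. Default dt is 0.2·dz²
(diffusion-limited); blow-up (NaN or |n| > 1e6) aborts with a
diagnostic pointing at dt/grid. Subcritical runs decay monotonically;
supercritical runs form laterally patterned, temporally stationary
plumes with the gyrotactic vz–density anticorrelation.

## 7. Pipeline and reproducibility

The pipeline executes configured stages in the order simulate → render
→ spectrum/density/motility/piv → theory, hands artifacts between
stages, and writes standard formats (trajectory CSV, multi-page TIFF
with JSON sidecar, metric records). A single global seed expands to
per-stage seeds as `(seed·100003 + stage index) mod 2³¹`. The manifest
records parameter hashes, seeds and headline metrics and contains no
timestamps, so identical configs produce identical manifests. Units
are µm/s/counts internally; the config boundary uses explicitly
suffixed field names (µm, mm, SI).

## 8. Problem sizes and what the tests show

The synthetic round trips run at deliberately chosen sizes: motility
recoveries at 1500 cells × 60 s × 30 fps (the scale of one biological
replicate), spectral fixtures at 128² px × 300 frames, continuum runs
at 48² grids for a few hundred seconds of physical time, stability
scans at 96–144 vertical points. These reproduce the study's derived
quantities from data with known ground truth; they validate the
estimators and the theory implementation, not the biology. What passing
tests do *not* show: real images have nonuniform illumination, optical
aberrations, cell-size dispersity and scattering; real cells have
density-dependent motility, cell–cell hydrodynamic interactions
(declared but unspecified in the underlying model, and out of scope
here), and photo-responses with their own dynamics. The generator's
statistical structure (exponential VACF, Beer–Lambert attenuation,
exponential pattern growth) is the analysis chain's own model of the
data — the round trips are consistency checks of exactly that model.

## 9. Known limitations

- B is unknown; every quantity that needs G inherits that uncertainty.
- The quasi-static orientation closure drops tumble-induced
  reorientation and the finite orientation relaxation time.
- `v` and `D` are treated as density-independent in the continuum
  model.
- The Beer–Lambert inversion saturates in dense plumes (no scattering
  model), biasing (n−n0)/α low exactly where plumes are densest.
- PIV measures cell flow; decomposing it into fluid flow and swimming
  drift is not attempted.
- The 2D nonlinear solver is first-order upwind in the advective cell
  flux: robust and conservative, but numerically diffusive near sharp
  plume boundaries.
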