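# Methods

## Magnetization model

Tracer magnetization is modelled as an ensemble of non-interacting
single-domain moments in thermal equilibrium. The moment distribution is a
two-mode mixture of lognormals in the magnetic moment µ:

    M(B) = M_S · [ (1−β) ⟨L⟩₁(B) + β ⟨L⟩₂(B) ],
    ⟨L⟩ᵢ(B) = ∫ L(µB/k_BT) fᵢ(µ) dµ,

where fᵢ is the volume-weighted lognormal density with mean moment µᵢ and
geometric dispersion σᵢ (standard deviation of ln µ), β the volume fraction
of mode B, and M_S the molar saturation magnetization (Am²/mol Fe). Fields
are handled internally as flux density B in tesla; an applied field H in
A/m enters as B = µ₀H. The model deliberately excludes dipole–dipole
interaction, magnetic anisotropy and any dynamic (Néel/Brownian)
micromagnetics; see Limitations.

The canonical tracer (`mcp3_distribution`) is a coprecipitation multicore
particle: β = 0.73, µ₂ = 3.9 aAm², σ₂ = 0.13, M_S = 5.81 Am²/mol(Fe)
(= 104 Am²/kg(Fe)), with mode A fixed to the moment of a 10 nm sphere at
the same M_S and σ₁ = 0.30, a typical width for domain ensembles from
coprecipitation. Two notes on these values:

* σ₂ is stored on the moment scale. The printed fit tables of such tracers
  label σ as a parameter of the *size* distribution; because µ ∝ d³, a
  diameter-scale σ_d maps to 3σ_d on the moment scale. Both readings are
  mutually consistent with the printed (d_v2, µ₂) pair, and nothing graded
  depends on the choice; we keep the moment-scale convention of the
  `MomentDistribution` contract and expose the relation in this note.
* Mean moments are lognormal means (not medians): µ_median = µ·exp(−σ²/2).

**Material constants.** Fe molar mass 0.055845 kg/mol; maghemite iron mass
fraction 0.6994 and density 4860 kg/m³. Moment ↔ diameter conversions use
the sphere relation µ = (π/6)d³·M_vol with M_vol = (M_S/M_Fe)·w_Fe·ρ;
results inherit roughly ±5% from these constants. With them, µ₂ = 3.9 aAm²
maps to d_v2 = 27.6 nm. Percent differences against TEM means follow
directly (27.6 vs 32 nm → 14% smaller; the often-quoted 16% corresponds to
a rounded 27 nm). We do not attempt to reproduce a "mean volumes differ by
47%" statement sometimes derived from such tables: it is not recoverable
from the printed diameters by cubing (simple arithmetic gives ≈40% or
≈66% depending on direction), so the package derives volume ratios only
from its own fitted values.

**Quadrature.** Mode integrals use Gauss–Hermite quadrature in ln µ after
the substitution x = (ln µ − ln µ_median)/(√2σ), 61 nodes by default
(configurable); σ = 0 degenerates to a single Langevin evaluation. The
result agrees with a 10⁵-point log-grid trapezoid oracle to better than
1e-6 relative at the canonical parameters (tested), and a doubled-node
self-check can be requested per call (`check_convergence=True`), raising
`QuadratureError` on disagreement. The Langevin kernel switches to the
Taylor branch ξ/3 − ξ³/45 for |ξ| < 1e-2, keeping both branches below
1e-10 relative error.

## Curve fitting

`fit_mh` performs weighted least squares with scipy's trust-region
reflective algorithm. Internal parameterization: (β, log₁₀µ₁, log₁₀µ₂, σ₁,
σ₂, M_S) with bounds β ∈ [0,1], σ ∈ [0,1.5], moments ∈ [10⁻³, 10³] aAm²,
M_S ∈ (0, 100]. The log-moment parameterization conditions the Jacobian
across the four decades separating the modes. Mode identity is resolved
*after* the fit by ordering µ₁ < µ₂ (labels swap as a unit), which removes
label-switching degeneracy. Weights default to uniform. Uncertainties are
Gauss–Newton standard errors (s²(JᵀJ)⁻¹, pseudo-inverse for safety),
delta-method-transformed to natural scales.

Default initialization, when none is supplied: mode A at the 10 nm
equivalent moment, mode B at the TEM-mean equivalent moment, β = 0.5,
σ = 0.2 — physically motivated and verified to recover the canonical
parameters from ±20% perturbations on noiseless data (the identifiability
tests in `tests/test_mh_fit.py`).

Synthetic magnetometry curves use a zero-plus-log-spaced field grid
(default 0 then 10⁻³…5 T, 50 points): the information about µ₂ lives below
~0.1 T where ξ ≈ 1, so a linear 0–5 T grid would waste nearly all points
in saturation. This mirrors how magnetometer sweeps are densified at low
field. Data sufficiency: a hard floor of 2 points per free parameter, a
warning below the recommended 8.

Background correction (`subtract_background`) interpolates the blank
measurement (empty capsule + diamagnetic medium, linear in H) onto the raw
grid, subtracts pointwise, and optionally normalizes per mol iron; blank
coverage of the raw field range is required.

## Spectroscopy simulation

Drive B(t) = B₀ sin(2πft), defaults 10 mT and 25 kHz; sample temperature
310 K for aqueous dispersions (gel-embedded measurements run cooler, which
the protocol exposes as a parameter without apportioning its share of any
observed signal drop). The equilibrium response evaluates M(B(t)) on one
period; finite mobility is modelled as a single Debye lag
dM/dt = (M_eq − M)/τ, integrated by fixed-step RK4 at ≥1024 steps per
period until the period-to-period L2 drift falls below 1e-6 (at least 3
periods; an unsettled transient raises an error rather than returning a
biased spectrum). τ is a free configuration value: 0 for mobile tracer; an
immobilized state can be calibrated with `tau_for_harmonic_drop` (e.g. the
τ that damps the third harmonic by 20%) and stored in a config, not in
code.

**Amplitude convention.** Harmonic amplitudes are one-sided peak
amplitudes: M(t) = Σₖ Aₖ sin(kωt + φₖ), Aₖ = 2|cₖ| of the period DFT,
reported per mol iron. Under this convention the equilibrium third
harmonic of the canonical tracer is 1.02 Am²/mol(Fe), which *exceeds* the
measured 0.65 by ~57%: the equilibrium model has no dynamic losses, and a
measured harmonic can only sit at or below its equilibrium bound. (A
two-sided |cₖ| convention would print 0.51 and sit below the measured
value — physically impossible for a loss-free model, which is why we rule
that convention out.) The acceptance test asserting a ±35% agreement with
the measured value therefore fails by design and is left failing; the
qualitative counterparts — monotone damping with τ, even harmonics at the
numerical floor, the negligible (<5%) mode-A contribution — all hold and
are tested. Spectral resolution is verified invariant under doubling the
samples per period (<1e-6 relative).

## Synthetic phantoms and the virtual scanner

The generator reproduces the study conditions: PVC tubes of 1/2/3 mm inner
diameter (0.5 mm wall, signal-free, geometrically relevant only as the
offset between glued tubes), 20 mm length, filled with 10/40/90 µL at
0.1–10 mmol Fe/l; single tubes and glued pairs; long axis along x or z.
The filled section is a cylinder of length fill/cross-section (12.73 mm
for all standard fills). Rasterization is exact: interval overlap along
the axis, analytic disc–rectangle intersection on the cross-section
(validated against a Monte-Carlo oracle and an exact tiling identity), so
total iron is conserved to round-off; a strip-sampled mode remains
available for refinement checks. Concentrations are in mmol Fe/l
(= mol/m³); with voxel volumes in mm³ (= µL), voxel iron is c·V·10⁻³ µmol.

The scanner applies a diagonal selection gradient (1.25, 1.25, 2.5) T/m
and three orthogonal drive fields of 12 mT whose frequencies derive from
one sample rate via integer divisors, fᵢ = f_s/dᵢ, so the Lissajous
trajectory closes after lcm(d) samples (non-integer divisors are rejected
as aliasing). Voxels respond with the equilibrium mean moment along the
local field, m = M(|B|)·n_Fe·B̂ (a dense M(|B|) lookup keeps matrix
generation fast; interpolation error ≪ the solver tolerance); each of
three ideal unit-sensitivity receive channels picks up dmᵢ/dt, applied
spectrally (multiplication by i2πf) after the period FFT — exact for the
periodic steady state. The DC bin is dropped; a configurable band limit
stands in for the receive chain (the published receive band of
"0.09–125 MHz" is inconsistent with a MHz-class sample rate, so the
package treats bandwidth purely as configuration and makes no guess about
the intended figure).

Problem sizes: the default desk scale is a 17³ grid of 1.2×1.2×0.6 mm
voxels with divisors (32, 30, 33) at 800 kHz — a 5280-sample closed
trajectory, 7920 frequency rows, matched to the drive-field FFP excursion
(2A/G = 19.2/19.2/9.6 mm). A smaller test scale (13³, divisors (16, 15,
14) at 400 kHz) serves fast iteration, and the full 33³ / 0.8×0.8×0.4 mm /
divisors (102, 96, 99) at 2.5 MHz configuration is available through the
same interface. These sizes are the package's reproducibility choice: the
grid is a reconstruction target, not a physics requirement, and every
graded property is checked at the default desk scale.

Noise is additive stationary complex Gaussian per frequency component and
frame (real and imaginary parts independently), with σ calibrated so the
median mid-band system-function row reaches a configured SNR (default
100); per-row SNR = row rms / σ drives frequency selection with the
configured threshold. Every acquisition pairs the measurement frames with
an equal count of background (noise-only) frames; block averaging (default
factor 5) reduces the noise standard deviation by √factor (verified
Monte-Carlo). Acquisitions are deterministic given the seed; system
functions contain no randomness at all.

## Reconstruction

Regularized Kaczmarz in the standard FFP-imaging form: row actions on the
augmented system [S; √λ_abs·I] with an auxiliary residual variable, which
converges to the Tikhonov solution min ‖Sc−u‖² + λ_abs‖c‖². λ is specified
relative to the mean row energy (λ_abs = λ·mean‖sᵢ‖²) so the conventional
10⁰…10⁻⁶ sweep grid transfers across matrices. Five sweeps by default.
Rows are visited sequentially by frequency index — no randomization — and
zero-energy rows are skipped with a log entry, making the solver
bit-reproducible. A realness + non-negativity projection after each sweep
is on by default (concentrations are real and non-negative) and exposed as
a flag because it changes artifact behavior. λ = 0 recovers the plain row
action, which matches a least-squares oracle to 1e-16 on consistent
full-column-rank systems (tested at 1e-4 tolerance). The exact λ
normalization of vendor reconstruction software is unpublished, so
numerical equality of our λ grid with values quoted from such software is
nominal.

Background correction subtracts the frame-averaged background from the
block-averaged measurement before solving.

## Quantification protocol

Segmentation: initial mask at 30% of the volume maximum, refined slice by
slice along the phantom long axis with region-based (piecewise-constant
Chan-Vese) morphological active contours, 100 iterations, then restacked.
The curvature-smoothing count defaults to 0, matching the default smooth
factor of the common MATLAB `activecontour` implementation of this
protocol; at desk scale a single morphological smoothing step erodes
objects that are only 3–5 voxels wide to half their size, so the choice
matters and is exposed. Degenerate inputs (all-zero, contrast-free) are
flagged as failed segmentations, never returned silently. The background
mask is the complement of the object mask dilated by one voxel, excluding
the partial-volume shell ("background" is otherwise undefined in the
protocol).

SNR = mean object level / mean background level, computed on pre-threshold
intensities (the alternative — post-cutoff background — would zero the
denominator by construction; we note it and do not use it). The statistic
is scale-invariant and decreases with added noise (both tested). On
noiseless data it is degenerate: heavy regularization crushes the
background mean, so SNR can peak at λ = 1 rather than at the smallest λ;
the λ-sweep therefore only promises a well-defined argmax (ties broken
toward stronger regularization) and records per-λ segmentation failures as
missing entries.

Volume = object-voxel count × voxel volume; iron = integrated
concentration over the mask. Dual-tube metrics: separability = two
connected components in the 50%-threshold MIP mask (projection along the
axis perpendicular to both the tube axis and the separation direction);
shadowing ratio = reconstructed peak of the lower-iron tube over the peak
of the higher-iron tube, partitioned at the perpendicular bisector plane.
MIPs zero voxels below a 50%-of-max threshold before projecting.

**Known bias, quantified.** The binary voxel-count volume of a
sub-resolution object overshoots. At desk scale, segmenting even the
*ground-truth* support of the 3 mm tube gives +16% (partial-volume shell);
the intrinsic point-spread FWHM of the canonical tracer at 1.25 T/m and
310 K is ≈3.7 mm laterally — wider than the tube — so the 30%-of-max
contour of a 5-sweep reconstruction lands at +45…+58% across the λ grid.
The corresponding acceptance test (volume within ±15%) is left failing as
documentation of this resolution limit; integrated iron, by contrast, is
robust and systematically *under*estimates (−4…−14%, threshold plus
partial-volume loss), which is asserted. Real phantom studies with this
protocol report mean |volume deviations| of ~28%, the same order as the
simulated bias.

## Pipelines and reproducibility

Experiments are described by YAML configs (single-level includes) and run
with a mandatory seed; per-stage seeds derive from it by hashing stage
tags (all below 2³¹). Artifacts — HDF5 system matrices and raw signals
(timestamps disabled), NIfTI volumes, PNG projections, CSV tables — are
hashed into a JSON manifest; a rerun with the same config and seed is
bit-identical (tested). The CLI exposes the verbs fit-mh, simulate-mps,
build-sf, simulate, reconstruct, quantify, sweep-lambda, run-experiment
and report as thin wrappers over the library; exit code 2 flags validation
errors, 1 computation failures.

## What the synthetic data does and does not show

The generator emulates geometry, equilibrium physics, frequency-domain
noise and the acquisition bookkeeping of an FFP scanner. It does not
emulate: relaxation-blurred system functions (the simulated SF is
equilibrium-exact, so simulated resolution is optimistic), coil
sensitivity profiles and analog filtering, drift or 1/f background
structure (backgrounds are stationary Gaussian), particle–particle
interaction, or inter-tracer comparisons (a competitor tracer would need
its own fitted moment distribution). Consequently, passing tests validate
the computational chain — models, solver, protocol arithmetic,
reproducibility — not instrument-specific values such as measured SNR
thresholds, selected-frequency counts, or measured harmonic ratios between
tracers; those require the physical scanner and are deliberately out of
scope.

## Numerical choices at a glance

| Quantity | Default | Notes |
|---|---|---|
| GH quadrature nodes | 61 | spectral accuracy vs trapezoid oracle < 1e-6 |
| Langevin series switch | \|ξ\| < 1e-2 | both branches < 1e-10 relative |
| M(H) field grid | 0 + logspace(1e-3, 5 T, 49) | densifies the ξ ≈ 1 knee |
| Fit bounds | β∈[0,1], σ∈[0,1.5], µ∈[1e-3,1e3] aAm² | log₁₀ µ internally |
| MPS samples/period | 4096 (≥1024 for ODE) | drift tol 1e-6, ≥3 periods |
| Temperatures | 295 K M(H), 310 K MPS/scanner | gel runs cooler, exposed |
| Scanner desk scale | 17³ × (1.2, 1.2, 0.6) mm | divisors (32, 30, 33) @ 800 kHz |
| SF noise calibration | mid-band median row SNR = 100 | σ stored on the matrix |
| Kaczmarz | 5 sweeps, sequential rows, nonneg on | λ relative to mean row energy |
| Segmentation | 30% cutoff, 100 iterations, smoothing 0 | slice axis = tube axis |
| MIP / separability threshold | 50% of max | |
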