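# Methods

`rhizoseit` images plant root systems in a thin, water-filled rhizotron
(52 cm x 52 cm x 2.5 cm, 36 Ag/AgCl electrodes) with spectral electrical
impedance tomography (sEIT) and converts the recovered polarization images
into root traits. This note records the models, the tunable parameters and
the numerical choices, including the places where the design was genuinely
open and the package had to commit to one option.

## Forward model

The tank is thin compared to its face, so the complex potential u* of an
injected AC current is modelled in 2D with thickness-scaled conductance:

    div( sigma* t grad u* ) = -I* [ delta(x_A) - delta(x_B) ],

with insulating outer boundaries, complex conductivity sigma* = sigma' +
i sigma'' (S/m), tank thickness t = 0.025 m and unit current I* = 1 A, so the
voltage across a potential dipole M,N equals the transfer impedance
Z* = u*(M) - u*(N). Discretization is linear (P1) triangles on a structured,
graded tensor-product mesh whose node set contains every electrode position
exactly; electrodes are points (the 0.5 cm physical wire protrusion is
ignored, standard at this scale). The pure-Neumann nullspace is fixed by a
zero-mean gauge (Lagrange multiplier), which also makes single-electrode
(pole) solves admissible: dipole fields are differences of pole fields, so
one sparse LU factorisation per conductivity model serves all injections.

Apparent complex resistivity is rho_a* = K Z* with the geometric factor K
computed numerically from a homogeneous reference solve (no half-space
formula applies in a closed tank); by construction rho_a* equals the true
resistivity exactly on the homogeneous model, and K is independent of the
reference value. Quadrupoles are canonically oriented (M,N swapped where
needed) so K > 0 and apparent phases of weakly polarizable media stay near
zero.

Sensitivities d ln rho_a / d ln rho_cell are computed by the adjoint method:
for P1 elements the row entry is sigma_c t A_c (grad u_AB . grad u_MN) / Z.
On a homogeneous model each row sums to 1 (degree-1 homogeneity), a property
the tests exploit.

Accuracy: against a truncated cosine-series solution of the Neumann problem,
potential differences agree to < 0.5% on a refined mesh. Note that the
*max-norm* difference between a dataset and its recomputation on a 1-to-4
subdivided mesh converges slowly (point-electrode singularities); bulk
agreement (95th percentile) is at the 0.2 mrad / 0.5% level on ~5k cells.

## Survey design

The measurement scheme is built greedily to maximise the spatially weighted
sum of the model-resolution-matrix diagonal,

    R = (J^T Wd^2 J + lambda Wm^T Wm)^{-1} J^T Wd^2 J,

with J the log-log Jacobian of the selected configurations on the
homogeneous water background, Wd data weights from the error model, Wm a
first-order (edge-difference) smoothness operator, and per-cell weights 1
inside the expected rooting zone (x 0.085-0.435 m, y 0.125-0.425 m) and 0.1
outside. Only the real part is used: expected phases are tens of mrad, so
real and imaginary sensitivity patterns are nearly proportional. Marginal
gains of every candidate are exact rank-one (Sherman-Morrison) updates,
evaluated in batch; ties break lexicographically in (A,B,M,N). The injection
budget (default 40 dipoles, matching a ~1 h acquisition) is enforced
greedily; the default target is 800 configurations.

Open choices the package had to make:

- **Candidate pool.** All reciprocal-unique quadrupoles whose electrode-index
  separations |A-B|, |M-N| lie in {1,2,3,5,8,13,21} (a ladder mixing short
  and long dipoles), then two hygiene filters: configurations that are
  near-null on the background (|Z_hom| < 5% of the pool median) or whose
  sensitivity row has L1 norm > 5 are dropped. Without the filters the
  greedy concentrates on voltage-null, phase-amplifying configurations whose
  apparent phases leave the small-phase regime (up to ~3 rad for a -25 mrad
  anomaly) — unusable for any instrument or linearized phase inversion.
  The L1 cap directly bounds phase amplification: to first order the
  apparent phase is the sensitivity row dotted with the cell phases.
- **Design lambda.** Fixed at 0.01 x the trace heuristic
  trace(J^T Wd^2 J)/trace(Wm^T Wm) for a scheme of the target size — the
  level a discrepancy-converged inversion typically cools to. At the raw
  heuristic the weighted objective saturates after ~100 configurations and
  resolution diagonals leave [0,1]; at the cooled level the greedy stays
  monotone to 800 configurations and diag(R) stays in [0, ~0.45]. (Strict
  nonnegativity of diag(R) is not a theorem under smoothness regularization;
  per-mil negative excursions can appear at intermediate scheme sizes.)
- **Design mesh.** A coarse dedicated mesh (~700 cells). Resolution ranking
  only needs the coarse spatial structure of the sensitivities, and the
  greedy would be intractable at inversion-mesh size on one CPU.
- **Central batch.** The reduced-scheme comparison removes every
  configuration touching an interior (non-perimeter) electrode — all three
  interior columns, 12 electrodes. Removing only the middle column leaves
  the centre well covered and the comparison degenerates.

## Error model and noise

Impedance magnitude errors follow d|Z*| = a|Z*| + b (defaults a = 2%,
b = 0.01 Ohm for measured data; a = 1%, b = 0.001 Ohm in the synthetic
experiment) and phase errors are a constant c per frequency (0.5 mrad
synthetic). The same model generates synthetic Gaussian noise and weights
the inversion misfit. For measured data c is estimated as half the
population standard deviation of the phases at each frequency, floored at
0.1 mrad to avoid zero weights. The water-reference correction for measured
data multiplies each magnitude by (modelled homogeneous |Z|)/(measured
water |Z|) and subtracts the measured water phase — a per-configuration
ratio/subtraction reconstruction of the setup correction, confined to one
function so it can be swapped if the original recipe becomes available.

## Inversion

Each frequency is inverted independently, in two stages.

**Magnitude stage.** Damped Gauss-Newton on m = ln rho fitting ln|Z|, with
first-order smoothness and data weights 1/(a + b/|Z|). lambda starts at the
trace heuristic and is halved whenever a step stalls, until the
error-weighted RMS enters [0.9, 1.1] (discrepancy principle) or lambda
bottoms out; steps use a halving line search, at most 30 outer iterations.
The starting model is homogeneous at the *median* apparent resistivity
(robust to outlier configurations). Magnitude positivity comes free from
the log parameterization.

**Phase stage.** Phases are small (tens of mrad), so the cell-phase image
solves a regularized Gauss-Newton sequence about the converged magnitude
model, reusing the real Jacobian as the phase sensitivity but evaluating
predicted phases with full complex forward solves. The nonlinearity matters:
a single linearized step leaves a quadratic misfit of ~0.6 mrad for a
25 mrad anomaly — larger than the 0.5 mrad noise — which would drag the
discrepancy search into over-fitting and noisy backgrounds. The phase
regularization strength is chosen as the *largest* lambda whose converged
solution fits at RMS <= 1.1 (bracketed and bisected), i.e. the smoothest
admissible phase image.

The pooled error-weighted RMS (magnitude residuals over a|Z|+b, phase
residuals over c) is reported per inversion; on data whose noise matches the
error model it lands in [0.9, 1.1] by construction. Noise-ensemble averaging
is cell-wise: mean log-magnitude, mean phase.

## Debye decomposition

Per-cell spectra rho*(omega) from the per-frequency inversions are fitted
with a superposition of Debye terms on a fixed log-spaced relaxation-time
grid (20 points per decade spanning one decade beyond the band's relaxation
times, default band 0.79 Hz - 1 kHz):

    rho*(omega) = rho_0 ( 1 - sum_k m_k [ 1 - 1/(1 + i omega tau_k) ] ).

With c_k = rho_0 m_k the model is *linear* in (rho_0, c), so the fit is a
convex non-negative least-squares problem with first-difference smoothing
(strength 0.05 relative to the scaled data rows) on the c spectrum. This
replaces the more common log-parameterized nonlinear iteration: it is
deterministic, has no starting-model sensitivity, and is fast enough to
decompose every cell of an image stack. Noiseless on-grid round trips
recover m_tot within 1%, tau_mean within 5% (log scale) and rho_0 within
0.5%.

Integral parameters: total chargeability m_tot = sum m_k and mean log
relaxation time tau_mean = exp(sum m_k ln tau_k / sum m_k); cells with
m_tot < 1e-3 are classified as non-polarizable background. Relaxation times
map to polarization length scales via Stern-layer ion diffusion,
tau = r^2/(2D) with D = 1e-9 m^2/s, and to measurement frequency via
tau = 1/(2 pi f); the analysis band therefore probes 0.56-20.07 um, and a
0.5 mm structure would need f ~ 1.3 mHz (tau ~ 125 s).

## Root traits

Root zones are polygons traced on tank photographs (or explicit cell lists),
rasterized to cells by centroid inclusion, optionally partitioned into 10 cm
depth bands. The trait predictor is the volume-weighted mean chargeability
m_bar = sum V_k m_tot,k / sum V_k integrated over the zone,
m_rz = V_rz m_bar, reported in cm^3. Calibrated power laws (defaults
A_surf = 221 m_rz^0.93 cm^2, M_bio = 0.169 m_rz^0.94 g) convert m_rz to
traits; new calibrations are fitted by least squares in log10-log10 space,
with R^2 and PCC reported in log space (the relations are plotted and fitted
log-log; the original convention is unstated). tau_bar, the volume-weighted
mean of tau_mean, is exposed as the candidate predictor of the squared mean
root diameter.

Image quality: PCC on cell values; SSIM on 2 mm nearest-cell rasters with
scikit-image's standard constants and window and the joint dynamic range of
both images (the original SSIM settings are unpublished; these are recorded
here because SSIM is sensitive to them — see Limitations).

## Synthetic world

The generator states the conditions the analysis assumes; its defaults are
not tuned.

- Background: tap water, 105.1 uS/cm, purely real (no polarization).
- Phantom: a root-fan polygon hanging from the water line; root cells carry
  a Debye dispersion built from a log-normal m(tau) spectrum centred at
  tau = 3 ms (observed mean relaxation times lie within 1-12 ms and real
  root spectra show no pronounced single peak), scaled so the resistivity
  phase at 1 kHz equals -25 mrad (bracketing on the monotone phase-vs-scale
  relation); no DC-magnitude contrast by default, matching the observation
  that magnitude images show no root signature.
- Plant ensemble: 23 plants (7 maize, 7 black bean, 5 pinto bean, 4 soy
  bean), 13-73 days after sowing; surface areas log-uniform up to 2554 cm^2,
  biomass coupled near-linearly (10% residual scatter) up to ~2.15 g, mean
  diameters uniform in 0.3-0.5 mm; per-plant root-zone chargeability density
  from the *inverted* surface-area calibration with 20% multiplicative
  log-normal scatter, so recovery tests have known ground truth; per-plant
  tau centres log-uniform in 1-12 ms. All draws derive from one master seed
  (per-replicate child seeds via numpy SeedSequence).
- Scheme-comparison experiment: clean data simulated on a mesh distinct from
  the inversion mesh (~2.5k inversion cells — desk scale), 10 noise
  realizations per arm at (1%, 0.001 Ohm, 0.5 mrad), inversions with
  matching error estimates, cell-wise averaging, PCC/SSIM against the true
  phase image.

What the generator does **not** emulate: electrode polarization and contact
impedance, leakage currents, 3D current paths (the synthetic pipeline is
natively 2D, so the water-reference correction is exercised only by
construction), soil backgrounds, realistic branching root architecture, and
diurnal physiology. A green recovery test therefore establishes internal
consistency of design -> forward -> noise -> inversion -> decomposition ->
integration, not instrument fidelity.

## Known limitations

- **SSIM level.** Ensemble-averaged reconstructions reach PCC ~ 0.89-0.94
  but SSIM only ~ 0.3-0.4 against the piecewise-constant truth at the 2 mm
  raster/7-pixel window recorded above. The residual smoothing halo is the
  resolution limit of an 800-configuration, 40-dipole scheme on this
  reconstructed electrode geometry: even fitting clean data 25x below the
  noise floor saturates SSIM near 0.5. Published SSIM values for such
  experiments depend strongly on raster scale, window and data range, none
  of which are standardized; the optimized > reduced ordering is robust,
  the absolute SSIM level is not.
- The electrode layout is a parameterized reconstruction (perimeter ring +
  three interior columns); all downstream code consumes coordinates, so a
  surveyed layout can be substituted without code changes.
- The greedy design adds batches (default 25) between exact-gain
  re-evaluations; a batch that would decrease the objective falls back to
  the single best candidate, preserving monotonicity at some speed cost.
- Per-frequency inversions are independent (no spectral regularization), as
  in the reference workflow; time-lapse and 3D are out of scope.
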