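# Methods

This note documents the models, parameter choices, numerical schemes and
design decisions behind `ghostnav`, and what the synthetic-data tests do and
do not establish about real data.

## Signaling: the EGFR–phosphatase reaction–diffusion network

Four species live on a periodic 1-D membrane contour of length 2πR
(R = 2 µm, 20 equal bins): ligandless phosphorylated receptor `Ep`,
phosphorylated ligand-bound dimeric receptor `EEp`, active PTPRG `RGa`, and
active PTPN2 `N2a`. The kinetics are dimer-based — autonomous activation
scales with the square of the inactive receptor pool, ligand binding
consumes receptor pairs, and dissociation of a dimer returns half its
receptor content to `Ep`. PTPRG provides a double-negative feedback
(receptor inactivates the phosphatase that dephosphorylates it); PTPN2 a
slow negative feedback with timescale separation ε = 0.01, justified by the
~4 min receptor recycling time. Default rate constants (min⁻¹, concentrations
normalized to the PTPRG total): α1 = 0.001, α2 = 0.3, α3 = 0.7, β1 = 11,
β2 = 1.1, k1 = k2 = 0.5, γ1 = 1.9, γ2 = 0.1, k_on = 0.05, k_off = 0.28,
RGt = N2t = 1. Lateral diffusion D_Ep = D_RGa = 0.008 µm²/min; the liganded
dimer is immobile.

**Integration.** Explicit Euler–Maruyama at dt = 0.01 min with periodic
central-difference Laplacians. Additive white noise acts on the `Ep`
equation only, amplitude σ = 0.02 with standard Wiener increments
(variance dt); at dt = 0.01 this reproduces the quoted increment variance
while keeping the noise intensity dt-invariant. Spatial simulations use the
quasi-steady-state form of PTPN2,
N2a = N2t (k1 + β2 s)/(k1 + k2 + β2 s) with s = Ep + EEp; the full slow ODE
is available (`n2a_mode="full"`). The two agree exactly at fixed points and
to ~1–2 % RMS for near-stationary (basal, noise-driven) dynamics, but *not*
during strong stimulus transients, where the slow variable genuinely lags
its quasi-steady state by design — the QSS form is the modeling choice for
the spatial runs, not an approximation that is uniformly accurate.

**Ligand.** EGF enters bin-locally: the free ligand seen by a bin is
EGF_t(θ, t) − EEp(θ), modeling depletion of a low physiological dose by
binding. Gradients are wrapped Gaussians on the contour; amplitudes and
angular widths may follow linear-in-time schedules ("dynamic" gradients).
The standard gradient template (amplitude 0.1 in units of the PTPRG total,
angular s.d. 0.5 rad, centered at π, on for t ∈ [5, 65] min) was chosen once
as a sub-saturating dose that elicits the documented regime phenotypes; it
is configuration, not a fitted quantity.

**Conservation.** After every step species are clipped into their
conservation box (0 ≤ Ep + EEp ≤ Et, 0 ≤ RGa ≤ RGt, 0 ≤ N2a ≤ N2t) and clip
events are counted. Because basal Ep (~0.003) is far below the stationary
noise spread (~0.018), the basal state rides the zero bound and a fraction
of order 0.5–1 % of bin-updates clip; this is inherent to the printed noise
amplitude, not a numerical artifact, and the recorded clip fraction makes it
auditable.

**Receptor-abundance regimes.** With the standard gradient and fixed seeds,
total receptor Et ∈ {1.1, 1.26, 1.35, 1.85} produces: basal (no
post-washout polarization), criticality (transient memory, tens of
minutes), stable polarization (permanent memory), and pre-activation (high
uniform phosphorylation, no stimulus-locked polarization). The in-silico
polarization index p(t) = (max − min)/(mean + 10⁻⁶) is reported as defined,
but memory detection defaults to a threshold on the absolute spatial range
(max − min < 0.1 for 3 consecutive samples): at the basal state the
mean-normalized index is dominated by the noise floor (mean ~0.003 with
fluctuations ~0.018) and cannot separate noisy-basal from polarized.

**In-silico receptor inhibition.** Pharmacological receptor inhibition is
emulated by scaling the autocatalytic rate α2 by a factor (default 0.05)
from a chosen time onward, abolishing the memory phase.

## Bifurcation analysis

The front/back two-compartment projection replaces diffusion with linear
exchange (default scaled coefficients 0.02/0.02 for Ep and RGa) and keeps
the reaction terms with PTPN2 at QSS (fixed points coincide with the full-ε
ones). At a symmetric state the 4×4 Jacobian block-diagonalizes over even
and odd perturbations; the odd block is A − 2 diag(exchange), and its
determinant's zero crossing locates the pitchfork. The printed form of the
odd-mode reduction matrix in the source literature is typographically
corrupted, so the reduction is derived from the block symmetry directly and
verified against eigen-decomposition (zero eigenvalue with front = −back
eigenvector structure).

With the default parameters: the asymmetric (IHSS) branch is traced by
pseudo-arclength continuation (secant predictor, Newton corrector, step
2×10⁻³) from a relaxed asymmetric state; it is stable for
Et ∈ [1.2672, 1.3566] and attaches to the middle (saddle) homogeneous
branch at Et ≈ 1.212 and ≈ 2.096. The basal branch never loses stability
before it disappears in a fold near Et ≈ 2.1, so the pitchfork relevant to
the diagram's subcritical structure is the largest odd-mode crossing
(Et_PB ≈ 2.096); the SN_PB is the fold bounding the stable polarized window
from below, Et_SN ≈ 1.2672 — just above the criticality value 1.26, with
the stable-polarized value 1.35 inside the window. HSS–IHSS coexistence
below the PB makes it subcritical.

**Nondimensionalization and amplitude equation.** The two-variable
reduction uses the printed dimensionless groups (t0 = 1/(k1+k2),
E0 = k1/β2, RG0 = (k1+k2)/γ1, x0 = √(D_Ep t0)); the PTPN2 sink is
Taylor-expanded about the dimensionless operating point Es. The printed
formula for q1 is dimensionally inconsistent with these scalings; it is kept
as printed because it only enters the linear coefficient c1 (through
q9 = q1 − q7), not the subcriticality-deciding c2, c3. The Galerkin
expansion to third harmonics yields a quintic Stuart–Landau equation whose
closed-form coefficients require the higher harmonics to be damped:
q10 − (n k_m)² < 0 for n = 2, 3. Wavenumbers below √(q10)/2 ≈ 0.29 —
including the first ring mode of a 2-µm cell, k_m = x0/R ≈ 0.045 — lie in a
resonant band where the truncation is invalid, so the default is k_m = 1,
the intrinsic dimensionless diffusion length of the activator (subcriticality
c2 > 0, c3 > 0 holds robustly for k_m ≳ 0.5; k_m is overridable). The
amplitude-equation fold √(c2/(2c3)) agrees with the 4-ODE SN_PB only in
order of magnitude — the expansion is approximate and is used to certify the
*type* of bifurcation, not its position.

## Cell mechanics

The boundary is the zero level set of ψ on a Cartesian grid (5 points/µm;
negative inside), advected by the Hamilton–Jacobi equation with Godunov
upwinding (second-order ENO by default, first-order selectable) at
dt = 0.01 min. The cortex is a Voigt element (k_c = 0.1 nN/µm³,
τ_c = 0.08 nN·min/µm³) in series with a viscous cytoplasm
(τ_a = 0.1 nN·min/µm³); its elongation field l is transported with the
interface and relaxed locally, giving the normal velocity
v = −(k_c/τ_c) l + (1/τ_c + 1/τ_a) P_total. Velocities are evaluated in a
narrow band (6 cells) and extended off the interface by closest-point
interpolation; ψ is re-distanced every 50 steps by iterating the
reinitialization equation with a smoothed sign function (12 iterations),
which preserves the sub-cell interface position; the grid window recenters
itself when the migrating cell nears a border.

**Pressures.** With membrane mean m, maximum M of the per-sector activity:
protrusion K_prot (Ep − m)/(M − m) where Ep > m; retraction
−K_retr (m − Ep)/(M − m) where Ep < m; area restoration K_area (A(0) − A(t))
uniform; tension −K_ten (κ − 1/R). The trailing "n" of the printed pressure
laws is read as the outward normal vector (dimensional consistency), not an
exponent. Both protrusion and retraction are normalized by (M − m), the
literal printed denominator of the retraction law (up to its corrupted
sign): normalizing retraction instead by (m − min) pins the deepest noise
dip at full strength, over-retracts a migrating cell and breaks the model's
own 2-D area conservation (~11 % deficit); with the (M − m) normalization
the default runs conserve area to better than 5 % and the simulated
gradient-phase speed falls inside the experimental calibration band
0.49 ± 0.173 µm/min. Defaults: K_prot = 0.08, K_retr = 0.05 nN/µm²,
K_area = 0.02 nN/µm⁴, K_ten = 0.1 nN/µm.

The driving kymograph is interpolated linearly in time and mapped to the
grid by angle from the current centroid (20 sectors, lab frame); the
per-sector activity is smoothed with a 3-sector circular rolling mean before
pressure evaluation — cortical force generation is coherent over more than
one 18° sector, and unsmoothed independent per-bin noise couples into large
area fluctuations through the scale-free pressure normalization.

## Motility model and fitting

The velocity follows dv = −v/τ dt + (√(2D)/τ)(dW + b û dt) per Cartesian
component; this prefactor convention is the single reading compatible with
the linear MSD convention MSD → 4Dt (stationary speed variance D/τ per
component). The bias magnitude b is treated as dimensionless inside the
noise-scaled term; time-dependent bias b(t) is piecewise constant. Printed
reference sets: (τ = 11.105 min, D = 0.425 µm²/min) without stimulus,
(τ = 38.143, D = 2.207, b = 0.134) under uniform stimulation. Integration
refines the sampling interval internally (≥ 8 substeps, and below τ/20), at
which the discretization bias of recovered parameters is ≲ 1 %; positions
accumulate by trapezoidal integration, velocities start from the stationary
distribution.

**Fitting.** MSD is the ensemble average from track origins (no time
averaging) fitted linearly over lags [2 τ̂, T/4]; when persistence is long
relative to the record and that window holds fewer than 8 lags it moves to
[3 τ̂, 0.6 T], beyond the ballistic transient. VACF uses central-difference
velocities and a mono-exponential fit over the leading run of lags where
VACF > 0.05 VACF(0), *excluding lag 0*: finite differencing distorts the
zero-lag variance but leaves lags ≥ 1 exactly mono-exponential for an OU
process. Goodness is reported as R² (MSD) and the standard error of
estimate (VACF). At 300 tracks × 300 min recovery of the printed sets is
typically within a few percent (τ somewhat noisier than D).

## Quantification procedures

* **Kymographs**: per-bin ratio (PTB_i/(PTB_T − PTB_endo))/(EGFR_i/EGFR_T),
  then baseline-subtracted and scaled by the global maximum. The whole-
  membrane temporal profile normalizes the summed ratio to its 5-min
  pre-stimulus baseline (0) and overall maximum (1).
* **Activation classes**: the pre-activation GMM operates on the *raw*
  per-bin ratios — the per-cell normalization subtracts exactly the
  between-cell baseline differences it needs. Threshold = crossing of the
  two weighted component densities (midpoint-of-means fallback, flagged);
  a cell is pre-activated when strictly more than 30 % of its pre-stimulus
  bins exceed it; remaining cells split by a second GMM on their mean
  response over [0, 65] min.
* **Signaling memory**: fraction of bins above (mean + s.d.) of the
  normalized kymograph = FPA(t); memory ends when FPA stays at or below its
  own time-average minus s.d. (clamped at 0) for 3 consecutive samples.
* **Morphology memory**: threshold (mean − s.d.) of solidity during the
  gradient; the adopted reading of the ambiguous rule is "memory ends at
  the *last* post-washout time still below the threshold", which is robust
  to brief re-crossings during recovery. Solidity is computed from the
  smoothed-mask contour polygon (pixel-count solidity of a rasterized disc
  is biased low by ~5 % at a 20-px radius). Directed protrusion area splits
  mask differences front/back about the axis through the initial centroid
  perpendicular to the gradient, as A_front/A_front,tot − A_back/A_back,tot,
  Gaussian-smoothed in time; the ≥1.2 µm² threshold applies to
  experimental-style masks and is off for simulation masks.
* **Migration memory (ensemble)**: sliding 5-point windows of pooled cos θ
  compared against a no-stimulus reference by two-sided KS test; memory ends
  at the first post-washout window with p ≥ α (= 0.05, configurable) in 2
  consecutive windows; windows with < 20 samples widen symmetrically,
  flagged. Note the estimator measures when the *statistics* return to
  baseline: after a persistent-walk bias switches off, the OU velocity
  keeps the ensemble genuinely aligned for ~τ longer, and detection power
  grows with ensemble size; synthetic scoring therefore uses a memoryless
  post-bias phase so the constructed truth is sharp.
* **Per-cell migration memory**: constant-velocity Kalman (RTS) smoothing
  (process s.d. 0.1 µm/min², measurement s.d. 0.5 µm, both configurable),
  then the first post-washout run of 3 consecutive cos θ < 0.75.
* **Sigmoid fits**: f(t) = a0/(aⁿ + tⁿ) by bounded nonlinear least squares,
  optionally with a fixed; the half-decay time equals a identically
  (aⁿ + tⁿ = 2aⁿ ⇔ t = a), asserted as an invariant. The source data's
  free-a fits report a ~ 10 alongside ~30 min average half-lives; under
  this functional form half-life ≡ a, so that discrepancy reflects
  reporting across heterogeneous cells, and only the closed-form identity
  is asserted here.
* **Delay embedding**: Savitzky–Golay smoothing (window 11, order 3),
  delay from the first autocorrelation drop below 1/e (for a sinusoid this
  is analytically 0.19 of the period — slightly less than a quarter
  period), dimension from Kennel's false-nearest-neighbour criteria
  (ratio 15, loneliness 2, threshold 5 %, cap 5, cap flagged). Explicit
  settings override.
* **Gradient alignment**: wrapped-Gaussian fit to the 20-bin EGF
  projection; the reported angle is the circular bin distance between the
  EGF and EGFRp maxima × 2π/20 (circular perimeter assumption).

## Synthetic data

Generators are deterministic given their seed and ship their ground truth.
Fluorescence records invert the ratio definition exactly (zero-noise round
trips are exact to 10⁻⁹) and add multiplicative log-normal noise with a
constant 10 % endosomal reporter fraction; parametric kymographs carry a
signal-locked wrapped-Gaussian lobe with a configurable post-stimulus
plateau; mask series grow a narrow protrusion lobe (width 0.15 rad, length
2 µm) whose amplitude ramps over the gradient hour and persists for the
configured memory; track ensembles concatenate mOU phases with velocity
carried across switches. What these emulate is the *geometry* of the
measurements, not microscopy physics: no shot noise model, no segmentation
errors, no photobleaching, no cell-to-cell parameter heterogeneity beyond
seeds. Passing estimator-recovery tests therefore establishes correctness
of the procedures, not their robustness to every failure mode of live-cell
imaging.

## Problem sizes and reproducibility

Default analysis scales: stochastic membrane runs of 300 simulated minutes
at dt = 0.01; level-set runs of 35–65 simulated minutes on a moving-window
grid; motility ensembles of 300–3000 tracks × 300 min for fitting
(3000 in the acceptance script, which keeps the stochastic recovery error
of D and τ in the low percent range). One seed governs a run; per-module
sub-seeds are derived with fixed offsets so module order never changes
results. The CLI is a thin layer over the library; experiment presets write
a manifest (parameters, seed, version) that reproduces byte-for-byte on
deterministic paths.

## Known limitations

* 1-D membrane only; no receptor trafficking, no mechanochemical feedback
  from shape back to signaling; the mechanics has no substrate adhesion,
  cell–cell contact or explicit cytoskeletal fields.
* The two-compartment exchange rate (0.02) is a projection convention; the
  full 20-bin system's effective mode-1 coupling is weaker, so pinned
  polarized states in the PDE persist somewhat below the 2-compartment
  SN_PB and the memory duration at criticality depends on stimulus shape
  and noise realization.
* The weakly nonlinear analysis certifies subcriticality near the chosen
  wavenumber; it is not a quantitative predictor of the SN_PB position.
* Memory-duration rules inherit the published thresholds (3 consecutive
  samples, mean ± s.d., cos θ < 0.75); their per-cell values on noisy
  unpolarized records are waiting-time statistics and should be interpreted
  at the ensemble level.
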