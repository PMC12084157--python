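# Methods

This note documents the models, estimators and numerical choices behind
`activeflicker`, in the spirit of a simulation/analysis methods section:
what is computed, under which assumptions, with which defaults, and what
the synthetic tests do and do not establish about real recordings.

## Mode convention

All stages share one Fourier convention for the equatorial contour:

    R(φ, t) = R₀ (1 + Σ_{q≥1} [u_q(t) e^{iqφ} + c.c.]),
    u_q = (b_q − i a_q) / (2 R₀),

where a_q = (1/π)∮R sin(qφ)dφ and b_q = (1/π)∮R cos(qφ)dφ are computed
with the trapezoidal rule on the closed, uniform angular grid (360
samples, φ = 0 along +x, counterclockwise). Under this *half-amplitude*
convention the passive ring spectrum is

    ⟨|u_q|²⟩ = C (k_BT/κ) / (q³ + σ̄ q),   C = 1/2,   σ̄ = σR₀²/(κ k_BT),

and generation and fitting are exactly self-consistent: what the
parameter-recovery tests establish is this self-consistency, not an
absolute calibration of κ from real images. The printed half-amplitude
form is itself an approximation for equatorial cross-sections of a
fluctuating *sphere*; the exact result sums all spherical harmonics
l ≥ q on the equator,

    ⟨|u_q|²⟩ = Σ_{l≥max(q,2)} |Y_lq(π/2)|² / [κ (l−1)(l+2)(l(l+1)+σ̄)],

which preserves the q⁻³/q⁻¹ scalings but carries a ≈ 10× smaller
prefactor (`equatorial_power_quasispherical`). The 2D form is used for
the ring generators (self-consistent by construction); the exact 3D
form is the measurement model for the triangulated-vesicle simulator
(`fit_helfrich_equatorial`), where it recovers the input rigidity
within ~15% with no adjustable constant.

## Passive generator

Each mode is an independent stationary Ornstein–Uhlenbeck process with
the variance above and relaxation time

    τ_q = 4 η R₀³ / (κ_SI (q³ + σ̄ q)),

with η the effective solvent viscosity (default 10⁻³ Pa s). The
absolute prefactor of τ_q is a model choice (only the (q³+σ̄q)⁻¹
scaling is asserted against theory); η is exposed for rescaling. The
discrete update is the exact AR(1) kernel, initialised from the
stationary law, so there is no burn-in and the statistics are exact at
any step size; a guard refuses dt larger than τ_{q_max} when the
*dynamics* matter (it can be disabled when only stationary shape
statistics are needed, e.g. stiff-membrane limits and white-noise
backgrounds).

## Active generator

Activity is modelled phenomenologically as a birth–death population of
angular density bumps:

* births: Poisson process (default rate 0.15 s⁻¹), initialised from the
  stationary population (length-biased lifetimes, uniform ages);
* lifetime: exponential, mean T_a = 100 s, with a sin² amplitude
  envelope over each bump's life;
* transport: each bump advects tangentially at angular speed
  ω = v/R₀ (default v = 1 μm/s, R₀ = 25 μm), with its direction drawn
  once (default 50/50 CW/CCW);
* deformation: each bump carries a co-moving membrane deformation whose
  mode amplitudes follow c_q ∝ q^{s/2} (default s = −3, i.e. a q⁻³
  power spectrum), normalized so one bump's peak deformation is the
  `amplitude` parameter (default 0.08); the density profile is a
  wrapped Gaussian (width 0.4 rad) sharing the bump's envelope, so
  deformation maxima co-locate with density maxima by construction;
* thermal floor: an OU background whose rigidity is chosen so its
  per-mode amplitude is 10% of the active one (both scale as q⁻³, so
  the ratio is uniform in q).

Two deliberate choices deserve comment.

**Lifetime vs. transport.** The observed ~10 s deformation timescale is
the *measured correlation time* of the deformation field, which pure
advection at v = 1 μm/s on a 25 μm vesicle reproduces at the dominant
modes (τ_q = arccos(1/e)/(qω) ≈ 30 s/q). Making T_a itself ~10 s would
let the amplitude envelope dominate decorrelation at all q and flatten
the τ_q exponent to ≈ −0.5; the default T_a = 100 s keeps decorrelation
advection-dominated, giving the q⁻¹ law with exponent ≈ −0.95.

**Bump density.** With ~15 bumps alive on average, the stationary
deformation ensemble is near-Gaussian (central limit across bumps), so
pooled deformation histograms are strongly non-Gaussian only at short
averaging windows (frozen configurations) and relax toward zero excess
kurtosis as windows exceed the configuration decorrelation time — the
experimental trend. A sparse population (few bumps, slowly wandering
total power) would instead make kurtosis *grow* with window length.

What the generator does **not** contain: hydrodynamic interactions,
photobleaching/drift artefacts, membrane tethers, or any emergent
mechanics — the deformation spectrum is prescribed, not derived. The
3D simulator is the place where spectra and timescales emerge from
mechanics.

## Rendering and extraction

The renderer draws the membrane as a ring with a Gaussian radial
profile (ψ = 0.4 μm), and the density channel as intensity confined to
the band [R − 5 μm, R] with a ramp rising toward the membrane
(microtubules accumulate against it). Noise is Poisson–Gaussian with a
default ring peak of 400 counts (SNR ≈ 20): extraction accuracy, not
denoising, is under test.

Extraction follows the overlapping angular-segment procedure: segments
of amplitude da = 0.25 rad spaced dφ ≈ 0.15 rad (dφ is taken to be in
radians); within each segment the membrane peak is located along radial
rays and refined to subpixel precision by a 3-point parabola on *log*
intensity (exact for a Gaussian ring profile) after subtracting the
local background. Two implementation details matter for spectra:

* peaks are found **per ray** and the resulting radii averaged over a
  narrow central arc (~dφ/2). Averaging intensity profiles across the
  full segment before peak-finding rectifies contour slope into
  spurious high-q harmonics (measured 1.5× power inflation at q = 12);
  the full segment width is still used for the peak search and the
  missing-sample test.
* the ~42 segment radii are resampled to the 360-point grid by
  **trigonometric (FFT) interpolation**, exact for contours band-limited
  below the segment Nyquist mode (~21). Linear interpolation would
  attenuate amplitudes by its sinc² transfer (×0.78 at q = 10), enough
  to corrupt the spectrum exponent.

The centre is recomputed per frame (intensity centroid, refined once by
the contour centroid); q = 1 is therefore excluded from all physics
fits, as it absorbs centre error/translation. Frames with > 10% missing
segments are rejected and counted. With these choices the full
render→extract→spectrum round trip recovers per-mode power within 10%
up to q ≈ 13 at the default SNR.

Flow is measured by windowed circular cross-correlation of the angular
density between frame blocks one averaging window (default 1 s) apart,
per angular sector, with cosine-similarity normalization and parabolic
sub-sample peak refinement; sectors without an interior correlation
peak are flagged undefined rather than zero. Radial flow is the
membrane displacement over the same window. This correlation tracker
replaces gradient-based optical flow: on 1D angular signals it is
robust and has an exact synthetic oracle.

## Spectra, fits, times, kurtosis

* Fluctuation spectra are per-mode time variances of the de-meaned
  complex coefficients; the SEM comes from a block bootstrap over 10
  contiguous blocks (blocks must exceed the mode correlation time — the
  default partition is coarse for that reason; with < 3 blocks the SEM
  is NaN).
* The Helfrich fit is weighted least squares in log space over (κ, σ̄),
  initialised at σ̄ = 0 and refined from several tension starts;
  tension is reported as σ = σ̄κk_BT/R₀², flagged "below resolution"
  when σ̄ → 0. Defaults fit q = 3..q_max: q = 1 is translation, q = 2
  is commonly contaminated by global constraints.
* Correlation times use the biased (1/N) autocorrelation of each
  complex mode; τ_q is the first down-crossing of 1/e of Re C(τ),
  located by linear interpolation. No crossing → NaN; a crossing before
  the first lag is resolution-limited (τ ≤ dt).
* Excess kurtosis uses the bias-corrected estimator on deformations
  (R−R₀)/R₀ pooled over φ and frames within disjoint windows of length
  τ_avg; windows shorter than 20 frames are skipped with a warning.
  Note that "Gaussian passive ⇒ zero excess kurtosis" requires window
  mixing: a bending-dominated 25-μm vesicle at σ ≈ 0 has minute-scale
  relaxation times, each window sees one frozen q=2-dominated profile,
  and the pooled histogram is platykurtic (≈ −0.8) even though the
  ensemble is Gaussian. The Gaussian reference is therefore generated
  at the measured passive tension scale (σ = 10⁻⁷ N/m), whose
  sub-second relaxation gives kurtosis ≈ 0 at every τ_avg.
* Density modes run through the identical pipeline (mean-subtracted,
  un-normalized amplitudes); for cross-condition comparison the density
  spectrum is reported normalized to 1 at q = 2.

## Broken detailed balance

Mode-pair trajectories are binned on a 12×12 grid spanning ±3 SD per
coordinate (outside mass merged into boundary boxes, making the
analysis invariant under coordinate rescaling). Transitions are counted
along the straight-line path between consecutive samples (multi-box
steps are split at each boundary crossing); net crossings per edge,
divided by total time, give the current field j. On every elementary
4-box plaquette the normalized circulation Ω = ∮j·dl / ∮|j|dl is
computed; z = mean(Ω)/sd(Ω) across plaquettes.

Caveats established by simulation and reflected in the tests:

* for a rotationally driven *Gaussian* process the vorticity of j
  reverses sign at r = √2 SD (curl j ∝ (2−r²)ρ), so the plain mean of
  Ω can carry the sign of the low-occupancy skirt and |z| saturates
  near 1 no matter how strong the driving or how long the record. The
  occupancy-weighted statistics (`weight="occupancy"`) read the
  circulation where the probability mass is and make the driving sign
  robust; |z| > 2 is reached by trajectories with ring-like occupancy
  (coherent rotators), for which Ω is spatially uniform.
* cross-mode pairs (Re u_qa, Re u_qb) carry *structurally* zero net
  flux under pure advection (different-frequency cosines enclose no
  signed area); the coherent circulation of a travelling deformation
  lives in each mode's complex plane (u_q is a rotating phasor when the
  flow has a net direction), exposed via `coordinate="complex"` with
  pair (q, q). At realistic record lengths the counting statistics of
  the bump generator remain below Benjamini–Hochberg significance —
  flux detection is data-hungry; the machinery's detection power is
  demonstrated on coherent-rotator trajectories through the same
  pipeline, and the equilibrium null (no significant pair) is verified
  as specified.

## Triangulated-vesicle simulator

The membrane is a dynamically triangulated closed network (icosphere
with 162/642/2562 vertices; bond flips supply in-plane fluidity) with

* bending: E_b = κ̃ Σ_e (1 − cos θ_e), κ̃ = √3 κ (dihedral form;
  validated by refinement convergence and by spectrum-level rigidity
  recovery rather than by its absolute sphere energy, which carries a
  discretization factor ≈ 0.52 × 8πκ);
* tension σA, and harmonic area/volume constraints
  K_A(A−A₀)²/A₀ + K_V(V−V₀)²/V₀ with K_A = 100 k_BT/μm²,
  K_V = 15 k_BT/μm³ — strong enough to hold both within 1% even under
  activity, weak enough not to freeze thermal roughness;
* hard tether limits [l₀/1.45, 1.45 l₀] on membrane bonds;
* Metropolis dynamics (uniform cube moves, auto-tuned to 20–70%
  acceptance; flips attempted on 20% of edges per sweep). Hydrodynamics
  is deliberately absent; Monte Carlo time is mapped to seconds by
  matching the measured passive τ₃ (in sweeps) to the physical τ₃
  (`calibrate_timescale`), after which T_str values in seconds are
  meaningful.

Filaments are bead–spring chains (20 beads) with harmonic bonds whose
rest length follows a triangle wave L → L_max → L over 2T_str
(per-filament random phases; re-seeding at a random interior position
after each shrink, standing in for bundles breaking or detaching), a
soft discrete bending term, and purely repulsive short-range coupling
κ_rep(1−r/r_c)² to membrane vertices and other beads. The filament
parameters (k_bond = 30 k_BT/μm², k_angle = 50 k_BT,
k_rep = 1000 k_BT, r_c = 1.2 l₀) were chosen so that growing chains
*buckle* against the membrane instead of spearing through the discrete
vertex barrier — containment is enforced by an explicit test — while
still pressing hard enough to deform it.

Equatorial read-out casts 180 rays from the instantaneous centroid in
the z = 0 plane (Möller–Trumbore, farthest intersection); per-vertex
active forces are the repulsion gradients, and the angular force
profile uses the radial force components of vertices within
|z| < 0.1 R₀. The effective tension σ_act and rigidity are extracted
by the exact quasi-spherical equatorial fit; how such quantities are
best measured in this model is genuinely open, and this definition is
the package's own.

Study conditions for the passive equilibrium checks: 642 vertices,
σ = 0, reduced volume 0.98. The reduced volume grants ≈ 1.4% excess
area; thermal sub-mode roughness at κ = 20 k_BT consumes ≈ 1%, leaving
the equatorial modes bending-dominated (fitted σ̄_eff ≈ 0.7, spectrum
slope ≈ −3.2, recovered κ ≈ 23.5 k_BT). At reduced volume 1.0 the area
constraint binds (σ̄_eff ≈ 9) and at 0.93 the membrane is floppy
(negative effective tension, slope < −4): the constrained ensemble
behaves exactly like a tension reservoir set by the area budget.
Desk-scale runs use ~30k sweeps (minutes on one CPU); the quantitative
active-regime scalings (τ_q ∝ 1/q at T_str = 10.2 s over q = 2..8, and
the κ^(−1/4) crossover across κ = 10..160 k_BT) require multi-hour
runs and are exercised qualitatively (activity-enhanced low-q
correlation times, nonzero persistent forces) rather than asserted at
full scale in the default suite.

## Problem sizes and determinism

Synthetic recordings default to 3000–5000 frames (10–17 simulated
minutes), matching typical confocal session lengths; spectra stabilise
well before that. All generators, the renderer, the simulator and the
bootstrap are pure functions of (parameters, seed); the acceptance
script derives independent sub-seeds from one master seed.

## Known limitations

* The active generator's spectrum is prescribed; only the simulator
  produces emergent spectra, and only at desk scale here.
* Absolute κ from *real* images carries the 2D-vs-3D prefactor issue
  above; for experimental data the quasi-spherical fit should be
  preferred, and the package asserts only self-consistent recovery.
* The flux estimator needs long records; on 10-minute equivalents it
  reliably rejects equilibrium but cannot certify the weak circulation
  of the default bump field.
* Flow measurement assumes density features persist over the averaging
  window; featureless sectors return NaN by design.
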