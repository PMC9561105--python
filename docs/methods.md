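# Methods

This note documents the models, defaults, numerical choices, and limitations
behind `fbpm`.  Units are fixed package-wide: μm, s, K, g/cm³, mPa·s;
concentrations are in whatever unit the kinetic scenario's `c_half` uses
(pM, nM, μM — the analysis is scale-equivariant).

## Particle physics (`fbpm.physics`)

A bead of radius *a*, density ρ_p, in a medium of density ρ_m and viscosity
η at temperature *T*:

- **Free diffusivity** D₀ = kT/(6πηa) (Stokes–Einstein).
- **Equilibrium height**: the gap height *h* between bead and surface is
  exponentially distributed with mean h_B = kT/(Δρ·(4/3)πa³·g) — the
  barometric balance of thermal energy against buoyant weight.  Defaults
  T = 296 K, η = 0.93 mPa·s (water at 23 °C), g = 9.81 m/s²; all
  overridable.  For the two standard bead types: 2.8 μm / 1.6 g/cm³ →
  h_B ≈ 60 nm; 1.0 μm / 1.8 g/cm³ → h_B ≈ 1 μm.
- **Wall hindrance, parallel**: f∥(β) = 1 − (9/16)β + (1/8)β³ − (45/256)β⁴
  − (1/16)β⁵ with β = a/(a+h), the fifth-order Faxén (method-of-reflections)
  series for translation parallel to a plane wall.  The truncated series
  misses the logarithmic lubrication divergence at contact, so it is clamped
  below at 0.05 (configurable).  It is smooth and monotone; its far-field
  residual is (9/16)β, i.e. ~5.6×10⁻⁵ at h/a = 10⁴.
- **Wall hindrance, perpendicular**: the Brenner-type rational approximation
  f⊥ = (6h² + 2ah)/(6h² + 9ah + 2a²), vanishing linearly at contact.  Used
  only by the simulator's height dynamics.
- **Characteristic diffusivity**: E[D₀·f∥(h,a)] over the exponential height
  distribution, by adaptive quadrature (substituting u = h/h_B).  With these
  choices the 1 μm : 2.8 μm ratio evaluates to ≈ 5.6.  Observed ratios are
  reported as "approximately a factor 4"; the discrepancy is a property of
  the chosen hindrance closure (a steeper near-wall law for the 1 μm bead,
  e.g. including higher-order reflections, lowers the ratio), not of the
  averaging.  The quadrature is cross-checked against a Monte-Carlo average
  over sampled heights within 1%.

## Simulator (`fbpm.simulate`)

Each particle is integrated at substep resolution (default 10 substeps per
frame at 60 Hz, Euler–Maruyama):

- **Unbound**: gap height evolves by overdamped dynamics
  dh = [−D⊥(h)/h_B + D⊥′(h)]dt + √(2D⊥(h)dt)·ξ with a reflecting wall at
  h = 0.  The D⊥′ (Itô) drift term makes the exact stationary law of the
  discretized process the barometric exponential; this is verified by a
  KS test on a long trajectory.  Lateral steps are Gaussian with variance
  2·D₀·f∥(h,a)·dt per axis.
- **Bound**: positions follow an Ornstein–Uhlenbeck tether around the anchor
  point (the position at the binding instant) with stationary standard
  deviation ℓ_c = 0.03 μm and relaxation time 0.05 s, so the windowed
  effective diffusivity in the bound state sits far below the published
  cutoffs.  The height is frozen while bound.
- **State switching**: per-substep Bernoulli transitions with probabilities
  rate·dt (a warning is raised if any rate·dt > 0.1).  States: unbound,
  bound_specific (k_off = 0.25/s, i.e. the ~4 s single-bond lifetime),
  bound_nonspecific (k_ns = 0.002/s association, 1/s dissociation: rare,
  short-lived sticking), and an optional multivalent tier entered from the
  specific state at rate p_multi with slower dissociation (default off).
  Binding is height-independent by default — hit rate and binder densities
  are folded into one effective association rate, which is all the analysis
  layer can see — with an optional height-gated mode (binding only when
  h < 0.05 μm) for physical realism.
- **Concentration mapping**: the Hill-shaped k_on(C) above.  The true
  functional form of effective association versus concentration is not
  published; a Hill shape with n_mol = 1 is the simplest saturating,
  monotone choice and gives the generator a well-defined half-saturation
  C_half to recover.  Defaults: k_on_max = 0.02/s, C_half = 50 (pM-scale for
  a sandwich oligonucleotide assay), chosen so that unbound lifetimes span
  the ~50–500 s range over the assay's sensitive window and activities are
  O(1) event/particle/min, the scale such sensors operate at.
- **Recording**: positions are reported at frame boundaries with additive
  Gaussian localization noise σ_loc = 0.02 μm; recordings are 1–3 blocks of
  300 s at 60 Hz; ensembles default to 500 particles over a 706×530 μm
  field of view.  Per-particle seeds are spawned from the master seed
  (`numpy.random.SeedSequence`), so runs are bit-reproducible and any
  particle can be regenerated alone.  All random numbers are drawn by a
  numpy `Generator` and passed into the integration kernel, so the
  numba-compiled kernel and its pure-Python fallback produce identical
  output.

**What the generator emulates / does not.**  It reproduces the features the
analysis chain relies on: two motion states separated in effective D,
exponential dwell times with concentration-dependent association, censoring
at block edges, localization noise, non-specific short events, hindered and
height-modulated unbound diffusion.  It does not model binder surface
density heterogeneity, particle size dispersity or magnetic content
variation, DNA hybridization thermodynamics, matrix effects (plasma is
representable only as an elevated k_ns), drift, illumination non-uniformity,
or slow sensor memory (see Monitoring below).  Passing tests therefore
validate the estimators and the pipeline logic, not the chemistry of any
particular assay.

## Localization (`fbpm.localize`)

- **Detection**: local maxima above median + 5·MAD within a
  minimum-separation neighbourhood (defaults 5 MAD, 4 px).
- **Phasor localization**: position from the phase of the first Fourier
  coefficient of the ROI's marginal sums, x₀ = −angle(c₁)·N/(2π), offsets
  reported relative to the ROI centre (default ROI 7 px).  A constant
  background contributes only to the DC term, so no background fit is
  needed; a constant ROI is rejected as undefined.
- **Linking**: per-frame bipartite assignment minimizing total displacement
  (Hungarian algorithm) among candidate pairs within a maximum displacement;
  unmatched detections seed new tracks, gaps up to `max_gap` frames are
  bridged by linear interpolation and flagged invalid.  A stub filter drops
  tracks shorter than `min_track_length` localized frames (shot-noise
  detections rarely persist).  Pixel size defaults: 0.345 or 0.588 μm/px for
  the two camera configurations used with 2.8 and 1 μm beads.

## Motion analysis (`fbpm.motion`)

- **Windowed diffusivity**: sliding window W = 30 frames (0.5 s, step 1
  frame), MSD over lags 1–5 using all overlapping valid pairs, D =
  (origin-constrained least-squares slope)/(4Δt).  W and the lag set trade
  responsiveness against estimator variance: 0.5 s resolves the seconds-
  scale dwells at 60 Hz with ~30% relative estimator noise.  The static
  localization-noise floor of this estimator is ≈ 16·σ_loc² (≈ 0.007 μm²/s
  at σ_loc = 20 nm); negative slopes are clipped to zero and counted.
- **Segmentation**: hysteresis — enter bound when D < 0.6·cutoff, exit when
  D > cutoff, with the published cutoffs 0.15 (1 μm) and 0.05 μm²/s
  (2.8 μm).  The hysteresis band suppresses threshold chatter from
  estimator noise.  Dwells shorter than 90 trace samples (three window
  lengths, 1.5 s) are merged into their surroundings: windowed-D noise is
  correlated over about one window length, so a debounce shorter than that
  lets noise excursions masquerade as binding events, while 1.5 s remains
  well below the ~4 s bond lifetime.  Consequence: events shorter than
  ~1.5 s (including most 1 s non-specific sticks) are not counted — the
  segmented activity measures *resolvable* events, which is also true of
  any windowed-MSD analysis of real recordings.  On simulated 2.8 μm
  sandwich data, frame-level agreement with ground truth is ≈ 99%.
- **Quality filter**: (i) stuck — mean D < 0.01 μm²/s; (ii) hyperactive —
  transition count above the ensemble mean by > 4 SD; (iii) colliding —
  pairs closer than 0.7 μm (≈ 2 px) for an uninterrupted run > 1 s, both
  excluded (the published rule gives no tolerance; these are the
  operationalized defaults).  A warning is emitted when ≥ 10% of particles
  are excluded, the level above which a recording is suspect.

## Dwell-time statistics (`fbpm.kinetics`)

- **Extraction**: dwells between consecutive transitions within each
  recording block.  Dwells touching a block edge are flagged `censored`;
  the subset truncated by the block *end* is additionally `right_censored`.
- **Exponential MLE** (censored mode): τ̂ = (Σ all observed durations) /
  (number of dwells ending in an observed transition).  A dwell clipped at
  the block start but ending in a transition counts as an event — by
  memorylessness its observed duration is a valid draw — which makes the
  estimator exactly invariant under subdividing an uninterrupted recording.
  SE = τ̂/√n_events.
- **Naive mode** treats every dwell as complete.  It reproduces the
  behaviour of finite-window measurements: when the true lifetime far
  exceeds the recording (e.g. high-concentration competition assays), the
  naive estimate saturates near the window duration (~850 s for 3×300 s)
  instead of diverging.  Both modes are exposed because both behaviours are
  needed — correctness and fidelity to published finite-window values.
- **Survival curves**: empirical 1 − CDF over complete dwells (censored
  count reported alongside).
- **Bi-exponential fit**: two-component mixture by EM on complete dwells
  (≥ 50 required), components ordered τ₁ < τ₂; degenerate fits (τ₂/τ₁ < 2
  or weight pinned near 0/1) fall back to the single exponential with a
  warning.  Intended for coexisting monovalent/multivalent bond
  populations.
- **Activity**: binding plus unbinding transitions per particle per minute
  (both directions counted, per the definition of switching activity); SEM
  across particles.  **Bound fraction**: per-particle time average, then
  particle average; SEM across particles.  The replication unit for SEM is
  the particle within a block.

## Dose-response and monitoring (`fbpm.response`)

- **Hill fit**: weighted least squares of
  y = y_min + (y_max − y_min)·xⁿ/(EC50ⁿ + xⁿ) with EC50 and n fitted on a
  log scale internally (positivity across pM–μM ranges); decreasing
  responses are handled by y_max < y_min.  Weights are inverse-variance
  with per-point uncertainties floored at the median uncertainty;
  zero-concentration blanks are excluded from Hill fits (they belong to
  relaxation analysis).  95% CI on EC50: linearized covariance on
  log-EC50 — normal quantile when real SEMs are supplied
  (absolute-σ treatment), Student-t on the residual dof otherwise; a seeded
  percentile bootstrap (1000 resamples) serves as fallback when the
  covariance is unusable and is available on request.  Calibration: in 200
  replicate fits at 5% noise the CI covers the generative EC50 ~95% of the
  time.  Multi-start initialisation over a small EC50 grid guards against
  local minima; flat data (dynamic range < 2× median uncertainty) raises an
  unidentifiable-fit error.
- **Relaxation fit**: y(t) = y_∞ + (y₀ − y_∞)exp(−t/τ) by least squares;
  offset-invariant; warns on poor fits (R² < 0.5).
- **Monitoring**: block-by-block pipeline (QC → diffusivity → segmentation →
  activity/bound fraction/lifetimes); failed blocks are flagged missing and
  the series continues.  Note the simulator itself is memoryless in
  concentration — sensor relaxation (slow de-occupancy of binders) is
  emulated by driving it with an exponentially relaxing applied
  concentration in the linear regime (C ≪ C_half), and the relaxation fit
  recovers that generative time constant.
- **EC50 across readouts**: activity, bound fraction, and lifetime EC50s
  need not coincide — each readout is a different nonlinear functional of
  k_on(C) — so end-to-end recovery is validated to within a factor 2 of the
  generative C_half (with k_on_max ≪ k_off the activity readout is nearly
  proportional to k_on and lands close to C_half).

## Problem sizes and determinism

Validation suites run at desk scale: ensembles of 30–250 particles and
blocks of 45–300 s, sized so every statistical assertion has ≥ 2–3σ margin
under its frozen seed while the whole suite stays fast.  All stochastic
tests are seeded; simulator output is bit-reproducible given
(config, seed).  The integration kernel is numba-jitted with an identical
pure-Python fallback.

## Known limitations

- The hindrance closure is a truncated series with a near-contact clamp;
  absolute characteristic-D values (and their size ratio) inherit its
  error.
- Segmentation is threshold/hysteresis on windowed D; it cannot resolve
  events shorter than ~3 window lengths and lags true transitions by up to
  ~half a window.  More powerful state classifiers (HMMs, learned models)
  would recover shorter events.
- The bi-exponential fit ignores censoring (complete dwells only).
- Competition-assay lifetime plateaus are reproduced in naive mode by
  construction; the censored mode instead returns honest lower-information
  estimates with large SEs at such concentrations.
- The simulator's bound-state anchor is fixed; real multivalent bonds allow
  slow anchor migration.
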