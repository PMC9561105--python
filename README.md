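# fbpm — free-diffusion Biosensing by Particle Mobility

`fbpm` simulates and analyses experiments in which biofunctionalized
microparticles (e.g. 1 or 2.8 μm Dynabeads) hover over a binder-coated sensor
surface and reversibly bind to it through single molecular bonds.  Tracking
hundreds of particles at 60 Hz turns each particle into a single-molecule
sensor: while unbound it shows free Brownian motion with high effective
diffusivity *D*; a target-mediated bond confines it, and *D* drops sharply.
Counting these digital switching events, their dwell times, and the fraction
of time spent bound yields continuous, reversible concentration readouts for
sandwich assays (signal rises with target) and competition assays (signal
falls) — down to picomolar oligonucleotide and micromolar small-molecule
(e.g. cortisol) concentrations.

The package is aimed at people developing or studying such particle-mobility
sensors: it provides the complete analysis chain used on real trajectory
data, plus a physics-based simulator that generates realistic synthetic
experiments with exact ground truth for validating every analysis step.

## The model in brief

**Particle physics.**  A bead of radius *a* and density ρ_p in a medium of
density ρ_m has free diffusivity D₀ = kT/(6πηa).  Sedimentation against
thermal motion gives an exponential (barometric) distribution of
particle–surface gap heights with mean h_B = kT/(Δρ·V·g) — about 60 nm for a
2.8 μm bead (ρ_p = 1.6 g/cm³) and about 1 μm for a 1 μm bead (1.8 g/cm³).
Near the wall, hydrodynamic coupling reduces the in-plane mobility by a
factor f∥(h, a) (fifth-order Faxén series in β = a/(a+h)); averaging
D₀·f∥ over the height distribution yields the *characteristic diffusivity*
observed for the unbound state.

**Kinetics.**  Binding is a continuous-time Markov process with an effective,
concentration-dependent association rate

    sandwich:     k_on(C) = k_ns + k_on_max · Cⁿ / (C_halfⁿ + Cⁿ)
    competition:  k_on(C) = k_ns + k_on_max · C_halfⁿ / (C_halfⁿ + Cⁿ)

and exponential dissociation (single bonds live ~4 s; short-lived
non-specific sticking and a long-lived multivalent tier are also modelled).

**Analysis.**  Trajectories → sliding-window MSD diffusivity traces
(D = origin-constrained slope of MSD over lags 1–5, window 0.5 s) →
hysteresis segmentation at the published cutoffs (>0.15 μm²/s free for 1 μm
particles, >0.05 μm²/s for 2.8 μm) → quality filter (stuck, hyperactive, and
colliding particles excluded) → dwell times with right-censoring at block
edges → censored exponential maximum-likelihood lifetimes, switching
activity (events·particle⁻¹·min⁻¹), bound fraction → dose–response curves
fitted with the four-parameter sigmoid

    y(x) = y_min + (y_max − y_min) · xⁿ / (EC50ⁿ + xⁿ)

to extract EC50 with a 95% confidence interval, and exponential relaxation
fits for monitoring time series.

## Worked example

```python
import fbpm

spec = fbpm.ParticleSpec(radius_um=1.4, density_p=1.6)   # 2.8 um Dynabead
print(fbpm.stokes_einstein_d0(spec))        # 0.1665 um^2/s  (free D0)
print(fbpm.boltzmann_mean_height(spec))     # 0.0604 um      (~60 nm)
print(fbpm.characteristic_diffusivity(spec))  # 0.0614 um^2/s (wall-hindered)

# simulate one 5-minute sandwich-assay recording at the half-saturation
# concentration (C_half = 50 concentration units), then analyse it blind
scen = fbpm.KineticScenario()                 # k_on_max=0.02/s, k_off=0.25/s
cfg = fbpm.SimConfig(n_particles=50, block_s=300.0, seed=7)
trajs, truth = fbpm.simulate_fov(spec, scen, cfg, concentration=50.0)
res = fbpm.analyze_ensemble(trajs, fbpm.AnalysisConfig(cutoff=0.05))
print(res.summary())
```

The analysis report (abridged):

```
activity_per_min : 0.812 ± 0.085     # switching events per particle per minute
bound_fraction   : 0.0307 ± 0.0035
unbound_lifetime : tau = 142.5 ± 14.1 s  (58 events, 93 censored dwells)
bound_lifetime   : tau = 4.55 ± 0.45 s   (101 events)
```

The recovered bound lifetime matches the generative 1/k_off = 4 s, and the
unbound lifetime reflects the effective association rate of resolvable
events at this concentration.  Rerunning across a concentration series and
calling `fbpm.build_dose_response` + `fbpm.fit_hill` yields the EC50
calibration; `fbpm.run_monitoring` analyses a concentration-time profile
block by block.

A command-line interface wraps the same chain:

```bash
fbpm --config run.yaml --out-dir out simulate --concentration 50
fbpm --config run.yaml --out-dir out analyze out/trajectories.csv
fbpm --out-dir out render out/trajectories.csv       # synthetic TIFF stack
fbpm --out-dir out localize out/stack.tiff           # phasor tracking
fbpm --config run.yaml --out-dir out dose-response manifest.csv
fbpm --config run.yaml --out-dir out monitor blocks.csv
```

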