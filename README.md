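# trichomech

Micro-force spectroscopy of glandular trichome rupture.

Type VI glandular trichomes of tomato (*Solanum lycopersicum* and the wild
relative *S. habrochaites*) store defensive fluid in a cavity atop a short
stalk; the gland head tears off at the head–intermediate-cell junction under
a few micronewtons of force, releasing the fluid onto whatever touched it —
typically an insect leg. `trichomech` implements the complete measurement
chain for quantifying this defense mechanism from microscopy video:

* **imaging** — sub-pixel centroid tracking of the pipette tip in
  bright-field image stacks;
* **calibration** — micropipette spring constants *k* from droplet-weight or
  two-pipette deflection series, with uncertainty;
* **forcecurve** — two-regime changepoint segmentation of position traces,
  force conversion *F(t) = k·Δx(t)*, rupture detection, rescaled-curve
  ensemble collapse, and junction torque/critical-stress computation
  (τ = r·F·sinθ, σ_c = Rτ/I_z with I_z = πR⁴/4);
* **beam** — the trichome stalk as a truncated-cone Euler–Bernoulli
  cantilever: bending-modulus estimation and inversion of observed stalk
  deflections into insect-applied forces,
  F⊥ = 3πE·R1³R2/(4L³)·Δx, with first-order uncertainty propagation;
* **fluidics** — Reynolds/Weber/Bond classification of the fluid release
  (Re = ρUL/μ, We = ρU²L/σ, Bo = ρgL²/σ) and Lucas–Washburn capillary
  viscometry;
* **stats** — 1.5·IQR outlier screening, two-way ANOVA (Type II) and Tukey
  HSD with a compact letter display over the species × location groups;
* **synthio** — ground-truthed synthetic generators for every input
  (trajectories, image stacks, calibration series, grouped force datasets,
  deflection series), emulating the statistical structure of the real
  measurements so that each inference stage can be validated as a round
  trip.

## Worked example

`examples/01_rupture_force_from_trace.py` simulates a single rupture
experiment (pipette with k = 0.10 μN/μm translated at 33 μm/s, tracking
noise 0.1 μm) and runs the full inference chain:

```
contact onset:      2.020 s (truth 2.000 s)
rupture force F_r:  6.01 uN (truth 6.01 uN)
time to rupture:    3.62 s after contact
free / post slope:  33.0 / 33.0 um/s
junction torque:    180.2 uN.um
critical stress:    0.133 MPa
```

The pipette's position shows two constant-slope regimes — free motion, then
slowed motion during elastic loading — and returns to the free slope after
rupture. The rupture force is the peak of the loading curve; with the lever
arm and junction radius it converts into the torque and the maximal bending
stress at the junction at the moment of failure. The other scripts in
`examples/` demonstrate calibration, image tracking, grouped statistics,
insect-force inversion and fluid characterization, one capability each.

A thin CLI wraps the same functions
(`trichomech simulate|track|calibrate|analyze-rupture|insect-force|fluidics|group-stats|run-all`);
`trichomech run-all --seed 0 --outdir out/` performs a reproducible
end-to-end run from a YAML config with provenance-stamped outputs.

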