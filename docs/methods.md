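# Methods

## Physical model

A pulled glass micropipette is a linear cantilever spring: lateral tip force
and deflection are related by F = k·Δx, with k an empirically calibrated
constant (manufactured range 0.04–1.17 μN μm⁻¹). During a rupture
experiment the pipette is translated at a constant free speed
(γ̇ = 33 μm s⁻¹) toward a gland head; on contact the tip slows and the
pipette bends, storing the deflection Δx(t); at rupture the head detaches
and the tip snaps back to its free trajectory. The applied force follows
from the gap between the extrapolated free trajectory and the observed
position.

The junction between gland head and intermediate cell is treated as a solid
circular section of radius R with second moment of area I_z = πR⁴/4. A
rupture force F_r applied at lever arm r and angle θ to the lever vector
produces the torque τ_r = r·F_r·sinθ, and the bending stress is maximal at
the section boundary: σ_c = R·τ_r/I_z = 4τ_r/(πR³). In μm/μN units σ_c is
already in MPa. The model ignores the cell-wall shell structure of the real
junction (the section is treated as solid), so σ_c is a lower bound on the
stress carried by the actual walls; it serves for *relative* comparisons
across groups.

The stalk is a homogeneous, linearly elastic truncated-cone cantilever of
length L, top radius R1 and base radius R2 (R1 ≤ R2), with effective moment
of area πR1³R2/4, giving tip stiffness k_beam = 3πE·R1³R2/(4L³). No shear
correction is applied (slenderness L/R ≫ 1). The same relation is used in
both directions: known force → bending modulus E; known E → force from an
observed deflection.

### Angle conventions

Two distinct angles appear. θ_torque (forcecurve) is the angle between the
applied-force vector and the lever vector from the junction axis; it enters
the torque as sinθ. θ_axis (beam) is the angle between the insect's
applied-force direction and the in-plane perpendicular to the stalk axis;
the measured deflection senses only the in-plane perpendicular component
F⊥, so the full force is F_ins = F⊥/cosθ_axis. The division convention is
the default because a resultant cannot be shorter than one of its
orthogonal components; the multiplicative form (F⊥·cosθ) is available
behind `convention="literal"` for comparison with analyses that use it.

## Algorithms and numerical choices

**Changepoint segmentation.** Contact onset is found by exhaustive
two-segment least squares: every candidate breakpoint is scored by the sum
of squared residuals of independent line fits to the samples before and
after it (prefix-sum implementation, O(n); verified against a naive
per-split polyfit oracle). Minimum segment length 5 samples; on exact
SSE ties the earliest breakpoint wins (on noise-free data the kink sample
and its successor both give zero error). A breakpoint qualifies only if it
reduces the slope by ≥ 10% (configurable); otherwise "no contact" is
reported. Because a full trace has three regimes (free, loading,
post-rupture), the search window is first truncated at the rupture
snap-back — the single large forward jump when the stored deflection
releases — located by windowed mean-differencing (window 8) with a robust
5-σ acceptance threshold and refined to the largest single-step advance, so
two-regime traces without a rupture are never truncated. In-plane positions
are projected onto the direction of net motion before fitting, making the
analysis invariant to camera orientation.

**Rupture detection.** The rupture is the global force maximum, accepted
only if the force drops by ≥ 50% of the peak within 5 samples afterwards
(both configurable); a residual sticking force — gland fluid adhering to
the pipette — is therefore tolerated. The post-rupture slope is refit and
reported; on valid data it matches the free slope within noise.

**Rescaled collapse.** Each loading curve is normalized by its rupture time
and force so it ends exactly at (1, 1); an ensemble is interpolated onto a
common grid in [0, 1] and summarized by pointwise mean ± SD. Linear loading
collapses onto the identity line regardless of k and loading rate.

**Calibration fits.** Regression through the origin (zero load → zero
deflection); a free intercept is available for diagnostics only, since the
physical model has no offset and an intercept inflates σ_k at small n.
Droplet weights assume spheres of water (ρ = 1000 kg m⁻³); evaporation
corrections are out of scope.

**Centroid tracking.** Per frame: median background subtraction within the
ROI, Otsu threshold (or a fixed value), intensity-weighted centroid of
above-threshold pixels. Pixel centers sit at integer coordinates with the
origin at the top-left pixel center; since all downstream quantities are
position differences, any consistent convention cancels. Frames with no
above-threshold pixel are flagged missing and excluded from fits — never
interpolated, because changepoint estimates are sensitive to fabricated
points.

**Uncertainty propagation.** First-order delta method,
σ² = Σ(∂f/∂xᵢ·σᵢ)²; for the insect force the partials are ∂F/∂E = F/E and
∂F/∂L = −3F/L — the cubic length dependence makes L the dominant error
source, and stalk bases are often out of frame, so σ_L defaults to 20% of L
when not supplied. Agreement with Monte-Carlo sampling is within 10% at
small relative errors. Reported ±1σ force intervals clip at zero (forces
are positive); with the observed modulus spread (σ_E/E ≈ 64/55) the lower
edge always reaches zero.

**Group statistics.** Outlier screening uses the 1.5·IQR rule with
linear-interpolation quantiles (numpy default), applied to the pooled
sample by default (per-group optional). The two-way ANOVA uses Type II sums
of squares — appropriate for main-effect testing in the unbalanced design
(group sizes 16/24/29/10); Types I/III are available by flag. Tukey HSD
letters are assigned at α = 0.02 by insert-and-absorb; groups sharing a
letter are not significantly different. Groups with n = 1 are excluded from
Tukey with a warning.

**Fluidics.** SI units internally (unlike the μm-based mechanics modules);
an explicit μm→m converter is provided. Water values ρ = 1000 kg m⁻³ and
σ = 0.072 N m⁻¹ are defaults and should be read as bounds (the gland fluid
was not directly measurable). The viscosity fit assumes Lucas–Washburn
imbibition with full wetting (cosθ_c = 1) of the glass capillary, fitting
l² vs t through the origin; the contact angle is configurable and the
choice is surfaced in the output metadata.

## What the synthetic generators emulate — and what they do not

The generators reproduce the *statistical structure* of the real
measurements: two-slope trajectories at 33 μm s⁻¹ with grid-snapped contact
and rupture times (so noise-free traces invert exactly), spring constants
and rupture forces drawn from the manufactured/observed ranges
(0.04–1.17 μN μm⁻¹, 1–24 μN), Gaussian tracking noise (default 0.1 μm —
sub-pixel scale, carrying ~10 nN of force noise at k ≈ 0.1 μN μm⁻¹), the
four species × location groups at their observed means/SDs/counts
(5±2 n=16, 9±3 n=24, 6±3 n=29, 4±2 n=10, plus 5 planted outliers), and
truncated-cone deflections over the observed modulus range (8–235 MPa).

Deliberate idealizations: loading is kinematically rigid (deflection grows
linearly at a constant rate — observed loading slopes are linear; the
default rate, 0.5·k·v_free, halves the apparent tip speed as in measured
traces and respects the physical bound loading_rate < k·v_free); the
post-rupture residual force defaults to zero with a sticking-force option;
rupture-force draws are truncated at zero (physical positivity); tracking
noise is white and Gaussian. Group draws that the pooled 1.5·IQR rule would
itself flag are redrawn, so the planted-outlier labels are unambiguous
ground truth; the redraw touches well under 1% of probability mass but
does condition the stiff group's upper tail slightly. Passing tests on this
synthetic data therefore validate the inference chain, not the realism of
any particular biological dataset: real traces may show drift,
vibration-correlated noise, nonlinear loading, or partial ruptures that the
generators deliberately omit.

Stiff-pipette/weak-head corners of the parameter space load in a fraction
of a second and contribute only a handful of loading samples at the default
50 Hz frame rate — as in real recordings, where such events are nearly
instantaneous. Rupture-force recovery is insensitive to this (the peak
force does not require an exact breakpoint), but contact-time localization
to ±2 frames is only meaningful for well-resolved loading phases.

## Problem sizes

The validation suite uses desk-scale ensembles: 50 noise-free plus 200
noisy rupture scenarios, 25-point sweeps across the spring-constant and
modulus ranges, 200 replicates of the grouped analysis, 500 null-ANOVA
replicates, and 10⁵-sample Monte-Carlo checks of the uncertainty
propagation. These sizes give comfortable statistical resolution for every
claim tested while keeping a full run in minutes on one CPU.

## Known limitations

* The critical stress treats the junction as a solid section; cell-wall
  thickness effects and species differences in wall structure are not
  modeled.
* σ_c and τ_r take lever geometry (r, θ, R) as per-event user inputs
  measured from images; the package does not infer them.
* The Washburn viscometry assumes a cylindrical tube of known radius and
  full wetting; pipette taper is ignored.
* The Tukey separation power of the grouped analysis at the observed effect
  sizes is close to its nominal design point (~77–80% across replicate
  batches for the cultivar-stem group at α = 0.02): the zero-truncation and
  exact-outlier conditioning of the generator shrink the key group contrast
  by ≈ 10%, so separation rates in any given 200-replicate batch straddle
  80%.
* No mixed-effects modeling of per-plant clustering; observations are
  treated as independent within groups.
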