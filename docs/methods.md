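# Methods

`juxtacell` re-implements, as a tested pipeline driven entirely by synthetic
data with known ground truth, the computational core of a synthetic-cell
juxtacrine-signaling study: (i) luminescence-decay kinetics and catalytic
rate-constant estimation for NLuc and a SpyTag–SpyCatcher-reconstituted
split luciferase (NanoBiT); (ii) a radial reaction–diffusion model of
SspB recruitment to membrane-anchored iLID inside a vesicle; and (iii) the
fluorescence-image quantification procedures used to score membrane
recruitment in GUVs (giant unilamellar vesicles).

## Luminescence-decay kinetics

A luciferase of concentration `E` consumes its substrate `S` by mass action,
`dS/dt = -K·E·S`, so photon flux (proportional to reaction velocity) is

```
flux(t) = α·K·E·S0·exp(-K·E·t)
```

with `K` the catalytic rate constant (M⁻¹s⁻¹) and `α` an arbitrary detector
calibration. Estimation is two-stage:

1. per trace, OLS of `ln(flux)` on `t` yields the decay rate `λ = K·E`;
2. across traces, OLS of `λ` on `E` yields `K` as the slope, with a 95 %
   t-interval on `n−2` degrees of freedom.

Numerical choices, all configurable:

* **Natural log.** With `ln`, the fitted slope equals `K·E` with no base
  conversion; a log₁₀ fit would only rescale both stages consistently.
* **Intercept retained** in the `λ`-vs-`E` regression: it absorbs
  concentration-independent baseline or leakage; for clean decays it fits
  to zero anyway.
* **Fit window** defaults to the sample of maximum flux onward, discarding
  reagent-mixing transients before the peak. For near-flat traces
  (tiny `K·E`) this default can leave too few samples; pass an explicit
  window in that regime.
* **`min_flux` = 10 photons/s**: samples at or below this floor are
  detector noise and are excluded before taking logs.
* Because the fitted `λ` is reported as a magnitude, traces whose true
  decay rate is at or below the slope-noise floor fold negative estimates
  upward; rate constants should be estimated from series whose smallest
  `K·E` clearly exceeds that floor (the default enzyme series 1–20 nM with
  the published constants satisfies this comfortably).

## Radial reaction–diffusion model

Free SspB diffuses in a disk of radius `R` (default 10 μm — the 20 μm
vesicle cross-section) and binds iLID sites at the rim:

```
∂c/∂t = D (1/r) ∂r (r ∂r c)
db/dt = k_on·c(R)·(σ_max − b) − k_off·b,     k_off = k_on·Kd
```

`b` is the bound surface density (mol per unit rim length per unit depth)
and `σ_max = I_tot·R/2` redistributes the encapsulated iLID concentration
onto the rim. The photoswitch enters through `Kd`: `Kd_lit = 132 nM` under
blue light, `Kd_dark = 4.7 μM` in the dark — the published affinities of
the iLID/SspB-Nano pair — with `k_on = 10⁶ M⁻¹s⁻¹`. Default `D = 20 μm²/s`,
a typical cytosolic diffusivity for a small protein fusion. Defaults:
`S_tot = 100 nM`, `I_tot = 450 nM`, matching the encapsulated
concentrations.

**Discretization.** Uniform radial grid (`n_r = 64` nodes, node 0 at the
center); finite-volume form of the polar Laplacian with fluxes through
annular faces, symmetric at `r = 0`. The rim cell exchanges molecules with
the bound pool one-for-one, so total count (lumen integral + membrane pool)
is conserved to rounding error by construction — observed drift ~10⁻¹³
relative. Explicit Euler stepping with an enforced bound
`dt ≤ 0.2·dr²/D`; violating states (negative or non-finite concentrations)
raise a stability error naming the bound rather than propagating garbage.

**Steady state and oracle.** Because the scheme conserves count exactly and
binding is restricted to the rim, its discrete steady state satisfies the
same algebra as the well-mixed binding equilibrium with depletion:

```
B² − (I_tot + S_tot + Kd)·B + I_tot·S_tot = 0   (smaller root)
ratio = B/(S_tot − B)
```

independently of grid resolution. This closed form is the independent
oracle: finite-volume steady states agree with it to <1 % across randomized
parameter sets, and grid refinement changes the ratio by <0.5 %.
Convergence is declared when the maximum relative profile change per
simulated second falls below 10⁻⁶ (default `t_max` 3600 s; non-convergence
is flagged, not raised).

With these literature affinities the model predicts a lit-state
membrane:lumen molecule ratio of **2.85** and a dark-state ratio of
**0.094**; the study's own model quotes a lit prediction of about 6, which
requires an effective lit-state `Kd` near 60 nM — a value its main text
does not publish. We keep the literature constants as defaults rather than
calibrate to the quoted output; all affinities are configurable.

Two read-outs are always reported: the molecule-count ratio
`bound/free` (the model's natural quantity) and a shell intensity ratio
`(b/Δr + c(R))/c(0)` with `Δr` one grid cell, the analogue of what a
fluorescence image measures; the latter is resolution-dependent by
construction and is labelled as such.

## Image quantification

* **Periphery ratio**: bilinear samples at 30 points equally spaced along
  the annotated membrane circle (a configurable sampling phase `theta0`
  makes the measurement exactly equivariant under image+annotation
  rotation); lumen mean over the central disk of half the annotated radius
  (keeping clear of membrane-proximal PSF bleed); background mean over an
  annotated rectangle; ratio `(periphery − bg)/(lumen − bg)`.
* **Line profile**: 1 px-spaced bilinear samples along a segment,
  background-subtracted, negatives clipped, normalized to the maximum.
* **Interface ratio**: per line crossing the contact (oriented from outside
  the receiver into its lumen), background-subtract, then: membrane = mean
  of the 3 samples centered on the global maximum; lumen = mean of the 10
  samples immediately following that window, deeper into the lumen.
  Ties at the maximum resolve to the center of the maximal run, so an
  unblurred plateau-topped peak is measured at its centerline. When no
  clear peak exists — maximum less than 20 % above the median of the 10
  subsequent points — a plateau point stands in: the first sample (scanning
  inward) where the discrete derivative stays within 2 % of the profile's
  dynamic range for 3 consecutive samples *and* the profile is at ≥80 % of
  its maximum (the height condition stops the flat approach *before* the
  signal rise from qualifying). Per-line ratios are averaged into one
  value per interface. The "10 following points" are taken after the
  3-sample membrane window; taking them directly after the peak sample
  would place two of them inside the membrane itself.

Known bias: with a point-spread blur comparable to the painted interface
width, the 3-point membrane window underestimates the peak and the early
lumen points catch membrane bleed, so the recovered interface ratio sits
below truth (≈2.3 recovered at truth 2.5 under the defaults, exact
recovery when unblurred). This mirrors the real measurement's optics and
cancels in condition comparisons; quantitative recovery tests therefore use
unblurred renders, and cohort-contrast tests use the realistic settings.

## Synthetic data generator

Defaults encode the study conditions: enzyme series 1–20 nM, 30 min traces
sampled each minute; vesicle images with background 100 counts, lumen
contrast 300 counts, membrane ring 6 px wide, Gaussian PSF σ = 1.5 px,
Poisson shot noise plus 2-count Gaussian read noise, 16-bit quantization;
cohorts of 15 vesicles with radii drawn uniformly from 30–50 px (the study
does not publish its size distribution; this range at 0.2 μm/px spans
12–20 μm diameters). The lit-condition cohort is built at the threefold
membrane:lumen contrast observed experimentally; the no-iLID control at
ratio 1. The vesicle-pair geometry is two overlapping equal circles
truncated at their radical line — a deliberately simple deflation proxy —
with the contact chord painted 3 px thick (a membrane–membrane interface
is optically thin) at `ratio_interface × (lumen − bg)` above background,
and five measurement lines perpendicular to the chord.

What the generator does **not** emulate: realistic optics (Airy PSF, axial
sectioning), photobleaching, vesicle shape fluctuations, out-of-plane
(3-D) contributions to the membrane signal, and operator variability in
annotation placement. Passing round-trip tests therefore demonstrate that
the quantifiers invert this image model, not that they are unbiased on
arbitrary microscope data; the built-in bias of the interface rule under
blur (above) is the clearest example of the difference.

## Statistics and orchestration

Group comparison is the two-tailed Welch t-test (unequal variances,
Welch–Satterthwaite degrees of freedom) plus the boxplot five-number
summary (median, quartiles, min/max whiskers). Multi-group ANOVA with
Tukey or Bonferroni correction is left to standard statistical packages.
Identical constant groups return `t = 0, p = 1`; two *different* constant
groups raise a degenerate-variance error.

Pipeline runs are driven by a YAML config with one global seed; each stage
derives a sub-seed as `SeedSequence([seed, crc32(stage_name)])`, so stages
rerun independently yet reproducibly, and an identical config reproduces a
byte-identical report (the config hash excludes the output directory).

## Problem sizes

Defaults were chosen so a full run is interactive on one core: the lit
steady state converges in ≈34 simulated seconds (≈10⁵ explicit steps,
under a second of wall time at `n_r = 64`); property suites use `n_r =
16–24`; image cohorts are 15 images of 192×192 px. Larger grids and
cohorts only tighten the already-small discretization and sampling errors.

## Known limitations

* The disk model is 2-D; real vesicles are spheres and real images optical
  sections, which the study itself names as the main source of
  model–experiment discrepancy. No spherical variant is provided.
* Static dark/lit affinity states: no photocycle kinetics, no coupling of
  the luminescence decay into a time-varying light state, no slow
  dark-reversion of the bound complex.
* Annotations are inputs; there is no automatic vesicle segmentation.
* `α` and `S0` in the kinetics module are arbitrary scales: only `K` and
  quantities derived from `λ = K·E` are meaningful.
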