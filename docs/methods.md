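# Methods

This note records the models implemented by `batquant`, the choices made
where the procedures are conventionally under-specified, and what the
synthetic-data generators do and do not establish.

## Iso-contour VOI quantification

A VOI is an axis-aligned voxel-index box (0-based, half-open) drawn around
the target tissue. Quantification applies a relative threshold

    T = min + c · (max − min),    c = 0.30 by default,

with min/max taken over the VOI only, and retains voxels with value ≥ T
(ties retained). Outputs:

- `suv_mean` = mean retained concentration (Bq/cc) / (injected dose (Bq) /
  body weight (g)), reported in g/cm³;
- `metabolic_volume_cm3` = retained voxel count × voxel volume;
- `total_metabolic_activity` = product of the two (reported unlabelled, as
  the source tables do, although dimensionally it is g).

**Degenerate inputs.** A uniform VOI (max = min) has T = min and retains
every voxel. A VOI whose maximum is 0, or whose retained count falls below
a configurable minimum (default 1), is flagged *not quantifiable* (NQ)
instead of returning numbers; callers may opt into an exception. Images
still in counts/cc, or still dynamic, are rejected with instructions to
calibrate / select a frame first.

**SPECT calibration** multiplies counts/cc by a phantom-derived factor
(default 635 Bq/count, valid for both Tc-99m and I-123 on the emulated
system) exactly once; re-calibration is rejected.

**Smoothing/resampling** to coarse isotropic voxels (default 3 mm) is
mean-pooling over the footprint of each output voxel, implemented as
separable overlap-weighted averaging. Concentrations are intensive, so a
constant image is invariant and total activity is conserved wherever output
voxels tile the input exactly; edge voxels that extend past the grid
average only their covered footprint. A smoothing kernel is not otherwise
specified by the procedure being reproduced; mean-pooling was chosen as the
unique linear smoother that is exactly conservative on integer ratios.
Upsampling is rejected.

**Dynamic series.** Which frame(s) of a dynamic acquisition feed the SUV is
conventionally unstated; the default takes the **last** frame (latest, most
trapped uptake), with `sum` (duration-weighted mean concentration) and
explicit frame index as alternatives. The iso-contour is applied once, on
the selected static volume.

## PRF thermometry

Each magnitude spectrum is fitted with two line profiles — Lorentzian by
default, Gaussian selectable — plus a quadratic polynomial baseline, by
bounded nonlinear least squares (`scipy.optimize.least_squares`, tight
tolerances). Centers are constrained to fixed windows: water 4.2–5.2 ppm,
CH₂ 0.9–1.8 ppm; linewidths to (10⁻⁴, 0.5) ppm; amplitudes non-negative.
Initial centers come from the in-window maxima.

A resonance counts as **detected** only if its fitted amplitude clears
`max(3σ, 0.02 · dynamic range)`, σ being a robust (MAD-based) residual
scale. The absolute floor guards the noiseless limit where σ → 0; without
it an absent peak could be "detected" at zero amplitude. Failed fits and
undetected peaks yield NaN separations and are excluded from the series,
never interpolated or fabricated.

The separation series δ(t) = δ_water − δ_CH₂ is converted to temperature
change by

    ΔT(t) = −(δ(t) − δ̄_base) / k,    k = 0.01 ppm/°C,

with δ̄_base the mean over all accepted pre-cooling timepoints (window
configurable). The sign convention — warmer ⇒ water upfield ⇒ smaller
separation — is the standard PRF behaviour; only the coefficient's
magnitude is conventionally quoted, so the sign is a configuration switch.
CH₂ serves as the temperature-stable internal reference. ppm↔Hz conversion,
where needed, uses γ/2π = 42.577 MHz/T (configurable).

Summary values such as "ΔT at 1 h of cooling" are read at the accepted
timepoint nearest the requested time (`TemperatureSeries.delta_T_at`);
whether the source studies reported the endpoint, a window mean or an
extremum is unstated, so the endpoint is the default and the full series is
always returned.

## Biodistribution

%ID/g = 100 · A₀ / D / m with A₀ the activity decay-corrected to injection
time (A₀ = A · 2^(t/T½); half-lives F-18 6586 s, Tc-99m 21 636 s, I-123
47 592 s). Correction is applied by default — standard practice, though the
reproduced tables do not state it — and can be disabled; a counter
efficiency factor for raw counts is applied upstream of `OrganCount`.

## Synthetic data

The generators state a world and keep it fixed; they are not tuned to any
test outcome.

**Phantoms.** Compartments are ellipsoids (the bilobed interscapular depot
is approximated by two overlapping ellipsoids; no atlas anatomy).
Rasterisation is partial-volume by 3³ sub-voxel sampling, painting
compartments in order (later compartments replace earlier in proportion to
in-voxel fraction). The scanner is modelled as a Gaussian PSF of the
system's stated resolution (1.4 mm PET, 0.6 mm SPECT FWHM) followed by
Poisson noise on expected counts per voxel (concentration × voxel volume ×
`counts_per_Bq`), rescaled back to concentration units. The default
`counts_per_Bq` = 2 represents sensitivity × acquisition time giving a few
hundred expected counts in a hot ~1 mm³ voxel (peak SNR ≈ 20), consistent
with the emulated small-animal systems. The default rat torso places the
depot (acute-cold SUV by tracer), heart, liver and an SUV-0.3 background in
a 45 × 45 × 58.5 mm section at 0.9 mm (PET) / 0.4 mm (SPECT) sampling.
What phantoms do **not** model: tracer kinetics, attenuation/scatter,
reconstruction artefacts, anatomical realism beyond ellipsoids — so a green
recovery test establishes correctness of the quantification chain under
the stated noise/PSF model, not scanner fidelity.

**Cooling spectra.** Two Lorentzian resonances (water 4.70 ppm amplitude 1,
CH₂ 1.30 ppm amplitude 1.5 — BAT is fat-rich), linewidths 0.05 ppm, on a
1024-point 0–6 ppm axis, sampled every 4 min for 2.5 h. The programmed
trajectory holds ΔT = 0 for 20 min, ramps (linear or saturating
exponential) to the tissue's ΔT at one cooling-hour (defaults: BAT −1.2 °C,
muscle −2.4 °C, the control-group values), then holds. The separation
follows δ(t) = 3.40 − k·ΔT(t) ppm (3.40 ppm baseline separation is the
standard water−CH₂ value; not stated by the source). Noise is additive
Gaussian at amplitude/SNR (default SNR 20); `snr=inf` is bit-exactly
noiseless. Eddy currents, phase errors and baseline distortions of real
spectra are not modelled.

**Cohorts.** Per-subject SUV and metabolic volume are drawn from
zero-truncated Normals with the reported group means; printed "mean ± x"
dispersions are interpreted as **SEM** and converted to SD via √n (n = 4
tracer groups, n = 8 MRI/control) — the sources do not say SEM vs SD, so
the choice is a flag (`dispersion_is_sem`). Total metabolic activity is the
per-subject product, preserving the pipeline identity TMA = SUV × V. The
amino-acid-tracer group's volumes are emitted as NQ (quantifiable = False),
and its never-acquired condition is absent (NA), exercising both reporting
paths. MRS ΔT draws are untruncated Normals.

## Statistics

Unpaired comparisons default to Welch's t (robust to unequal variances;
pooled Student variant selectable); paired comparisons are the one-sample t
on differences; inter-group comparison is one-way fixed-effects ANOVA with
all k(k−1)/2 pairwise t-tests Bonferroni-adjusted as p_adj = min(1, m·p).
Degenerate inputs (zero variance in both groups, or zero-variance paired
differences) are flagged rather than returning NaN: p = 1 when means agree,
p = 0 with infinite statistic otherwise. Report tables print mean ± SEM,
mark p < 0.10 against baseline (↑) and against acute cold (†) — the
reporting threshold of the reproduced tables, distinct from the 0.05
significance level; both are parameters — and propagate NQ/NA. Markers
annotate only conditions later in the column order than their reference.

## Numerical notes

- Bit-exact claims (seeded generator determinism, SPECT calibration round
  trip) hold for quantized inputs (discrete counts); arbitrary floats
  round-trip to ~1 ulp.
- The peak fitter's 10⁻⁶ ppm noiseless accuracy relies on tight solver
  tolerances (xtol = ftol = gtol = 10⁻¹⁴); at SNR 20 and 0.05 ppm
  linewidth, single-spectrum center precision is ~10⁻³ ppm, i.e. ~0.1 °C
  per timepoint, which a multi-spectrum baseline average reduces further.
- The 30% iso-contour on a blurred compartment sits outside the 50% edge
  contour, so recovered volumes overestimate truth by ~10–15% at PET
  resolution for a 0.6 cm³ depot; noise inflation of the VOI maximum
  partially offsets this. This bias is a property of the published rule,
  not a defect of the implementation.

## Known limitations

- VOI boxes are axis-aligned and given (no automatic BAT detection, no
  oblique orientations; world geometry is per-axis spacing only).
- No image reconstruction, attenuation, scatter or registration.
- Thermometry is relative (change vs baseline), magnitude-spectrum only;
  no time-domain fitting, multi-voxel CSI or absolute temperature.
- Mixed-effects / repeated-measures designs and multiple-testing procedures
  beyond Bonferroni are out of scope.
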