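# batquant

Quantification of brown adipose tissue (BAT) activity in small-animal
studies, across the three measurement channels such studies combine:

1. **Emission imaging (PET/SPECT).** Iso-contour quantification of a
   hand-drawn volume of interest (VOI) around the interscapular BAT depot:
   the VOI is thresholded at

   `T = min + 0.30 · (max − min)`

   (min/max over the VOI), and voxels with value ≥ T form the *metabolic
   volume* V (cm³). The retained voxels yield

   `SUV_mean = C̄ / (D / W)` — mean concentration C̄ (Bq/cc) over retained
   voxels, normalised by injected dose D (Bq) per body weight W (g), printed
   in g/cm³ — and the composite index *total metabolic activity*
   `TMA = SUV_mean · V`. Raw SPECT output in counts/cc is first converted to
   Bq/cc with a phantom-derived factor of 635 Bq/count.

2. **MRS thermometry.** Serial single-voxel PRESS spectra of BAT carry a
   water resonance (~4.7 ppm) and the CH₂ methylene line of fat (~1.3 ppm).
   Water drifts with temperature at ~0.01 ppm/°C while CH₂ is stable, so
   after fitting both lines (Lorentzians over a polynomial baseline) the
   temperature change follows

   `ΔT(t) = −[δ(t) − δ̄_baseline] / 0.01 ppm·°C⁻¹`,

   where δ = δ_water − δ_CH₂ and the baseline is the pre-cooling mean
   (warmer tissue ⇒ water moves upfield ⇒ smaller separation).

3. **Biodistribution.** Dissected-organ gamma counts, decay-corrected to
   injection time, expressed as percent injected dose per gram:
   `%ID/g = 100 · A₀ / D / m`.

A synthetic-data module generates digital-rat phantoms (ellipsoidal
compartments, partial-volume rasterisation, Gaussian PSF of 1.4 mm FWHM for
PET / 0.6 mm for SPECT, Poisson counting noise), cooling-experiment spectrum
series with programmed temperature trajectories, and cohorts with the study
group structure (five tracers × four temperature conditions, n = 4 per
group; MRS control/acclimated groups, n = 8) — each carrying machine-readable
ground truth for recovery testing. Group comparisons (Welch/pooled t,
paired t, one-way ANOVA with Bonferroni-adjusted pairwise tests) and
table-style reports (mean ± SEM with p < 0.10 markers, NQ/NA propagation)
round out the chain.

The computational cores are scikit-learn-style estimators
(`IsoContourQuantifier`, `LorentzianPeakFitter`, `PRFThermometer`) with
`fit`, `get_params`/`set_params` and trailing-underscore fitted attributes;
module-level functions (`quantify_voi`, `fit_peaks`, `temperature_series`,
…) are thin wrappers over them.

## Worked example

```python
import numpy as np
from batquant import (VOIBox, quantify_voi, generate_phantom,
                      generate_cooling_series, CoolingProtocol,
                      PRFThermometer)
from batquant.simulate import default_rat_phantom

# digital rat, acute-cold FDG condition, PET PSF 1.4 mm, Poisson noise
image, truth = generate_phantom(default_rat_phantom("PET"), seed=1)
r = quantify_voi(image, VOIBox(((12, 38), (3, 16), (14, 31))))
print(f"SUV_mean {r.suv_mean:.2f} g/cm3, volume {r.metabolic_volume_cm3:.2f} cm3")
# -> SUV_mean 2.54 g/cm3, volume 1.01 cm3

# one-hour cooling run, BAT cooling by -1.2 degC, spectra every 4 min
series, _ = generate_cooling_series(CoolingProtocol(snr=20.0), seed=2)
therm = PRFThermometer(baseline_end_s=1200.0).fit(series["BAT"])
print(f"BAT delta-T at 1 h: {therm.series_.delta_T_at(4800.0):+.2f} degC")
# -> BAT delta-T at 1 h: -1.22 degC
```

The SUV_mean lands below the depot's true SUV of 3.24 because the 30%
iso-contour keeps a shell of partial-volume voxels; the recovered metabolic
volume correspondingly slightly exceeds the anatomical depot volume. The
thermometry estimate recovers the programmed −1.2 °C within the
noise-limited precision of the peak fits.

A command-line interface mirrors the library:
`batquant quantify`, `batquant fit-spectra`, `batquant simulate
phantom|spectra|cohort`, `batquant stats` (see `--help` on each).

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the whole chain end to end on seeded synthetic data — phantom
generation and VOI quantification (PET and calibrated SPECT), the
thermometry chain on a simulated cooling protocol, a full synthetic
dissection, and cohort report assembly — printing the measured quantities
and writing the JSON result mapping to `--out`.
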