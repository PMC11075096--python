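# hsdfm

Analysis toolkit for **hyperspectral dark-field microscopy (HSDFM)** of
tissue, aimed at label-free classification of tissue types — including
carcinoma subtypes — in breast lumpectomy specimens, where a fast
assessment of tumor margins can spare patients a second surgery.

A dark-field microscope illuminates the sample obliquely at an angle larger
than the objective's collection cone, so the camera sees back-scattered
light only.  Scanning a tunable filter from 480 to 650 nm (5 nm steps,
35 bands) yields a *data cube* `I(m, n, λ)` whose per-pixel spectra carry
tissue-specific scattering signatures.  This package implements the full
analysis chain on such cubes:

- **Reflectance normalization** against dark and white-standard cubes, each
  band scaled by its exposure time:
  `X = (I/Δτ₁ − I_dark/Δτ₂) / (I_ref/Δτ₃ − I_dark/Δτ₄)`,
  plus per-band spatial flattening of long-range illumination
  non-uniformity (`hsdfm.datacube`).
- **Supervised classification** with the spectral angle mapper: the
  spectral correlation angle (SCA) between a pixel spectrum **x** and a
  tissue endmember **μᵢ** is `αᵢ = arccos(x·μᵢ / (‖x‖‖μᵢ‖))`.  A pixel is
  assigned to type *i* when `αᵢ < αᵢᵗʰ`, with ties resolved by the minimum
  angle.  The threshold is anchored by the **orthogonalized SCA (OSCA)**:
  the smallest angle between μᵢ and any pixel of a reference cube known to
  contain none of that tissue, which guarantees zero false positives on the
  reference by construction (`hsdfm.sam`).
- **Unsupervised unmixing**: K-means over the pixel matrix `X ∈ ℝⁿˣᵖ`
  (Lloyd iterations, initial centers drawn from the distinct rows, best of
  10 restarts) discovers endmembers with no prior labels; per-pixel
  nonnegative least squares `mⱼ = argmin_{m≥0} ‖U m − xⱼ‖₂` turns them into
  continuous abundance maps (`hsdfm.unmix`).
- **Cross-validation** of the two routes: centroids are matched to library
  endmembers by spectral angle and scored by the bandwise residual ratio
  `(μᵢˢᵘᵖ − μᵢᵘⁿˢᵘᵖ)/μᵢᵘⁿˢᵘᵖ` and by Dice overlap of segmentation and
  abundance masks (`hsdfm.crossval`).
- **Phantom validation model**: Lorenz–Mie optics of dilute polystyrene
  microsphere suspensions (`μₛ′(λ) = μₛ(λ)(1 − g(λ))`, exactly linear in
  the bead volume fraction) and a seeded Monte-Carlo photon-transport model
  of the dark-field geometry (15° incidence, NA 0.13 collection within a
  1.6 mm field of view) that builds a reflectance look-up table over volume
  fraction and wavelength and inverts measured spectra to concentrations
  (`hsdfm.phantom`).
- **Synthetic scenes**: because real tissue cubes are not publicly
  distributable, `hsdfm.synthetic` generates raw cube triplets with
  linearly mixed tissue templates (blood with hemoglobin absorption dips at
  540/575 nm, fat flat above 550 nm, fibrous-tissue variants with a 3–4%
  ripple, four carcinoma shapes), exposure scaling, dark offset, smooth
  illumination fields and multiplicative sensor noise — with ground truth,
  so every stage of the chain is testable end to end.

## Worked example

Run the full synthetic study at one seed — generate a 128×128 scene with
five tissues (two carcinomas) at 2% noise, extract endmembers from
annotated regions, build the OSCA library, segment, run K-means + NNLS and
cross-validate:

```python
from hsdfm.pipeline import RunConfig, run_crossval

run = run_crossval(RunConfig(seed=0))
for p in run.report.pairs:
    print(f"{p.library_label:>6s} <-> cluster {p.cluster}: "
          f"angle {p.angle:.4f} rad, max |residual| "
          f"{100 * p.max_residual_ratio:.3f}%, Dice {p.dice:.3f}")
```

prints

```
  ICT1 <-> cluster 1: angle 0.0015 rad, max |residual| 0.695%, Dice 0.993
   IDC <-> cluster 0: angle 0.0026 rad, max |residual| 0.474%, Dice 0.987
   fat <-> cluster 4: angle 0.0031 rad, max |residual| 2.757%, Dice 0.986
   IMC <-> cluster 2: angle 0.0033 rad, max |residual| 0.936%, Dice 0.980
 blood <-> cluster 3: angle 0.0051 rad, max |residual| 1.236%, Dice 0.987
```

Every K-means cluster is identified with a tissue type; the two carcinoma
endmembers (IDC, IMC) found without any prior labels agree with the
supervised, annotation-guided ones to well under 2% per band, and their
abundance maps colocalize with the supervised segmentation (Dice ≈ 0.99).
The fat endmember is the hardest match (2.8%): its cluster absorbs mixed
boundary pixels from both neighbors — matching non-tumor clusters is
noticeably harder than matching the carcinomas, exactly because sub-pixel
mixing is strongest around the dominant normal tissues.

The phantom model in two lines:

```python
import numpy as np
from hsdfm.phantom import BeadPhantom, bulk_optical_properties

props = bulk_optical_properties(BeadPhantom(368.0, 0.003), np.array([500.0, 600.0, 700.0]))
# mu_s [1/mm]: 7.6695 5.0348 3.3331;  g: 0.7982 0.7371 0.7057
# mu_s' [1/mm]: 1.5477 1.3236 0.9808  (exactly mu_s * (1 - g))
```

A `hsdfm` command-line interface exposes the same stages
(`hsdfm simulate`, `normalize`, `extract-endmembers`, `build-library`,
`segment`, `unmix`, `crossval`, and `hsdfm phantom mie|mc|lut|invert`);
see `hsdfm --help`.

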