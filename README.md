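# natsynth-fus

Analysis pipeline for trial-based hemodynamic imaging experiments that
compare responses to **natural sounds** and **statistics-matched synthetic
sounds** — the paradigm used to ask whether a cortical region is driven by
standard frequency and spectrotemporal-modulation features (in which case
matched synthetics evoke the same response) or by higher-order structure
(in which case responses diverge, as they do in human non-primary auditory
cortex but not in ferret auditory cortex).

The package targets functional ultrasound (fUS) recordings — trial-
structured voxel timecourses acquired slice by slice in separate sessions —
but every statistic operates on generic voxel × sound response matrices.
It provides, in the order a study runs:

1. **`synthgen`** — a synthetic-data generator with fully known ground
   truth: planted low-rank components, gamma-shaped hemodynamics,
   sound-correlated motion artifacts shared between in- and out-of-cortex
   voxels, slice-wise noise, and a configurable natural-vs-synthetic
   response gap that grows with distance to primary auditory cortex
   ("human" profile) or is absent ("ferret" profile).
2. **`preprocess`** — power-Doppler image formation (SVD clutter filter),
   percent-signal-change normalization, time-window averaging into
   response matrices, best-frequency (tonotopy) maps.
3. **`scrub_cca`** — denoising part I: canonical correlation analysis on
   trial residuals finds timecourses shared between in- and out-of-cortex
   voxels (motion-like noise) and projects them out of the full data.
4. **`dss`** — denoising part II: denoising source separation. Whiten each
   (repetition, slice) matrix, average across repetitions, concatenate
   across slices, and take top principal components — the *reliable
   components* `R`. Denoising is `D_denoised = R R⁺ D`; the component count
   is chosen by cross-validation over held-out sound pairs.
5. **`nse`** — the core statistic and its noise correction (below), plus
   the spatial correlation profile and its 75%-decay distance τ₇₅.
6. **`components`** — histogram-entropy voxel decomposition (an ICA
   variant suited to data with many voxels) and cross-species component
   prediction with nested cross-validated ridge regression.
7. **`acoustic_features`** — cochleagrams (gammatone filterbank) and
   temporal/spectral/joint modulation energies, with a max-statistic
   permutation test for component–feature attribution.
8. **`spatial_stats`** — surface projections, annular distance-to-PAC
   profiles and slopes, sign tests across subjects, bootstrap model
   comparisons, category-wise NSE, normalized difference maps, and the
   video motion index.

## The core statistic

Dissimilarity between paired response vectors `x` (natural) and `y`
(matched synthetic) is the **normalized squared error**

```
NSE(x, y) = μ((x − y)²) / (μ(x²) + μ(y²) − 2 μ(x) μ(y))
```

with `μ(·)` the mean across sounds: 0 for identical responses, 1 for
independent responses, up to 2 for zero-mean anticorrelated responses.
`1 − NSE` equals the Pearson correlation when the signals share mean and
variance. Because measurement noise biases the power terms upward, powers
are replaced by unbiased estimates built from two independent measurement
splits `x₁, x₂`:

```
μ̂(x²) = ½ μ(x₁²) + ½ μ(x₂²) − ½ μ((x₁ − x₂)²)
```

(the residual power `μ((x₁ − x₂)²)` equals twice the noise power in
expectation), giving a corrected NSE whose noise floor is zero. Voxels are
used only when their test–retest NSE is below 0.4. The analogous unbiased
signal variance is `(var(r₁ + r₂) − var(r₁ − r₂)) / 4`.

## Worked example

Simulate a ferret-like dataset (no natural/synthetic gap) and a human-like
one (gap growing with distance to primary auditory cortex), run the full
denoising chain, and measure the corrected-NSE map and its distance slope:

```python
import numpy as np
import natsynth_fus as nf
from natsynth_fus import preprocess, scrub_cca, dss, nse, spatial_stats

for mode in ("ferret", "human"):
    sim = nf.simulate(seed=0, gap_profile=mode)
    ds = preprocess.percent_signal_change(sim.dataset)
    ds, _ = scrub_cca.scrub(ds, sim.geometry, k=20)
    ds, _ = dss.denoise_dataset(ds, sim.geometry, n_components=8)
    odd, even = preprocess.response_splits(ds)
    res = nse.nse_map(odd.natural(), even.natural(),
                      odd.synthetic(), even.synthetic())
    prof = spatial_stats.annular_profile(res.corrected_nse, sim.geometry,
                                         bin_size=0.5,
                                         valid_mask=res.valid_mask)
    print(f"{mode:6s} reliable voxels: {res.valid_mask.mean():.2f}  "
          f"median corrected NSE: {np.nanmedian(res.corrected_nse[res.valid_mask]):.3f}  "
          f"slope: {prof.slope:+.3f} NSE/mm")
```

prints

```
ferret reliable voxels: 0.96  median corrected NSE: -0.018  slope: -0.024 NSE/mm
human  reliable voxels: 0.96  median corrected NSE: 0.117  slope: +0.075 NSE/mm
```

96% of cortical voxels pass the test–retest reliability gate after
denoising. In the ferret-like simulation the corrected NSE sits at its
zero noise floor everywhere and the NSE-vs-distance slope is ~0 (natural
and matched synthetic sounds are indistinguishable); in the human-like
simulation responses diverge increasingly with distance from primary
auditory cortex, giving a clearly positive slope. This is the package's
desk-scale reproduction of the species contrast the paradigm was built to
detect.

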