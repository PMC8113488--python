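# smlmdecorr

Parameter-free rendering and resolution estimation for single-molecule
localization microscopy (SMLM).

SMLM software outputs a list of localization coordinates, not an image. To
estimate the resolution of the reconstruction with image-based methods, the
localizations must first be rendered — and the rendering choices (pixel
size, kernel) can bias the estimate. This package implements a processing
chain that removes those choices:

* **Bilinear histogram rendering.** Each localization with position
  [xₙ, yₙ] contributes unit mass split over its four nearest pixels,

  I[x, y] = Σₙ δ[x − ⌊xₙ⌋, y − ⌊yₙ⌋] ∗ wₙ,   wₙ = (1−fy, fy)ᵀ ⊗ (1−fx, fx),

  where fx, fy are the sub-pixel fractional positions. Unlike the standard
  histogram it carries the sub-pixel information, and unlike Gaussian
  rendering it assumes nothing about the localization uncertainty.
* **Decorrelation resolution estimation.** With F(k) the spectrum of the
  (mean-subtracted, apodized) image and Fn(k) = F(k)/|F(k)| its phase-only
  normalization, the cross-correlation

  d(r) = Σ_{|k|≤r} Re[F·conj(Fn)] / √( Σ_{|k|≤1} |F|² · Σ_{|k|≤r} |Fn|² )

  is swept over ideal low-pass cutoffs r (Nyquist = 1) and a bank of
  inverted-Gaussian high-pass pre-filters. The largest peak position r_max
  marks the effective cutoff frequency; the resolution is
  **2 · pixel_size / r_max**.
* **The parameter-free workflow.** The pixel size is swept and the smallest
  resolution retained (fine pixels fail from sparsity, coarse pixels are
  Nyquist-bound at twice the pixel size). Localization counts are
  normalized to the area covered by the structure (binarized 5 nm bilinear
  rendering, threshold 0.5), and the resolution-versus-density curve with
  its plateau tells whether the labeling density suffices — about
  1–4 × 10⁴ loc/µm² is required.
* **A synthetic SMLM generator** (filaments, rings, line pairs, gratings;
  compound-Poisson emitter blinking; Gaussian localization error) provides
  ground truth for every stage.

## Worked example

```python
from smlmdecorr import *

fov = FieldOfView(0, 0, 3000, 3000)                      # 3 x 3 µm field
phantom = make_phantom("filaments", {"count": 14, "length": 9000}, fov, seed=1)
config = SimConfig(fov=fov, emitter_linear_density=0.2,
                   mean_locs_per_emitter=20, sigma_loc=6.0, seed=1001)
table = simulate_localizations(phantom, config)
print(f"simulated {len(table)} localizations")

area = estimate_sample_area(table, fov)                  # 5 nm render, 0.5 threshold
print(f"sample area: {area:.2f} um^2  "
      f"density: {localization_density(len(table), area):.0f} loc/um^2")

sweep = pixel_size_sweep(table, fov)
for p, res in sweep.entries:
    label = "none" if res.resolution_nm is None else f"{res.resolution_nm:6.1f} nm"
    print(f"  pixel {p:5.1f} nm -> {label}")
print(f"best resolution: {sweep.best_resolution_nm:.1f} nm "
      f"at pixel size {sweep.best_pixel_size_nm:g} nm")
```

prints

```
simulated 504140 localizations
sample area: 2.72 um^2  density: 185170 loc/um^2
  pixel   2.0 nm ->   26.0 nm
  pixel   3.0 nm ->   22.2 nm
  pixel   4.0 nm ->   19.0 nm
  pixel   5.0 nm ->   18.0 nm
  pixel   7.5 nm ->   18.1 nm
  pixel  10.0 nm ->   21.4 nm
  pixel  15.0 nm ->   32.8 nm
  pixel  20.0 nm ->   42.3 nm
  pixel  30.0 nm ->   71.1 nm
  pixel  40.0 nm ->   94.8 nm
best resolution: 18.0 nm at pixel size 5 nm
```

The U-shape is the signature of the method: at 2–3 nm pixels gaps between
localizations degrade the estimate (sparsity-limited), at 20–40 nm the
estimate tracks roughly twice the pixel size (sampling-limited), and the
minimum — here 18.0 nm for a 6 nm localization precision — is the resolution
the data supports. `density_sweep` + `detect_plateau` repeat this per
localization count to verify the labeling density has reached its plateau.

## Command line

One subcommand per stage, each writing JSON with a reproducibility manifest:

```sh
smlmdecorr simulate --kind filaments --fov 0,0,3000,3000 --sigma-loc 6 --seed 1 --out sim/
smlmdecorr area       sim/sim_filaments_seed1.csv --fov 0,0,3000,3000
smlmdecorr resolution sim/sim_filaments_seed1.csv --fov 0,0,3000,3000 --pixel-size 5
smlmdecorr sweep-pixel   sim/sim_filaments_seed1.csv --fov 0,0,3000,3000
smlmdecorr sweep-density sim/sim_filaments_seed1.csv --fov 0,0,3000,3000 --seed 1
smlmdecorr render     sim/sim_filaments_seed1.csv --fov 0,0,3000,3000 --pixel-size 5
```

Localization tables are delimited text with ThunderSTORM-style headers
(`x [nm]`, `y [nm]`, optional `uncertainty [nm]`, `frame`); `resolution`
also accepts grayscale TIFFs.

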